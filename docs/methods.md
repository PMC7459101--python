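# Methods

## Radial normalization

A nucleus is an ellipsoid with centre c, semi-axes a ≥ b ≥ c′ and a proper
rotation R (principal → lab frame). For a signal at x the radial ratio is

ρ = |x − c| / R(u),  R(u) = 1 / √(Σᵢ uᵢ²/aᵢ²),

with u the unit direction of x − c expressed in the principal frame: the
boundary radius is taken along the ray *through the signal*, not the mean
radius, so the normalization is exact for non-spherical nuclei. The nuclear
volume is then divided into N = 10,000 concentric equal-volume shells;
signal s falls in the smallest shell k with ρ³ ≤ k/N. The continuous
**volume-mode index** ρ³ runs from 0.0 (centre) to 1.0 (border) and is
uniform for a spatially uniform signal population — that flat null is the
reason volume mode is the default. The raw ratio ρ (**linear mode**) is
also available because published distance-index charts do not always state
which scale they plot; every output table records the mode used. A
boundary-cell index comparison: volume-mode index = (linear index)³
exactly, so zone breakpoints (1/3, 2/3) on the volume-mode index cut the
nucleus into three equal-volume zones (centre / middle / periphery).

Signals marginally outside a fitted boundary are expected (ellipsoid fits
never contain every segmented spot): ratios in (1, 1.05] are clamped to 1
with a logged warning; beyond that tolerance the spot is rejected as a
segmentation/fit mismatch. The tolerance is configurable.

## Nuclear morphometry

**Mask fitting.** Binary masks (voxel-centre convention, (z, y, x) index
order, default spacing 0.13 × 0.13 × 0.2 µm) are fitted by second-order
moments: a solid ellipsoid with semi-axis a has central moment a²/5, so
semi-axes are √(5 λᵢ) of the voxel covariance eigenvalues and the
orientation is the eigenvector frame (sign-fixed to det +1). Moment
fitting is deterministic and, at the default spacing, recovers semi-axes
of 3–7 µm nuclei to well under 1%; masks below 30 voxels are rejected as
unstable. Reported volume is the measured voxel volume; the Feret
diameter of a parametric model is 2·a, of a mask the maximum pairwise
extent of its voxel centres (computed over the convex hull).

**Flattening.** From volume V and equatorial cross-section diameter d:
a = d/2, c = 3V/(4πa²), f = (c − a)/a. A sphere gives 0; flatter nuclei
are more negative. The sign convention — (c − a)/a rather than (a − c)/a
or 1 − c/a — is chosen so that the published ordering (myotube nuclei more
negative, "less spheroidal") is reproduced; it is a documented convention,
overridable by computing from the returned axes directly.

**Feret normalization.** Locus–centromere distances are Euclidean 3D
distances within a nucleus divided by that nucleus's Feret diameter, so
the systematic volume difference between Mb and Mt nuclei cannot
masquerade as locus repositioning. With two homologous signals per probe
the homolog-to-centromere assignment is unobservable; each gene signal is
paired with its *nearest* centromere signal by default (an explicit
assumption; all-pairs mode is available).

## Statistics

Group comparisons of nuclear observations use the two-sided Mann–Whitney U
test (exact null when min(n) ≤ 8 and the data are tie-free, otherwise the
tie-corrected normal approximation); other comparisons use Student's
t-test. Differential expression requires fold change ≥ 2 (or ≤ ½,
inclusive) and Benjamini–Hochberg adjusted p < 0.01 (exclusive). Per-locus
positional tests are reported without correction across loci by default
(matching per-locus significance reporting); BH across loci is a flag. The
Spearman correlation CI uses the Fisher z-transform with SE 1/√(n − 3);
a bootstrap CI was considered and rejected as the z-interval reproduces
published intervals at n = 11 to within rounding.

The K_mean neighbourhood contains genes on the GOI's chromosome whose
midpoint lies within ± window/2 of the GOI midpoint. The GOI itself is
excluded by default — including it correlates K_GOI with itself and
inflates the association; a flag restores inclusion. Per-gene windows
default to the study panel's values (0.95 Mbp for MYH2, VCAM1, MYOG,
NCAM1, ACTN3, DPP4, DES; 1.5 Mbp for ACTN2, HPRT1, MYF5, MYF6; 1.0 Mbp
otherwise).

C_co boundaries: the intermediate band is the open interval (0.5, 1.5);
its endpoints belong to the dominant groups. C_co with zero upregulated
transcripts is reported as +∞ (or NaN for 0/0) and classified "undefined".

## Synthetic-data generator

The generator emulates the *statistical* structure of the study's data,
not its optics — no PSF, noise or chromatic aberration.

**Nuclei.** Volume ~ Normal(μ, σ) truncated below at 50 µm³; flattening ~
Normal truncated to (−0.99, 0.5). Presets: Mb 970.9 ± 341.3 µm³,
−0.771 ± 0.286; Mt 811.1 ± 231.1 µm³, −0.935 ± 0.308. Each nucleus is an
oblate spheroid (a = b, c = a(1 + f)) — the two preset numbers then fully
determine shape — with uniformly random orientation. Note the flattening
truncation is *active*: with the Mt preset ~43% of the untruncated normal
mass lies below −0.99 (where the spheroid would degenerate), so the
realized flattening mean is the truncated-normal mean (≈ −0.72 for Mt),
not the raw preset; volume truncation, by contrast, is ≥ 2.7 SD below both
preset means and shifts the realized mean by < 4 µm³. Calibration tests
therefore check volumes against the preset means and flattening against
the analytic truncated mean.

**Spots.** The radial law is Beta(α, β) on the volume-mode index: draw
v ~ Beta(α, β), set ρ = v^(1/3), pick a uniform spherical direction in the
principal frame and scale component-wise by the semi-axes — the recovered
radial ratio is then exactly ρ, and Beta(1, 1) reproduces the uniform
null by inverse transform. Defaults follow the study scale: 80 nuclei per
group, two homolog signals per probe per nucleus.

**Expression.** Genes (default 2,000 over two 100 Mbp chromosomes for
experiments; the panel genome for full fixtures) are placed uniformly;
contiguous 1 Mbp blocks — the typical topologically-associating-domain
scale — share a latent log2 effect. A fixed count of blocks
(round(fraction_de × blocks), default fraction 0.1) is designated DE; their
effect is drawn from Normal(0, 2 bits) *conditioned on magnitude ≥ 1 bit*,
so "designated DE" means a genuine ≥ twofold latent change and the
designed DE fraction is recoverable by the twofold + BH filter. Per-gene
noise (0.2 bits) is added on top. Reported group means are the true means
(the reported fold change equals the latent effect exactly); raw p-values
come from a simulated 3-vs-3 replicate t-test with 0.1-bit replicate
noise, a typical small microarray design. Degenerate zero-variance tests
return p = 1 (identical groups) or 0. The GOI sampler picks genes
stratified half from DE and half from stable blocks, at most one per
block, mirroring the study's mixed panel of changing and stable loci.

**What passing tests do not show.** The generator draws independent
nuclei and spots from parametric laws; real data have segmentation error,
correlated homolog positions, probe-specific detection efficiency and
non-ellipsoidal nuclei. Passing calibration and recovery tests shows the
*pipeline arithmetic* is correct and powered at the study's sample sizes,
not that the biological effect sizes are realistic.

## Numerical choices

* Shell assignment backs off the boundary by 1e-9 so an index sitting on
  k/N (up to floating rounding) lands in shell k.
* Degenerate moment fits (equal eigenvalues) keep the eigensolver's axis
  order; the orientation sign is fixed to det +1.
* All randomness flows from one top-level seed, split per stage with
  `numpy.random.SeedSequence`; identical seeds give bit-identical outputs.
* Genomic coordinates are 0-based half-open in BED-like inputs, converted
  once at the I/O boundary; distances are reported in Mbp.
* Packaged GRCh38 panel coordinates are accurate to ~0.1 Mbp (gene bodies
  and centromere midpoints); only Mbp-scale gene–centromere distances are
  consumed, for which this precision is ample.

## Problem sizes used in the test suite

Simulation-backed tests run at the sizes the analysis is designed for:
600 nuclei for morphology calibration, 80 nuclei/group × 2 spots for
detection-power checks (20 seeds), 2,000-gene tables × 20 replicates for
the K-factor recovery experiment, and 10⁵ points for the radial-null
uniformity check. These choices are the package's own defaults for
desk-scale validation.

## Known limitations

* Ellipsoid models cannot represent lobed or indented nuclei; the radial
  ratio of such shapes is biased near concavities.
* The flattening sign convention is fixed by ordering arguments only.
* Probe-to-gene mapping of array probe sets is out of scope: the
  expression reader expects one record per gene with coordinates assigned.
* The exact Mann–Whitney null is used only for tie-free small samples;
  heavily tied small samples fall back to the tie-corrected approximation.
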