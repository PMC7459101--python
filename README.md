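# nucorg

Quantitative analysis of nuclear organization from 3D FISH microscopy,
joined with expression-change statistics — built around the comparison of
human skeletal **myoblasts (Mb)** with differentiated, fused
**myotubes (Mt)**, where gene loci reposition inside the nucleus as their
expression changes.

## What it computes

**Geometry side.** Each nucleus is modelled as an ellipsoid (parametric, or
moment-fitted from a binary voxel mask). For every FISH signal the package
computes the *radial ratio* ρ = |x − c| / R(x̂), the distance from the
nuclear centre divided by the boundary radius along the ray through the
signal, and maps it onto 10,000 concentric *equal-volume* shells. The
continuous form of this normalization, the **normalized distance index**
ρ³ ∈ [0, 1] (0 = centre, 1 = border), makes a spatially uniform null flat.
Nuclear shape is summarized by volume, **flattening** f = (c − a)/a (0 for
a sphere, negative when flattened) and the **Feret diameter** (maximum
caliper); locus–centromere distances are divided by the per-nucleus Feret
diameter so population-level size differences cannot mimic repositioning.

**Expression side.** Fold change is oriented Mt/Mb
(f_c = 2^(log₂Mt − log₂Mb)); differential calls require f_c ≥ 2 (or ≤ ½)
with Benjamini–Hochberg adjusted p < 0.01. Per chromosome the **change
coefficient** C_co = n_down / n_up groups chromosomes into up-dominant,
intermediate (0.5 < C_co < 1.5) and down-dominant. The **K factor**

    K = log₂(f_c)     if f_c > 1
    K = log₂(1/f_c)   if f_c ≤ 1

symmetrizes change magnitude; **K_mean** averages K over the ~1 Mbp genomic
neighbourhood of a gene of interest (GOI), and the Spearman correlation of
(K_GOI, K_mean) with a Fisher-z confidence interval quantifies whether
expression changes cluster in genomic neighbourhoods. A mobility-threshold
table joins each locus's Mb-vs-Mt positional test with its genomic distance
to the centromere (default threshold 50 Mbp).

**Synthetic studies.** A seeded generator produces every input the pipeline
reads: nucleus populations from the published Mb/Mt morphology statistics
(970.9 ± 341.3 µm³ / −0.771 ± 0.286 and 811.1 ± 231.1 µm³ / −0.935 ± 0.308),
FISH spots with Beta-distributed radial laws, block-correlated expression
tables, and confocal-resolution voxel masks (0.13 µm pixels, 0.2 µm
Z-steps).

## Worked example

Simulate 80 nuclei per group, place a probe with a middle-zone radial law in
myoblasts and a peripherally shifted law in myotubes, and test the shift:

```python
from nucorg import (simulate_nuclei, simulate_spots, MB_PRESET, MT_PRESET,
                    RadialLaw, spot_distance_index, compare_groups)

mb = simulate_nuclei(80, MB_PRESET, seed=1)
mt = simulate_nuclei(80, MT_PRESET, seed=2)

def indices(nuclei, law, seed):
    spots = simulate_spots(nuclei, "DPP4", law, spots_per_nucleus=2, seed=seed)
    by = {n.nucleus_id: n for n in nuclei}
    return [spot_distance_index(by[s.nucleus_id], s).normalized_distance_index
            for s in spots]

idx_mb = indices(mb, RadialLaw(2, 2), seed=3)   # middle-zone law
idx_mt = indices(mt, RadialLaw(5, 2), seed=4)   # peripheral shift
res = compare_groups(idx_mb, idx_mt, test="mann_whitney")
print(f"mean index Mb = {res.mean_a:.3f}, Mt = {res.mean_b:.3f}")
print(f"Mann-Whitney U = {res.statistic:.1f}, p = {res.p_value:.3g}")
```

Output:

```
mean index Mb = 0.481, Mt = 0.703
Mann-Whitney U = 5623.0, p = 4.24e-18
```

The mean volume-mode index rises from 0.481 (spots spread around the
middle zones) to 0.703 (mass pushed towards the nuclear border), and the
Mann–Whitney test on the 160 signals per group detects the repositioning
decisively.

The same analysis runs end to end from the shell:

```bash
nucorg simulate --out study/ --seed 7
nucorg report --input-dir study/ --out report/
```

which writes per-stage TSV tables (morphology, DE calls, chromosome
activity, K factors, radial comparisons, Feret-normalized distances,
mobility-threshold contingency) plus `summary.json` and a manifest
recording every parameter used.

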