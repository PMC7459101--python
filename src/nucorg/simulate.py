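"""Synthetic study generator: nuclei, FISH spots and expression tables.

Emulates the two cell populations of the myogenic-differentiation study —
proliferating myoblasts (Mb) and fused myotubes (Mt) — at the level the
analysis consumes:

* nucleus populations drawn from the published morphology statistics
  (volume and flattening mean ± SD per group), realized as randomly
  oriented oblate spheroids;
* FISH spots whose radial law is a Beta distribution on the volume-mode
  distance index, so any radial preference (central, middle-zone,
  peripheral) can be dialled in per probe and per group;
* expression tables with block-correlated fold changes: contiguous ~1 Mbp
  genomic blocks (the scale of topologically associating domains) share a
  latent log2 effect, mimicking neighbourhood-coherent expression changes;
* voxelized binary masks at confocal-stack resolution (0.13 µm pixels,
  0.2 µm Z-steps) for testing the mask-fitting path.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.transform import Rotation

from .errors import ConfigError, ResolutionError
from .expression import ExpressionRecord
from .geometry import NucleusModel, Spot, VoxelMask

#: confocal acquisition geometry used as the default voxel spacing (µm)
DEFAULT_SPACING = (0.13, 0.13, 0.2)


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Accept either a seed or a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# nuclei


@dataclass(frozen=True)
class MorphologyPreset:
    """Population-level nuclear morphology: volume and flattening mean ± SD."""

    name: str
    volume_mean: float
    volume_sd: float
    flattening_mean: float
    flattening_sd: float

    def __post_init__(self) -> None:
        if self.volume_mean <= 0 or self.volume_sd <= 0:
            raise ConfigError(f"{self.name}: volume mean/sd must be positive")
        if not -1.0 < self.flattening_mean < 1.0:
            raise ConfigError(f"{self.name}: flattening mean must be in (-1, 1)")
        if self.flattening_sd <= 0:
            raise ConfigError(f"{self.name}: flattening sd must be positive")


#: myoblast population: larger, less flattened nuclei
MB_PRESET = MorphologyPreset("Mb", volume_mean=970.9, volume_sd=341.3,
                             flattening_mean=-0.771, flattening_sd=0.286)
#: myotube population: smaller, more elongated (less spheroidal) nuclei
MT_PRESET = MorphologyPreset("Mt", volume_mean=811.1, volume_sd=231.1,
                             flattening_mean=-0.935, flattening_sd=0.308)

PRESETS: dict[str, MorphologyPreset] = {"Mb": MB_PRESET, "Mt": MT_PRESET}

#: truncation bounds applied when sampling morphology
VOLUME_FLOOR = 50.0  # µm³
FLATTENING_BOUNDS = (-0.99, 0.5)


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Analytic mean of a Normal(mean, sd) truncated to (lo, hi)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def simulate_nuclei(
    n: int,
    preset: MorphologyPreset,
    seed: int | np.random.Generator | None = None,
    id_prefix: str | None = None,
) -> list[NucleusModel]:
    """Draw ``n`` nuclei from a morphology preset.

    Volume is Normal truncated below at 50 µm³; flattening is Normal
    truncated to (-0.99, 0.5). Each nucleus is an oblate spheroid with
    a = b and c = a·(1 + f); the equatorial radius follows from the volume,
    a = (3V / (4·pi·(1+f)))**(1/3). Orientation is uniform over rotations
    and centres are spread on a grid (the analysis never uses absolute
    positions, only spot offsets from each centre).
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    rng = as_rng(seed)
    prefix = id_prefix if id_prefix is not None else preset.name
    av, bv = (VOLUME_FLOOR - preset.volume_mean) / preset.volume_sd, np.inf
    volumes = stats.truncnorm.rvs(
        av, bv, loc=preset.volume_mean, scale=preset.volume_sd, size=n, random_state=rng
    )
    lo, hi = FLATTENING_BOUNDS
    af = (lo - preset.flattening_mean) / preset.flattening_sd
    bf = (hi - preset.flattening_mean) / preset.flattening_sd
    flats = stats.truncnorm.rvs(
        af, bf, loc=preset.flattening_mean, scale=preset.flattening_sd, size=n,
        random_state=rng,
    )
    # uniform random rotations from normalized random quaternions
    quats = rng.normal(size=(n, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = Rotation.from_quat(quats).as_matrix()
    nuclei = []
    grid = int(math.ceil(n ** (1.0 / 3.0)))
    pitch = 40.0  # µm between nucleus centres; keeps nuclei disjoint
    for i, (v, f, rot) in enumerate(zip(volumes, flats, rots)):
        a = (3.0 * v / (4.0 * math.pi * (1.0 + f))) ** (1.0 / 3.0)
        c = a * (1.0 + f)
        center = pitch * np.array(
            [i % grid, (i // grid) % grid, i // (grid * grid)], dtype=float
        )
        nuclei.append(
            NucleusModel.parametric(
                nucleus_id=f"{prefix}_{i:04d}",
                center=center,
                semi_axes=(a, a, c),
                orientation=rot,
                group=preset.name,
            )
        )
    return nuclei


# ---------------------------------------------------------------------------
# spots


@dataclass(frozen=True)
class RadialLaw:
    """Beta(alpha, beta) law on the volume-mode distance index.

    Beta(1, 1) is the uniform-in-volume null; alpha > beta pushes signal
    mass towards the periphery, alpha < beta towards the centre.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigError(f"Beta shape parameters must be positive, got {self}")


def simulate_spots(
    nuclei: Sequence[NucleusModel],
    probe_id: str,
    law: RadialLaw,
    spots_per_nucleus: int = 2,
    seed: int | np.random.Generator | None = None,
) -> list[Spot]:
    """Place FISH spots in nuclei with a prescribed radial law.

    For each spot a volume-mode index v ~ Beta(alpha, beta) is drawn, the
    radial ratio set to rho = v**(1/3), and a direction drawn uniformly on
    the sphere in the principal frame; the spot sits at rho times the
    boundary point along that direction (component-wise scaling by the
    semi-axes), so its recovered radial ratio is exactly rho.
    """
    if not nuclei:
        raise ConfigError("nuclei list must be non-empty")
    if spots_per_nucleus < 1:
        raise ConfigError("spots_per_nucleus must be >= 1")
    rng = as_rng(seed)
    spots = []
    for nuc in nuclei:
        v = rng.beta(law.alpha, law.beta, size=spots_per_nucleus)
        rho = v ** (1.0 / 3.0)
        u = rng.normal(size=(spots_per_nucleus, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        principal = rho[:, None] * u * nuc.semi_axes[None, :]
        lab = nuc.center[None, :] + principal @ nuc.orientation.T
        for j in range(spots_per_nucleus):
            spots.append(
                Spot(
                    spot_id=f"{nuc.nucleus_id}:{probe_id}:{j}",
                    nucleus_id=nuc.nucleus_id,
                    probe_id=probe_id,
                    position=lab[j],
                )
            )
    return spots


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the block-correlated expression simulator.

    ``block_size_mbp`` sets the span of genomic blocks sharing a latent
    log2 effect (default 1 Mbp, the typical TAD scale). Blocks designated
    differentially expressed draw their effect from Normal(0,
    ``block_effect_sd``) conditioned on magnitude >= ``min_de_effect_bits``
    (default 1 bit, i.e. twofold), so a designated block carries a real
    twofold latent change; per-gene noise (``gene_noise_sd``) is added on
    top. Raw p-values come from a simulated two-sample t-test with
    ``n_replicates`` per group and replicate noise ``replicate_sd``.
    """

    n_genes: int = 2000
    chromosome_lengths_bp: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 100_000_000, "chr2": 100_000_000}
    )
    block_size_mbp: float = 1.0
    block_effect_sd: float = 2.0
    gene_noise_sd: float = 0.2
    fraction_de: float = 0.1
    min_de_effect_bits: float = 1.0
    n_replicates: int = 3
    replicate_sd: float = 0.1
    gene_length_bp: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not self.chromosome_lengths_bp:
            raise ConfigError("need at least one chromosome")
        if any(v <= 0 for v in self.chromosome_lengths_bp.values()):
            raise ConfigError("chromosome lengths must be positive")
        if self.block_size_mbp <= 0:
            raise ConfigError("block_size_mbp must be positive")
        if self.block_size_mbp * 1e6 > max(self.chromosome_lengths_bp.values()):
            raise ConfigError(
                "block size exceeds every chromosome length; no block structure possible"
            )
        if not 0.0 <= self.fraction_de <= 1.0:
            raise ConfigError("fraction_de must be in [0, 1]")
        for name in ("block_effect_sd", "gene_noise_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")


def simulate_expression(
    config: ExpressionSimConfig,
    seed: int | np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Generate an expression table with block-correlated fold changes.

    Genes are placed uniformly along the configured chromosomes. A fixed
    number of blocks — round(fraction_de × total blocks) — is designated
    DE; genes in those blocks receive the block's latent effect plus
    per-gene noise, others noise only. Reported group means are the true
    means (mean_log2_mt - mean_log2_mb equals the latent log2 fold change
    exactly); p_raw reflects a simulated replicate-level t-test.

    Returns the record list, or ``(records, truth)`` with a per-gene truth
    DataFrame when ``return_truth`` is set.
    """
    rng = as_rng(config.seed if seed is None else seed)
    chroms = list(config.chromosome_lengths_bp)
    lengths = np.array([config.chromosome_lengths_bp[c] for c in chroms], dtype=float)
    counts = rng.multinomial(config.n_genes, lengths / lengths.sum())
    block_bp = config.block_size_mbp * 1e6

    gene_chrom: list[str] = []
    gene_start = []
    gene_block = []  # (chrom index, block index) as a global id
    block_ids: list[tuple[int, int]] = []
    for ci, (ch, cnt) in enumerate(zip(chroms, counts)):
        n_blocks = int(math.ceil(lengths[ci] / block_bp))
        block_ids.extend((ci, b) for b in range(n_blocks))
        starts = np.sort(
            rng.uniform(0, lengths[ci] - config.gene_length_bp, size=cnt)
        ).astype(int)
        for s in starts:
            gene_chrom.append(ch)
            gene_start.append(int(s))
            gene_block.append((ci, int((s + config.gene_length_bp / 2) // block_bp)))

    n_de_blocks = int(round(config.fraction_de * len(block_ids)))
    de_order = rng.permutation(len(block_ids))[:n_de_blocks]
    de_blocks = {block_ids[i] for i in de_order}

    block_effect: dict[tuple[int, int], float] = {}
    for blk in sorted(de_blocks):
        if config.block_effect_sd == 0:
            eff = 0.0
        else:
            a = config.min_de_effect_bits / config.block_effect_sd
            mag = float(
                stats.truncnorm.rvs(a, np.inf, loc=0.0, scale=config.block_effect_sd,
                                    random_state=rng)
            )
            eff = mag if rng.random() < 0.5 else -mag
        block_effect[blk] = eff

    n = len(gene_chrom)
    delta = np.array([block_effect.get(blk, 0.0) for blk in gene_block])
    delta = delta + rng.normal(0.0, config.gene_noise_sd, size=n)
    baseline = rng.uniform(4.0, 12.0, size=n)

    reps_mb = baseline[:, None] + rng.normal(0, config.replicate_sd, (n, config.n_replicates))
    reps_mt = (baseline + delta)[:, None] + rng.normal(
        0, config.replicate_sd, (n, config.n_replicates)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        p_raw = stats.ttest_ind(reps_mb, reps_mt, axis=1).pvalue
    # degenerate zero-variance tests: identical samples -> 1, separated -> 0
    bad = ~np.isfinite(p_raw)
    if np.any(bad):
        diff = reps_mt.mean(axis=1) - reps_mb.mean(axis=1)
        p_raw = np.where(bad & (np.abs(diff) < 1e-12), 1.0, np.where(bad, 0.0, p_raw))

    records = []
    for i in range(n):
        records.append(
            ExpressionRecord(
                probe_id=f"probe_{i:05d}",
                gene_symbol=f"G{i:05d}",
                chromosome=gene_chrom[i],
                start_bp=gene_start[i],
                end_bp=gene_start[i] + config.gene_length_bp,
                mean_log2_mb=float(baseline[i]),
                mean_log2_mt=float(baseline[i] + delta[i]),
                p_raw=float(np.clip(p_raw[i], 0.0, 1.0)),
            )
        )
    if not return_truth:
        return records
    truth = pd.DataFrame(
        {
            "gene_symbol": [r.gene_symbol for r in records],
            "chromosome": gene_chrom,
            "block": [f"{chroms[ci]}:{b}" for ci, b in gene_block],
            "in_de_block": [blk in de_blocks for blk in gene_block],
            "block_effect": [block_effect.get(blk, 0.0) for blk in gene_block],
            "true_log2fc": delta,
        }
    )
    return records, truth


def sample_gois(
    truth: pd.DataFrame,
    n_goi: int = 11,
    seed: int | np.random.Generator | None = None,
    de_fraction: float = 0.5,
) -> list[str]:
    """Pick GOI gene symbols stratified over DE and stable blocks.

    Mirrors the study's locus panel, which mixed genes with strong
    expression changes and stable controls; at most one GOI per block so
    neighbourhoods do not coincide.
    """
    rng = as_rng(seed)
    n_de = int(round(n_goi * de_fraction))
    chosen: list[str] = []
    for want_de, k in ((True, n_de), (False, n_goi - n_de)):
        pool = truth[truth["in_de_block"] == want_de]
        blocks = pool["block"].unique()
        if len(blocks) < k:
            raise ConfigError(
                f"not enough {'DE' if want_de else 'stable'} blocks ({len(blocks)}) "
                f"for {k} GOIs"
            )
        for blk in rng.choice(blocks, size=k, replace=False):
            genes = pool[pool["block"] == blk]["gene_symbol"].to_numpy()
            chosen.append(str(rng.choice(genes)))
    return chosen


# ---------------------------------------------------------------------------
# voxelization


def voxelize(
    nucleus: NucleusModel,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    margin_voxels: int = 2,
) -> VoxelMask:
    """Rasterize an ellipsoid model onto a voxel grid (voxel-centre test).

    The grid covers the ellipsoid's axis-aligned bounding box plus a small
    margin; a voxel is set when its centre lies inside the ellipsoid. The
    mask is indexed (z, y, x) and voxel centres sit at index × spacing, so
    the rasterized nucleus centre generally shifts to a nearby grid
    position — only shape, not absolute position, is preserved.
    """
    if any(s <= 0 for s in spacing):
        raise ConfigError(f"spacing must be positive, got {spacing}")
    dx, dy, dz = spacing
    M = nucleus.orientation * nucleus.semi_axes[None, :]  # principal -> lab
    half = np.sqrt((M**2).sum(axis=1))  # bounding half-extents per lab axis
    nx = int(math.ceil(2 * half[0] / dx)) + 2 * margin_voxels
    ny = int(math.ceil(2 * half[1] / dy)) + 2 * margin_voxels
    nz = int(math.ceil(2 * half[2] / dz)) + 2 * margin_voxels
    x = np.arange(nx) * dx - (nx - 1) * dx / 2.0
    y = np.arange(ny) * dy - (ny - 1) * dy / 2.0
    z = np.arange(nz) * dz - (nz - 1) * dz / 2.0
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)  # offsets from nucleus centre
    q = pts @ nucleus.orientation  # lab -> principal (right-mult by R == R^T @ v)
    inside = ((q / nucleus.semi_axes) ** 2).sum(axis=-1) <= 1.0
    n_true = int(inside.sum())
    if n_true < 30:
        raise ResolutionError(
            f"spacing {spacing} too coarse for nucleus {nucleus.nucleus_id}: "
            f"only {n_true} voxels inside"
        )
    return VoxelMask(array=inside, spacing=spacing)
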