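"""Expression-change statistics: fold change, DE filtering, C_co, K factors.

The differentiation comparison is myotube (Mt) over myoblast (Mb): fold
change f_c = 2**(mean_log2_mt - mean_log2_mb), so f_c > 1 means upregulated
in myotubes. Differentially expressed (DE) transcripts are those with at
least a twofold change and Benjamini–Hochberg adjusted p below 0.01.

Per chromosome, the change coefficient C_co = n_down / n_up summarizes the
balance of DE directions; chromosomes with 0.5 < C_co < 1.5 form the
"intermediate" group whose members change in both directions.

The K factor symmetrizes expression-change magnitude::

    K = log2(f_c)      for f_c > 1
    K = log2(1 / f_c)  for f_c <= 1

so up- and downregulation contribute equally. K_mean is the arithmetic mean
K over genes in a genomic window (~1 Mbp, roughly one topologically
associating domain) around a gene of interest (GOI), and the Spearman
correlation between K_GOI and K_mean measures whether expression changes
cluster in genomic neighbourhoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    AnnotationError,
    InsufficientDataError,
    InvalidInputError,
    PipelineOrderError,
)
from .spatial import LocusAnnotation

ActivityGroup = Literal["up_dominant", "intermediate", "down_dominant", "undefined"]


@dataclass(frozen=True)
class ExpressionRecord:
    """One probe/gene: genomic location, group means and test results."""

    probe_id: str
    gene_symbol: str
    chromosome: str
    start_bp: int
    end_bp: int
    mean_log2_mb: float
    mean_log2_mt: float
    p_raw: float | None = None
    p_adj: float | None = None

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise InvalidInputError(
                f"{self.probe_id}: start_bp must be < end_bp "
                f"({self.start_bp} >= {self.end_bp})"
            )
        for name in ("p_raw", "p_adj"):
            p = getattr(self, name)
            if p is not None and not 0.0 <= p <= 1.0:
                raise InvalidInputError(f"{self.probe_id}: {name}={p} outside [0, 1]")

    @property
    def fold_change(self) -> float:
        return fold_change(self.mean_log2_mb, self.mean_log2_mt)

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.start_bp + self.end_bp)


@dataclass(frozen=True)
class KFactorResult:
    """K factor of a GOI and the mean K of its genomic neighbourhood."""

    gene_symbol: str
    k_goi: float
    k_mean: float | None
    window_mbp: float
    n_neighbors: int

    @property
    def defined(self) -> bool:
        return self.k_mean is not None


@dataclass(frozen=True)
class ChromosomeActivity:
    """Per-chromosome DE direction counts and change coefficient."""

    chromosome: str
    n_up: int
    n_down: int
    c_co: float
    group: ActivityGroup


def fold_change(mean_log2_mb: float, mean_log2_mt: float) -> float:
    """Linear Mt/Mb expression ratio from log2 group means."""
    if not (math.isfinite(mean_log2_mb) and math.isfinite(mean_log2_mt)):
        raise InvalidInputError(
            f"log2 means must be finite, got {mean_log2_mb}, {mean_log2_mt}"
        )
    return float(2.0 ** (mean_log2_mt - mean_log2_mb))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must all lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_adjusted_p(records: Sequence[ExpressionRecord]) -> list[ExpressionRecord]:
    """Fill ``p_adj`` by BH adjustment of ``p_raw`` across all records."""
    missing = [r.probe_id for r in records if r.p_raw is None]
    if missing:
        raise PipelineOrderError(
            "records lack p_raw; run/provide per-gene tests first: "
            + ", ".join(missing[:5])
        )
    adj = bh_adjust([r.p_raw for r in records])
    return [replace(r, p_adj=float(q)) for r, q in zip(records, adj)]


def differential_filter(
    records: Sequence[ExpressionRecord],
    fc_threshold: float = 2.0,
    alpha: float = 0.01,
) -> tuple[list[ExpressionRecord], list[ExpressionRecord]]:
    """Split records into (upregulated, downregulated) DE sets.

    Up: f_c >= fc_threshold and p_adj < alpha. Down: f_c <= 1/fc_threshold
    and p_adj < alpha. Fold-change bounds are inclusive, the alpha bound
    exclusive.
    """
    if fc_threshold < 1:
        raise InvalidInputError(f"fc_threshold must be >= 1, got {fc_threshold}")
    missing = [r.probe_id for r in records if r.p_adj is None]
    if missing:
        raise PipelineOrderError(
            "p_adj not populated (run attach_adjusted_p first) for: "
            + ", ".join(missing[:5])
        )
    up = [r for r in records if r.fold_change >= fc_threshold and r.p_adj < alpha]
    down = [r for r in records if r.fold_change <= 1.0 / fc_threshold and r.p_adj < alpha]
    return up, down


def change_coefficient(n_down: int, n_up: int) -> float:
    """C_co = downregulated / upregulated transcript count.

    Returns ``inf`` when n_up == 0 with n_down > 0 and ``nan`` for 0/0;
    both classify as "undefined" downstream.
    """
    if n_down < 0 or n_up < 0:
        raise InvalidInputError(f"counts must be non-negative, got {n_down}, {n_up}")
    if n_up == 0:
        return math.inf if n_down > 0 else math.nan
    return n_down / n_up


def classify_chromosome(
    c_co: float, low: float = 0.5, high: float = 1.5
) -> ActivityGroup:
    """Group a chromosome by its change coefficient.

    The intermediate band is the open interval (low, high); its boundaries
    go to the dominant groups. Non-finite C_co (no upregulated transcripts)
    is "undefined".
    """
    if not 0 < low < high:
        raise InvalidInputError(f"need 0 < low < high, got {low}, {high}")
    if math.isnan(c_co) or math.isinf(c_co):
        return "undefined"
    if c_co < 0:
        raise InvalidInputError(f"C_co must be non-negative, got {c_co}")
    if c_co <= low:
        return "up_dominant"
    if c_co < high:
        return "intermediate"
    return "down_dominant"


def chromosome_activity_table(
    up: Sequence[ExpressionRecord],
    down: Sequence[ExpressionRecord],
    low: float = 0.5,
    high: float = 1.5,
) -> list[ChromosomeActivity]:
    """Per-chromosome DE counts, C_co and activity group."""
    chroms = sorted({r.chromosome for r in up} | {r.chromosome for r in down})
    out = []
    for ch in chroms:
        n_up = sum(r.chromosome == ch for r in up)
        n_down = sum(r.chromosome == ch for r in down)
        c = change_coefficient(n_down, n_up)
        out.append(
            ChromosomeActivity(
                chromosome=ch,
                n_up=n_up,
                n_down=n_down,
                c_co=c,
                group=classify_chromosome(c, low, high),
            )
        )
    return out


def k_factor(f_c: float) -> float:
    """Symmetric expression-change magnitude in bits: K(f) = K(1/f) >= 0."""
    if not math.isfinite(f_c) or f_c <= 0:
        raise InvalidInputError(f"fold change must be positive and finite, got {f_c}")
    if f_c > 1:
        return math.log2(f_c)
    return math.log2(1.0 / f_c)


def neighborhood_k_mean(
    goi: str,
    records: Sequence[ExpressionRecord],
    window_mbp: float = 1.0,
    include_goi: bool = False,
    membership: Literal["midpoint", "overlap"] = "midpoint",
) -> KFactorResult:
    """Mean K factor of the genomic neighbourhood of a gene of interest.

    The neighbourhood holds records on the GOI's chromosome whose midpoint
    lies within ±window_mbp/2 of the GOI midpoint (``membership="overlap"``
    instead requires any overlap with that window). The GOI itself is
    excluded by default so K_GOI does not correlate with itself. An empty
    neighbourhood yields ``k_mean=None`` (flagged via ``defined``).
    """
    if window_mbp <= 0:
        raise InvalidInputError(f"window_mbp must be positive, got {window_mbp}")
    matches = [r for r in records if r.gene_symbol == goi]
    if not matches:
        raise InvalidInputError(f"GOI {goi!r} not present in expression records")
    target = matches[0]
    half_bp = window_mbp * 1e6 / 2.0
    lo, hi = target.midpoint_bp - half_bp, target.midpoint_bp + half_bp
    neigh = []
    for r in records:
        if r.chromosome != target.chromosome:
            continue
        if not include_goi and r.gene_symbol == goi:
            continue
        if membership == "midpoint":
            inside = lo <= r.midpoint_bp <= hi
        elif membership == "overlap":
            inside = r.end_bp >= lo and r.start_bp <= hi
        else:
            raise InvalidInputError(f"unknown membership rule {membership!r}")
        if inside:
            neigh.append(r)
    k_goi = k_factor(target.fold_change)
    if not neigh:
        return KFactorResult(goi, k_goi, None, window_mbp, 0)
    k_mean = float(np.mean([k_factor(r.fold_change) for r in neigh]))
    return KFactorResult(goi, k_goi, k_mean, window_mbp, len(neigh))


def correlate_kgoi_kmean(
    pairs: Sequence[tuple[float, float]]
) -> dict[str, float | int | str]:
    """Spearman correlation of (K_GOI, K_mean) pairs with a 95% CI.

    The CI comes from the Fisher z-transform of rho with standard error
    1/sqrt(n-3); the two-sided p is scipy's t-approximation. Returns a dict
    with rho, ci_low, ci_high, p_value, n and the CI method.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("pairs must be a sequence of (K_goi, K_mean) tuples")
    if np.any(~np.isfinite(arr)):
        raise InvalidInputError("pairs contain missing/non-finite values")
    n = arr.shape[0]
    if n < 4:
        raise InsufficientDataError(f"need at least 4 pairs for a correlation, got {n}")
    rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
    rho = float(rho)
    if abs(rho) >= 1.0:
        ci_low, ci_high = (rho, rho)
    else:
        z = math.atanh(rho)
        half = 1.959963984540054 / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return {
        "rho": rho,
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "p_value": float(p),
        "n": n,
        "ci_method": "fisher_z",
    }


def intrachromosomal_distance(locus: LocusAnnotation, chromosome: str | None = None) -> float:
    """Genomic gene–centromere separation in Mbp.

    ``chromosome`` optionally cross-checks that the locus annotation refers
    to the expected chromosome.
    """
    if chromosome is not None and locus.chromosome != chromosome:
        raise AnnotationError(
            f"{locus.gene_symbol} annotated on {locus.chromosome}, expected {chromosome}"
        )
    return abs(locus.midpoint_bp - locus.centromere_position_bp) / 1e6


def expression_records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of expression records (fold change included)."""
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "chromosome": [r.chromosome for r in records],
            "start_bp": [r.start_bp for r in records],
            "end_bp": [r.end_bp for r in records],
            "mean_log2_mb": [r.mean_log2_mb for r in records],
            "mean_log2_mt": [r.mean_log2_mt for r in records],
            "fold_change_mt_over_mb": [r.fold_change for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
        }
    )
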