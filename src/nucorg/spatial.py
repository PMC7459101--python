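"""Distance statistics between FISH signals and group-level comparisons.

Locus–centromere distances are Euclidean 3D distances within one nucleus,
normalized to that nucleus's Feret diameter so that overall size differences
between myoblast and myotube nuclei cannot masquerade as locus
repositioning. Group comparisons use the Mann–Whitney U test for nuclear
observations (exact null for small groups) and Student's t-test elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DataCompletenessError,
    InvalidInputError,
    PairingError,
)
from .geometry import RadialIndexResult, Spot

TestName = Literal["mann_whitney", "t_test"]

#: group sizes at or below this use the exact Mann-Whitney null (no ties)
EXACT_MWU_MAX_N = 8


@dataclass(frozen=True)
class DistancePair:
    """A gene-signal/centromere-signal distance inside one nucleus."""

    nucleus_id: str
    gene_spot_id: str
    centromere_spot_id: str
    raw_distance: float
    feret_normalized_distance: float


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison summary (two-sided)."""

    test_name: TestName
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


@dataclass(frozen=True)
class LocusAnnotation:
    """Genomic annotation of a gene locus and its chromosome's centromere."""

    gene_symbol: str
    chromosome: str
    gene_start_bp: int
    gene_end_bp: int
    centromere_position_bp: int
    probe_id: str | None = None
    window_mbp: float = 1.0

    def __post_init__(self) -> None:
        if self.gene_start_bp >= self.gene_end_bp:
            raise InvalidInputError(
                f"{self.gene_symbol}: gene start must be < end "
                f"({self.gene_start_bp} >= {self.gene_end_bp})"
            )
        if self.gene_start_bp < 0 or self.centromere_position_bp < 0:
            raise InvalidInputError(f"{self.gene_symbol}: negative genomic coordinate")

    @property
    def midpoint_bp(self) -> float:
        return 0.5 * (self.gene_start_bp + self.gene_end_bp)


def spot_pair_distance(spot_a: Spot, spot_b: Spot) -> float:
    """Euclidean 3D distance (µm) between two spots of the same nucleus."""
    if spot_a.nucleus_id != spot_b.nucleus_id:
        raise PairingError(
            f"spots {spot_a.spot_id} and {spot_b.spot_id} belong to different "
            f"nuclei ({spot_a.nucleus_id} vs {spot_b.nucleus_id})"
        )
    return float(np.linalg.norm(spot_a.position - spot_b.position))


def normalize_by_feret(distance: float, feret: float) -> float:
    """Scale an intranuclear distance by the nucleus's Feret diameter."""
    if feret <= 0:
        raise InvalidInputError(f"Feret diameter must be positive, got {feret}")
    if distance < 0:
        raise InvalidInputError(f"distance must be non-negative, got {distance}")
    return distance / feret


def pair_gene_centromere(
    gene_spots: Sequence[Spot],
    centromere_spots: Sequence[Spot],
    feret_by_nucleus: dict[str, float],
    pairing: Literal["nearest", "all"] = "nearest",
) -> list[DistancePair]:
    """Pair gene signals with centromere signals within each nucleus.

    ``nearest`` (default) pairs each gene signal with the closest centromere
    signal of the same nucleus — with two homologous signals per probe the
    homolog pairing is not observable, so nearest is used as the stated
    assumption. ``all`` emits every gene x centromere pair.
    """
    cen_by_nuc: dict[str, list[Spot]] = {}
    for s in centromere_spots:
        cen_by_nuc.setdefault(s.nucleus_id, []).append(s)
    pairs: list[DistancePair] = []
    for g in gene_spots:
        partners = cen_by_nuc.get(g.nucleus_id, [])
        if not partners:
            continue
        feret = feret_by_nucleus.get(g.nucleus_id)
        if feret is None:
            raise DataCompletenessError(
                f"no Feret diameter recorded for nucleus {g.nucleus_id}"
            )
        dists = [spot_pair_distance(g, c) for c in partners]
        if pairing == "nearest":
            chosen = [int(np.argmin(dists))]
        elif pairing == "all":
            chosen = list(range(len(partners)))
        else:
            raise InvalidInputError(f"unknown pairing mode {pairing!r}")
        for i in chosen:
            pairs.append(
                DistancePair(
                    nucleus_id=g.nucleus_id,
                    gene_spot_id=g.spot_id,
                    centromere_spot_id=partners[i].spot_id,
                    raw_distance=dists[i],
                    feret_normalized_distance=normalize_by_feret(dists[i], feret),
                )
            )
    return pairs


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: TestName = "mann_whitney",
) -> ComparisonResult:
    """Two-sided comparison of two independent samples.

    Mann–Whitney uses the exact null distribution when min(n_a, n_b) <= 8
    and the data are tie-free; otherwise the normal approximation with tie
    correction. The t-test is Student's (equal-variance) two-sample test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    if test == "mann_whitney":
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (min(a.size, b.size) <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "t_test":
        if a.size < 2 or b.size < 2:
            raise InvalidInputError("t-test requires n >= 2 per group")
        res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise InvalidInputError(f"unknown test {test!r}")
    return ComparisonResult(
        test_name=test,
        statistic=statistic,
        p_value=min(p, 1.0),
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
    )


def radial_distribution_summary(
    indices: Sequence[RadialIndexResult] | Sequence[float], n_bins: int = 10
) -> dict:
    """Histogram of distance indices over [0, 1] plus mean ± sd.

    Returns a dict with ``bin_edges``, ``fractions`` (summing to 1),
    ``counts``, ``mean`` and ``sd``.
    """
    if len(indices) == 0:
        raise InvalidInputError("cannot summarize an empty index list")
    if n_bins < 1:
        raise InvalidInputError(f"n_bins must be >= 1, got {n_bins}")
    vals = np.array(
        [
            r.normalized_distance_index if isinstance(r, RadialIndexResult) else float(r)
            for r in indices
        ]
    )
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return {
        "bin_edges": edges,
        "counts": counts,
        "fractions": counts / counts.sum(),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "n": int(vals.size),
    }


def zone_classification(
    index: float, breakpoints: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
) -> str:
    """Assign a distance index to the centre / middle / periphery zone.

    With the volume-mode index the default breakpoints (1/3, 2/3) carve the
    nucleus into three equal-volume zones.
    """
    low, high = breakpoints
    if not (0.0 < low < high < 1.0):
        raise InvalidInputError(f"breakpoints must satisfy 0 < low < high < 1, got {breakpoints}")
    if not 0.0 <= index <= 1.0:
        raise InvalidInputError(f"index must be in [0, 1], got {index}")
    if index < low:
        return "centre"
    if index < high:
        return "middle"
    return "periphery"


def mobility_threshold_analysis(
    per_locus_results: Iterable[tuple[LocusAnnotation, ComparisonResult]],
    distances_mbp: dict[str, float],
    threshold_mbp: float = 50.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Join per-locus positional tests with intra-chromosomal distances.

    Flags each locus as above/below the genomic-distance threshold and
    significant/non-significant at ``alpha``, the structure behind the
    observation that loci far (> 50 Mbp) from their centromere reposition
    during differentiation while nearer loci do not. The returned frame
    carries a ``contingency`` attribute: a 2x2 table of
    (above-threshold x significant) counts.
    """
    rows = []
    missing = []
    for locus, comp in per_locus_results:
        d = distances_mbp.get(locus.gene_symbol)
        if d is None:
            missing.append(locus.gene_symbol)
            continue
        rows.append(
            {
                "gene_symbol": locus.gene_symbol,
                "chromosome": locus.chromosome,
                "intrachromosomal_distance_mbp": d,
                "above_threshold": d > threshold_mbp,
                "p_value": comp.p_value,
                "significant": comp.p_value < alpha,
                "n_mb": comp.n_a,
                "n_mt": comp.n_b,
            }
        )
    if missing:
        raise DataCompletenessError(
            "missing intra-chromosomal distance for loci: " + ", ".join(sorted(missing))
        )
    table = pd.DataFrame(rows)
    contingency = pd.DataFrame(
        0,
        index=pd.Index([True, False], name="above_threshold"),
        columns=pd.Index([True, False], name="significant"),
    )
    for _, row in table.iterrows():
        contingency.loc[row["above_threshold"], row["significant"]] += 1
    table.attrs["contingency"] = contingency
    table.attrs["threshold_mbp"] = threshold_mbp
    table.attrs["alpha"] = alpha
    return table


def fusion_index(n_nuclei_in_multinucleated: int, n_total_nuclei: int) -> float:
    """Fraction of nuclei residing in multinucleated (fused) cells."""
    if n_total_nuclei < 1:
        raise InvalidInputError("total nucleus count must be >= 1")
    if not 0 <= n_nuclei_in_multinucleated <= n_total_nuclei:
        raise InvalidInputError(
            f"fused nuclei ({n_nuclei_in_multinucleated}) must lie in "
            f"[0, {n_total_nuclei}]"
        )
    return n_nuclei_in_multinucleated / n_total_nuclei
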