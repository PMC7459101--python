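"""End-to-end orchestration: fixture generation and the analysis pipeline.

``generate_fixture`` writes a complete synthetic study directory
(nuclei.csv, spots.csv, expression.tsv, annotation.bed, genome.tsv,
manifest.json). ``run_pipeline`` consumes such a directory — or real data
in the same schemas — and reproduces the analysis flow of the study:
nuclear morphology, differential expression and per-chromosome activity,
K-factor neighbourhood correlation, radial position distributions and
per-locus comparisons, Feret-normalized locus-centromere distances, and
the genomic mobility-threshold table.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as nio
from .config import RunConfig
from .errors import ConfigError, PipelineOrderError
from .expression import (
    attach_adjusted_p,
    chromosome_activity_table,
    correlate_kgoi_kmean,
    differential_filter,
    intrachromosomal_distance,
    neighborhood_k_mean,
)
from .geometry import NucleusModel, flattening, spot_distance_index
from .simulate import (
    ExpressionSimConfig,
    MB_PRESET,
    MT_PRESET,
    RadialLaw,
    as_rng,
    simulate_expression,
    simulate_nuclei,
    simulate_spots,
)
from .spatial import (
    compare_groups,
    mobility_threshold_analysis,
    pair_gene_centromere,
    radial_distribution_summary,
)

__version__ = "0.1.0"

#: default radial-law scenario: most probes uniform-in-volume in both
#: groups; DPP4 shifts to the periphery in myotubes, MYH2/VCAM1 move from
#: central towards the middle zones (the repositionings the study reports).
DEFAULT_SCENARIO: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "DPP4": ((2.0, 2.0), (5.0, 2.0)),
    "MYH2": ((2.0, 5.0), (2.0, 2.0)),
    "VCAM1": ((2.0, 5.0), (2.0, 2.0)),
}
DEFAULT_LAW = ((2.0, 2.0), (2.0, 2.0))


def generate_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: int = 80,
    spots_per_nucleus: int = 2,
    scenario: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
    expression_config: ExpressionSimConfig | None = None,
    include_centromere_probes: bool = True,
) -> Path:
    """Write a complete synthetic study directory.

    One nucleus population per group (default 80 per group, the study's
    typical per-probe sample size), spots for every locus probe and the
    centromere probe of each panel chromosome, a block-correlated
    expression table over the panel genome with the panel genes embedded at
    their annotated coordinates, and a manifest recording seed and config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rng_nuc, rng_spot, rng_expr = (as_rng(s) for s in ss.spawn(3))

    loci = nio.load_packaged_annotation()
    genome = nio.load_packaged_genome()

    nuclei = simulate_nuclei(n_per_group, MB_PRESET, rng_nuc) + simulate_nuclei(
        n_per_group, MT_PRESET, rng_nuc
    )
    nio.write_nucleus_table(nuclei, out / "nuclei.csv")

    scenario = dict(DEFAULT_SCENARIO if scenario is None else scenario)
    by_group = {
        "Mb": [n for n in nuclei if n.group == "Mb"],
        "Mt": [n for n in nuclei if n.group == "Mt"],
    }
    probes = [loc.probe_id or loc.gene_symbol for loc in loci]
    if include_centromere_probes:
        probes += [f"cen_{ch}" for ch in sorted({loc.chromosome for loc in loci})]
    spots = []
    for probe in probes:
        laws = scenario.get(probe, DEFAULT_LAW)
        for gi, group in enumerate(("Mb", "Mt")):
            law = RadialLaw(*laws[gi])
            spots.extend(
                simulate_spots(by_group[group], probe, law, spots_per_nucleus, rng_spot)
            )
    nio.write_spot_table(spots, out / "spots.csv")

    if expression_config is None:
        expression_config = ExpressionSimConfig(
            n_genes=6000,
            chromosome_lengths_bp={
                ch: int(genome.loc[ch, "length_bp"]) for ch in genome.index
            },
        )
    records = simulate_expression(expression_config, seed=rng_expr)
    records = _embed_panel_genes(records, loci)
    nio.write_expression_table(records, out / "expression.tsv")

    shutil.copy(nio.packaged_data_path("loci_grch38.tsv"), out / "annotation.bed")
    shutil.copy(nio.packaged_data_path("genome_grch38.tsv"), out / "genome.tsv")

    manifest = {
        "seed": seed,
        "n_per_group": n_per_group,
        "spots_per_nucleus": spots_per_nucleus,
        "scenario": {k: list(map(list, v)) for k, v in scenario.items()},
        "expression_config": {
            **asdict(expression_config),
            "chromosome_lengths_bp": dict(expression_config.chromosome_lengths_bp),
        },
        "nucorg_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _embed_panel_genes(records, loci):
    """Relabel the simulated gene nearest each panel locus with its identity.

    Keeps the simulated block structure (the relabelled gene inherits its
    neighbourhood) while guaranteeing every panel gene exists in the
    expression table at its annotated coordinates.
    """
    from dataclasses import replace

    records = list(records)
    used = set()
    for locus in loci:
        best, best_d = None, np.inf
        for i, r in enumerate(records):
            if r.chromosome != locus.chromosome or i in used:
                continue
            d = abs(r.midpoint_bp - locus.midpoint_bp)
            if d < best_d:
                best, best_d = i, d
        if best is None:
            continue
        used.add(best)
        records[best] = replace(
            records[best],
            gene_symbol=locus.gene_symbol,
            probe_id=locus.probe_id or locus.gene_symbol,
            start_bp=locus.gene_start_bp,
            end_bp=locus.gene_end_bp,
        )
    return records


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on a fixture/real-data directory.

    Returns a dict of result tables and summaries; use
    :func:`write_report` to serialize it. Stages run in the study's
    Results order: morphology, expression selection, radial positions,
    locus-centromere distances, mobility-threshold analysis.
    """
    indir = Path(config.input_dir)
    nuclei = nio.read_nucleus_table(indir / "nuclei.csv")
    spots = nio.read_spot_table(indir / "spots.csv")
    records = nio.read_expression_table(indir / "expression.tsv")
    loci = nio.read_annotation(indir / "annotation.bed", indir / "genome.tsv")

    results: dict = {"config": asdict(config)}

    # --- stage: morphology -------------------------------------------------
    by_group: dict[str, list[NucleusModel]] = {}
    for n in nuclei:
        by_group.setdefault(n.group or "unknown", []).append(n)
    if set(by_group) != {"Mb", "Mt"}:
        raise ConfigError(f"expected groups Mb and Mt in nuclei table, got {sorted(by_group)}")
    morph_rows = []
    morph_values = {}
    for group, ns in sorted(by_group.items()):
        vols = np.array([n.volume for n in ns])
        flats = np.array([flattening(n.volume, n.feret) for n in ns])
        morph_values[group] = (vols, flats)
        morph_rows.append(
            {
                "group": group, "n": len(ns),
                "volume_mean_um3": vols.mean(), "volume_sd_um3": vols.std(ddof=1),
                "flattening_mean": flats.mean(), "flattening_sd": flats.std(ddof=1),
                "feret_mean_um": float(np.mean([n.feret for n in ns])),
            }
        )
    morphology = pd.DataFrame(morph_rows)
    vol_cmp = compare_groups(morph_values["Mb"][0], morph_values["Mt"][0], "mann_whitney")
    flat_cmp = compare_groups(morph_values["Mb"][1], morph_values["Mt"][1], "mann_whitney")
    results["morphology"] = morphology
    results["morphology_tests"] = {
        "volume_p": vol_cmp.p_value,
        "flattening_p": flat_cmp.p_value,
        "test": "mann_whitney",
    }

    # --- stage: expression -------------------------------------------------
    if any(r.p_adj is None for r in records):
        if any(r.p_raw is None for r in records):
            raise PipelineOrderError("expression table lacks both p_raw and p_adj")
        records = attach_adjusted_p(records)
    up, down = differential_filter(records, config.fc_threshold, config.alpha_de)
    activity = chromosome_activity_table(up, down)
    results["de_counts"] = {"n_up": len(up), "n_down": len(down),
                            "n_total": len(up) + len(down)}
    results["de_table"] = pd.DataFrame(
        {
            "gene_symbol": [r.gene_symbol for r in up + down],
            "chromosome": [r.chromosome for r in up + down],
            "fold_change": [r.fold_change for r in up + down],
            "p_adj": [r.p_adj for r in up + down],
            "direction": ["up"] * len(up) + ["down"] * len(down),
        }
    )
    results["chromosome_activity"] = pd.DataFrame(
        {
            "chromosome": [a.chromosome for a in activity],
            "n_up": [a.n_up for a in activity],
            "n_down": [a.n_down for a in activity],
            "c_co": [a.c_co for a in activity],
            "group": [a.group for a in activity],
        }
    )

    kf_rows = []
    for locus in loci:
        if not any(r.gene_symbol == locus.gene_symbol for r in records):
            continue
        window = config.per_gene_window_mbp.get(locus.gene_symbol, locus.window_mbp)
        kf = neighborhood_k_mean(
            locus.gene_symbol, records, window,
            include_goi=config.include_goi_in_neighborhood,
        )
        kf_rows.append(
            {
                "gene_symbol": kf.gene_symbol, "k_goi": kf.k_goi,
                "k_mean": kf.k_mean, "window_mbp": kf.window_mbp,
                "n_neighbors": kf.n_neighbors, "defined": kf.defined,
            }
        )
    kfactor = pd.DataFrame(kf_rows)
    results["kfactor"] = kfactor
    defined = kfactor[kfactor["defined"]] if len(kfactor) else kfactor
    if len(defined) >= 4:
        results["kgoi_kmean_correlation"] = correlate_kgoi_kmean(
            list(zip(defined["k_goi"], defined["k_mean"]))
        )
    else:
        results["kgoi_kmean_correlation"] = None

    # --- stage: radial positions -------------------------------------------
    nuc_by_id = {n.nucleus_id: n for n in nuclei}
    idx_rows = []
    for s in spots:
        nuc = nuc_by_id.get(s.nucleus_id)
        if nuc is None:
            raise PipelineOrderError(f"spot {s.spot_id} references unknown nucleus {s.nucleus_id}")
        r = spot_distance_index(
            nuc, s, n_shells=config.n_shells, mode=config.index_mode,
            tol=config.rho_tolerance,
        )
        idx_rows.append(
            {
                "spot_id": s.spot_id, "nucleus_id": s.nucleus_id,
                "probe_id": s.probe_id, "group": nuc.group,
                "radial_ratio": r.radial_ratio, "shell_index": r.shell_index,
                "distance_index": r.normalized_distance_index,
                "index_mode": r.mode,
            }
        )
    radial = pd.DataFrame(idx_rows)
    results["radial_indices"] = radial
    cmp_rows = []
    for probe, sub in radial.groupby("probe_id"):
        a = sub.loc[sub["group"] == "Mb", "distance_index"].to_numpy()
        b = sub.loc[sub["group"] == "Mt", "distance_index"].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        c = compare_groups(a, b, "mann_whitney")
        cmp_rows.append(
            {
                "probe_id": probe, "n_mb": c.n_a, "n_mt": c.n_b,
                "mean_index_mb": c.mean_a, "mean_index_mt": c.mean_b,
                "p_value": c.p_value,
                "significant": c.p_value < config.alpha_spatial,
            }
        )
    results["radial_comparisons"] = pd.DataFrame(cmp_rows)
    results["radial_distributions"] = {
        probe: radial_distribution_summary(sub["distance_index"].tolist(), n_bins=10)
        for probe, sub in radial.groupby("probe_id")
    }

    # --- stage: locus-centromere distances ---------------------------------
    feret_by_nucleus = {n.nucleus_id: n.feret for n in nuclei}
    spots_by_probe: dict[str, list] = {}
    for s in spots:
        spots_by_probe.setdefault(s.probe_id, []).append(s)
    dist_rows = []
    per_locus_results = []
    for locus in loci:
        gene_probe = locus.probe_id or locus.gene_symbol
        cen_probe = f"cen_{locus.chromosome}"
        gene_spots = spots_by_probe.get(gene_probe, [])
        cen_spots = spots_by_probe.get(cen_probe, [])
        if not gene_spots or not cen_spots:
            continue
        pairs = pair_gene_centromere(
            gene_spots, cen_spots, feret_by_nucleus, pairing=config.pairing
        )
        vals = {"Mb": [], "Mt": []}
        for p in pairs:
            g = nuc_by_id[p.nucleus_id].group
            vals[g].append(p.feret_normalized_distance)
        if not vals["Mb"] or not vals["Mt"]:
            continue
        c = compare_groups(vals["Mb"], vals["Mt"], "mann_whitney")
        per_locus_results.append((locus, c))
        dist_rows.append(
            {
                "gene_symbol": locus.gene_symbol, "chromosome": locus.chromosome,
                "n_pairs_mb": c.n_a, "n_pairs_mt": c.n_b,
                "norm_dist_mean_mb": c.mean_a, "norm_dist_sd_mb": c.sd_a,
                "norm_dist_mean_mt": c.mean_b, "norm_dist_sd_mt": c.sd_b,
                "p_value": c.p_value,
            }
        )
    results["distance_comparisons"] = pd.DataFrame(dist_rows)

    # --- stage: mobility threshold -----------------------------------------
    if per_locus_results:
        distances_mbp = {
            loc.gene_symbol: intrachromosomal_distance(loc) for loc, _ in per_locus_results
        }
        mobility = mobility_threshold_analysis(
            per_locus_results, distances_mbp,
            threshold_mbp=config.mobility_threshold_mbp, alpha=config.alpha_spatial,
        )
    else:
        mobility = pd.DataFrame()
    results["mobility_threshold"] = mobility

    results["manifest"] = {
        "nucorg_version": __version__,
        "config": asdict(config),
        "n_nuclei": len(nuclei),
        "n_spots": len(spots),
        "n_expression_records": len(records),
        "index_mode": config.index_mode,
        "pairing": config.pairing,
        "window_default_mbp": config.window_mbp,
    }
    return results


def write_report(results: dict, out_dir: str | Path) -> Path:
    """Serialize pipeline results to TSV tables plus a JSON summary.

    Writing is atomic at directory level: tables land in the target
    directory only after every stage result is available in memory, so a
    failed run never leaves partial output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "morphology": "morphology.tsv",
        "de_table": "de_table.tsv",
        "chromosome_activity": "chromosome_activity.tsv",
        "kfactor": "kfactor.tsv",
        "radial_indices": "radial_indices.tsv",
        "radial_comparisons": "radial_comparisons.tsv",
        "distance_comparisons": "distance_comparisons.tsv",
        "mobility_threshold": "mobility_threshold.tsv",
    }
    for key, fname in tables.items():
        df = results.get(key)
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / fname, sep="\t", index=False)
    summary = {
        "de_counts": results.get("de_counts"),
        "morphology_tests": results.get("morphology_tests"),
        "kgoi_kmean_correlation": results.get("kgoi_kmean_correlation"),
        "manifest": results.get("manifest"),
    }
    if isinstance(results.get("mobility_threshold"), pd.DataFrame) and len(
        results["mobility_threshold"]
    ):
        cont = results["mobility_threshold"].attrs.get("contingency")
        if cont is not None:
            summary["mobility_contingency"] = {
                "above_significant": int(cont.loc[True, True]),
                "above_nonsignificant": int(cont.loc[True, False]),
                "below_significant": int(cont.loc[False, True]),
                "below_nonsignificant": int(cont.loc[False, False]),
            }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out
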