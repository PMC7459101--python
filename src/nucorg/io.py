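"""Table and mask readers/writers for every format the pipeline touches.

All tables are plain text (CSV for microscopy-side tables, TSV for the
genomics-side ones) with case-insensitive headers. Genomic coordinates are
0-based half-open in BED-like inputs and converted exactly once, here at
the I/O boundary. Every writer's output is re-readable by the matching
reader (schema closure).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError
from .expression import ExpressionRecord
from .geometry import NucleusModel, Spot, VoxelMask
from .spatial import LocusAnnotation

NUCLEUS_COLUMNS = [
    "nucleus_id", "group", "center_x_um", "center_y_um", "center_z_um",
    "a_um", "b_um", "c_um",
    "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
]
SPOT_COLUMNS = ["spot_id", "nucleus_id", "probe_id", "x_um", "y_um", "z_um"]
EXPRESSION_COLUMNS = [
    "probe_id", "gene_symbol", "chromosome", "start_bp", "end_bp",
    "mean_log2_mb", "mean_log2_mt", "p_raw",
]


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns: Sequence[str], path: Path | str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, columns: Sequence[str], path: Path | str) -> None:
    for c in columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric value in column {c!r} at data row {bad[0] + 1}"
            )
        df[c] = coerced


# ---------------------------------------------------------------------------
# nuclei


def read_nucleus_table(path: str | Path) -> list[NucleusModel]:
    """Read a nucleus CSV into parametric models.

    Required columns: nucleus_id, group, center_{x,y,z}_um, {a,b,c}_um and
    the row-major orientation r11..r33. Optional volume_um3 / feret_um
    override the parametric values (used for mask-derived nuclei).
    """
    df = _read_table(path, sep=",")
    _require(df, NUCLEUS_COLUMNS, path)
    numeric = [c for c in NUCLEUS_COLUMNS if c not in ("nucleus_id", "group")]
    _numeric(df, numeric, path)
    nuclei = []
    for i, row in df.iterrows():
        axes = np.array([row["a_um"], row["b_um"], row["c_um"]], dtype=float)
        rot = np.array(
            [[row[f"r{r}{c}"] for c in (1, 2, 3)] for r in (1, 2, 3)], dtype=float
        )
        try:
            model = NucleusModel.parametric(
                nucleus_id=str(row["nucleus_id"]),
                center=[row["center_x_um"], row["center_y_um"], row["center_z_um"]],
                semi_axes=axes,
                orientation=rot,
                group=str(row["group"]),
            )
            if "volume_um3" in df.columns and np.isfinite(row.get("volume_um3", np.nan)):
                model = NucleusModel(
                    nucleus_id=model.nucleus_id, center=model.center,
                    semi_axes=model.semi_axes, orientation=model.orientation,
                    volume=float(row["volume_um3"]),
                    feret=float(row["feret_um"]) if "feret_um" in df.columns
                    and np.isfinite(row.get("feret_um", np.nan)) else model.feret,
                    source="mask_fit", group=model.group,
                )
        except Exception as exc:
            raise ParseError(f"{path}: invalid nucleus at data row {i + 1}: {exc}") from exc
        nuclei.append(model)
    return nuclei


def write_nucleus_table(nuclei: Sequence[NucleusModel], path: str | Path) -> None:
    rows = []
    for n in nuclei:
        r = {
            "nucleus_id": n.nucleus_id,
            "group": n.group,
            "center_x_um": n.center[0], "center_y_um": n.center[1],
            "center_z_um": n.center[2],
            "a_um": n.semi_axes[0], "b_um": n.semi_axes[1], "c_um": n.semi_axes[2],
        }
        for i in range(3):
            for j in range(3):
                r[f"r{i+1}{j+1}"] = n.orientation[i, j]
        r["volume_um3"] = n.volume
        r["feret_um"] = n.feret
        rows.append(r)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spots


def read_spot_table(path: str | Path) -> list[Spot]:
    """Read a spot CSV (spot_id, nucleus_id, probe_id, x/y/z_um[, volume_um3])."""
    df = _read_table(path, sep=",")
    _require(df, SPOT_COLUMNS, path)
    _numeric(df, ["x_um", "y_um", "z_um"], path)
    spots = []
    for i, row in df.iterrows():
        try:
            spots.append(
                Spot(
                    spot_id=str(row["spot_id"]),
                    nucleus_id=str(row["nucleus_id"]),
                    probe_id=str(row["probe_id"]),
                    position=[row["x_um"], row["y_um"], row["z_um"]],
                    signal_volume=float(row["volume_um3"])
                    if "volume_um3" in df.columns and np.isfinite(row.get("volume_um3", np.nan))
                    else None,
                )
            )
        except Exception as exc:
            raise ParseError(f"{path}: invalid spot at data row {i + 1}: {exc}") from exc
    return spots


def write_spot_table(spots: Sequence[Spot], path: str | Path) -> None:
    pd.DataFrame(
        {
            "spot_id": [s.spot_id for s in spots],
            "nucleus_id": [s.nucleus_id for s in spots],
            "probe_id": [s.probe_id for s in spots],
            "x_um": [s.position[0] for s in spots],
            "y_um": [s.position[1] for s in spots],
            "z_um": [s.position[2] for s in spots],
            "volume_um3": [s.signal_volume for s in spots],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# expression


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read an expression TSV; p_adj is read if present, else left unset."""
    df = _read_table(path, sep="\t")
    _require(df, EXPRESSION_COLUMNS, path)
    _numeric(df, ["start_bp", "end_bp", "mean_log2_mb", "mean_log2_mt", "p_raw"], path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ExpressionRecord(
                    probe_id=str(row["probe_id"]),
                    gene_symbol=str(row["gene_symbol"]),
                    chromosome=str(row["chromosome"]),
                    start_bp=int(row["start_bp"]),
                    end_bp=int(row["end_bp"]),
                    mean_log2_mb=float(row["mean_log2_mb"]),
                    mean_log2_mt=float(row["mean_log2_mt"]),
                    p_raw=float(row["p_raw"]) if np.isfinite(row["p_raw"]) else None,
                    p_adj=float(row["p_adj"])
                    if "p_adj" in df.columns and np.isfinite(row.get("p_adj", np.nan))
                    else None,
                )
            )
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"{path}: invalid record at data row {i + 1}: {exc}") from exc
    return records


def write_expression_table(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "chromosome": [r.chromosome for r in records],
            "start_bp": [r.start_bp for r in records],
            "end_bp": [r.end_bp for r in records],
            "mean_log2_mb": [r.mean_log2_mb for r in records],
            "mean_log2_mt": [r.mean_log2_mt for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation / genome definition


def read_genome_table(path: str | Path) -> pd.DataFrame:
    """Genome definition TSV: chromosome, length_bp, centromere_bp."""
    df = _read_table(path, sep="\t")
    _require(df, ["chromosome", "length_bp", "centromere_bp"], path)
    _numeric(df, ["length_bp", "centromere_bp"], path)
    return df.set_index("chromosome")


def read_annotation(bed_path: str | Path, genome_path: str | Path) -> list[LocusAnnotation]:
    """Read a BED-like locus TSV joined with a genome definition.

    BED columns (0-based half-open): chromosome, start_bp, end_bp,
    gene_symbol[, window_mbp, probe_id]. Chromosomes must exist in the
    genome definition, which supplies centromere positions.
    """
    df = _read_table(bed_path, sep="\t")
    _require(df, ["chromosome", "start_bp", "end_bp", "gene_symbol"], bed_path)
    _numeric(df, ["start_bp", "end_bp"], bed_path)
    genome = read_genome_table(genome_path)
    loci = []
    for i, row in df.iterrows():
        ch = str(row["chromosome"])
        if ch not in genome.index:
            raise ParseError(
                f"{bed_path}: unknown chromosome {ch!r} at data row {i + 1} "
                f"(not in {genome_path})"
            )
        if row["start_bp"] >= row["end_bp"]:
            raise ParseError(
                f"{bed_path}: start_bp >= end_bp at data row {i + 1} "
                f"({row['start_bp']} >= {row['end_bp']})"
            )
        loci.append(
            LocusAnnotation(
                gene_symbol=str(row["gene_symbol"]),
                chromosome=ch,
                gene_start_bp=int(row["start_bp"]),
                gene_end_bp=int(row["end_bp"]),
                centromere_position_bp=int(genome.loc[ch, "centromere_bp"]),
                probe_id=str(row["probe_id"]) if "probe_id" in df.columns else None,
                window_mbp=float(row["window_mbp"]) if "window_mbp" in df.columns else 1.0,
            )
        )
    return loci


def packaged_data_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(importlib.resources.files("nucorg") / "data" / name)


def load_packaged_annotation() -> list[LocusAnnotation]:
    """The GRCh38 annotation of the study's 12-locus FISH panel."""
    return read_annotation(
        packaged_data_path("loci_grch38.tsv"), packaged_data_path("genome_grch38.tsv")
    )


def load_packaged_genome() -> pd.DataFrame:
    return read_genome_table(packaged_data_path("genome_grch38.tsv"))


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path, spacing: tuple[float, float, float] = (0.13, 0.13, 0.2)) -> VoxelMask:
    """Read a single-nucleus 3D TIFF stack (boolean or 0/255) as a mask."""
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim != 3:
        raise ParseError(f"{path}: expected a 3D stack, got shape {arr.shape}")
    return VoxelMask(array=arr > 0, spacing=spacing)


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), mask.array.astype(np.uint8) * 255)
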