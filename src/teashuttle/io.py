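"""Readers and writers for the pipeline's plain-text exchange formats.

Formats: plate CSV (sample_id, role, concentration, replicate,
absorbance), MFC voltage CSV (condition_id, time_s, voltage_V) with a YAML
metadata sidecar, CV sweep CSV (cycle, direction, voltage_V, current_uA),
expression TSV (genes x samples) with a sample-class CSV, target
prediction CSV, STRING-dialect edge-list TSV, GMT gene-set files, and
plain one-gene-per-line lists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assay import AbsorbancePlate, PLATE_COLUMNS
from .deg import ExpressionStudy
from .electrochem import MFCSeries, Voltammogram
from .enrichment import GeneSetDB


# -- plates ---------------------------------------------------------------

def read_plate(path: str | Path, assay: str) -> AbsorbancePlate:
    wells = pd.read_csv(path)
    return AbsorbancePlate(wells[PLATE_COLUMNS], assay=assay)


def write_plate(plate: AbsorbancePlate, path: str | Path) -> None:
    plate.wells.to_csv(path, index=False)


# -- MFC ------------------------------------------------------------------

def write_mfc(series_list: list[MFCSeries], csv_path: str | Path,
              meta_path: str | Path | None = None) -> None:
    frames = [pd.DataFrame({"condition_id": s.condition_id,
                            "time_s": s.time_s, "voltage_V": s.voltage_v})
              for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {s.condition_id: {
            "external_resistance_ohm": s.external_resistance_ohm,
            "anode_area_m2": s.anode_area_m2} for s in series_list}
        Path(meta_path).write_text(yaml.safe_dump(meta))


def read_mfc(csv_path: str | Path,
             meta_path: str | Path | None = None) -> list[MFCSeries]:
    df = pd.read_csv(csv_path)
    meta = (yaml.safe_load(Path(meta_path).read_text())
            if meta_path is not None else {})
    out = []
    for cond, grp in df.groupby("condition_id", sort=False):
        kwargs = meta.get(cond, {})
        out.append(MFCSeries(str(cond), grp["time_s"].to_numpy(),
                             grp["voltage_V"].to_numpy(), **kwargs))
    return out


# -- CV -------------------------------------------------------------------

def write_voltammogram(vgram: Voltammogram, path: str | Path) -> None:
    rows = []
    for cycle in sorted(vgram.cycles):
        for direction, pts in vgram.cycles[cycle].items():
            for v, i in pts:
                rows.append((cycle, direction, v, i))
    pd.DataFrame(rows, columns=["cycle", "direction", "voltage_V",
                                "current_uA"]).to_csv(path, index=False)


def read_voltammogram(path: str | Path, v_low: float | None = None,
                      v_high: float | None = None) -> Voltammogram:
    df = pd.read_csv(path)
    cycles: dict[int, dict[str, np.ndarray]] = {}
    for (cycle, direction), grp in df.groupby(["cycle", "direction"],
                                              sort=False):
        cycles.setdefault(int(cycle), {})[str(direction)] = \
            grp[["voltage_V", "current_uA"]].to_numpy(float)
    lo = v_low if v_low is not None else float(df["voltage_V"].min())
    hi = v_high if v_high is not None else float(df["voltage_V"].max())
    return Voltammogram(cycles, lo, hi)


# -- expression -----------------------------------------------------------

def write_expression(study: ExpressionStudy, matrix_path: str | Path,
                     classes_path: str | Path) -> None:
    study.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    study.sample_classes.rename("subtype").rename_axis("sample") \
        .to_csv(classes_path)


def read_expression(matrix_path: str | Path, classes_path: str | Path,
                    already_logged: bool = True) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    classes = pd.read_csv(classes_path, index_col="sample")["subtype"]
    return ExpressionStudy(matrix, classes, already_logged)


# -- targets and edges ----------------------------------------------------

def read_target_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_target_predictions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


# -- gene sets ------------------------------------------------------------

def read_gmt(path: str | Path,
             category_map: dict[str, str] | None = None) -> GeneSetDB:
    """GMT rows: term_id <tab> description <tab> gene...

    The GO domain is taken from ``category_map`` (term_id -> BP/CC/MF) or
    parsed from a ``[BP]``-style prefix of the description; it defaults
    to BP.
    """
    terms = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        tid, desc, genes = parts[0], parts[1], set(parts[2:])
        cat = "BP"
        if category_map and tid in category_map:
            cat = category_map[tid]
        elif desc.startswith("[") and "]" in desc:
            cat = desc[1:desc.index("]")]
            desc = desc[desc.index("]") + 1:].strip()
        terms[tid] = (desc, cat, genes)
    return GeneSetDB(terms)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    lines = []
    for tid, (name, cat, genes) in db.terms.items():
        lines.append("\t".join([tid, f"[{cat}] {name}", *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))
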