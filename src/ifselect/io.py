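"""Readers and writers: matrices (CSV/TSV/MTX), gene-id mapping, feature
lists, IFS curves, essential subsets, consensus tables and rules.

Tabular artifacts are CSV, nested ones JSON (sorted keys, fixed float
formatting), so that repeated runs with the same seed produce byte-identical
files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .data import LabeledExpressionMatrix
from .ifs import IFSCurve, IFSRecord
from .metrics import MetricReport
from .ranking import RankedFeatureList
from .rules import Rule
from .selection import ConsensusTable, EssentialSubset

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"
MATRIX_FORMATS = ("csv", "tsv", "mtx")


# ---------------------------------------------------------------------------
# labeled matrices

def write_matrix(matrix: LabeledExpressionMatrix, path, fmt: str = "csv") -> None:
    """Write cells × genes values with labels.

    csv/tsv: one row per cell, header = gene ids, final column = label.
    mtx: MatrixMarket values plus ``<stem>.genes.txt`` / ``<stem>.labels.txt``
    sidecars (one gene id / label per line).
    """
    path = Path(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        matrix.to_frame(LABEL_COLUMN).to_csv(path, sep=sep, index=False)
    elif fmt == "mtx":
        spio.mmwrite(str(path), sp.csr_matrix(matrix.values))
        stem = path.with_suffix("")
        stem.with_suffix(".genes.txt").write_text(
            "\n".join(matrix.gene_ids) + "\n"
        )
        stem.with_suffix(".labels.txt").write_text(
            "\n".join(str(l) for l in matrix.labels) + "\n"
        )
    else:
        raise ValueError(f"unknown matrix format {fmt!r}; valid: {MATRIX_FORMATS}")
    logger.info("write_matrix fmt=%s path=%s shape=%s", fmt, path,
                matrix.values.shape)


def read_matrix(path, fmt: str = "csv") -> LabeledExpressionMatrix:
    """Read a labeled matrix written by :func:`write_matrix`."""
    path = Path(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if LABEL_COLUMN not in df.columns:
            raise ValueError(
                f"{path}: missing required {LABEL_COLUMN!r} column"
            )
        labels = df[LABEL_COLUMN]
        if labels.isna().any():
            rows = (labels[labels.isna()].index + 2).tolist()  # 1-based + header
            raise ValueError(f"{path}: missing label on file row(s) {rows[:5]}")
        expr = df.drop(columns=[LABEL_COLUMN])
        for col in expr.columns:
            coerced = pd.to_numeric(expr[col], errors="coerce")
            if coerced.isna().any() and not expr[col].isna().any():
                row = int(coerced[coerced.isna()].index[0]) + 2
                raise ValueError(
                    f"{path}: non-numeric expression value at file row {row}, "
                    f"column {col!r}"
                )
            expr[col] = coerced
        return LabeledExpressionMatrix(
            values=expr.to_numpy(dtype=float),
            gene_ids=list(expr.columns),
            labels=labels.astype(str).to_numpy(dtype=object),
        )
    if fmt == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        genes_path = stem.with_suffix(".genes.txt")
        labels_path = stem.with_suffix(".labels.txt")
        for sidecar in (genes_path, labels_path):
            if not sidecar.exists():
                raise ValueError(f"{path}: missing sidecar file {sidecar}")
        values = np.asarray(spio.mmread(str(path)).todense(), dtype=float)
        gene_ids = genes_path.read_text().splitlines()
        labels = np.array(labels_path.read_text().splitlines(), dtype=object)
        return LabeledExpressionMatrix(values=values, gene_ids=gene_ids,
                                       labels=labels)
    raise ValueError(f"unknown matrix format {fmt!r}; valid: {MATRIX_FORMATS}")


# ---------------------------------------------------------------------------
# gene id mapping

def read_mapping_table(path) -> dict[str, str]:
    """Two-column (id, symbol) mapping file; tab or comma separated."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",")
        parts = [p.strip() for p in parts]
        if len(parts) != 2 or not all(parts):
            raise ValueError(f"{path}: malformed mapping row at line {lineno}")
        gid, symbol = parts
        if gid in mapping and mapping[gid] != symbol:
            raise ValueError(
                f"{path}: duplicate id {gid!r} mapped to both "
                f"{mapping[gid]!r} and {symbol!r} (line {lineno})"
            )
        mapping[gid] = symbol
    return mapping


def map_gene_ids(ids: list[str], mapping: dict[str, str] | str | Path) -> list[str]:
    """Translate gene ids to symbols; unmapped ids pass through (logged)."""
    if not ids:
        raise ValueError("ids must be nonempty")
    if not isinstance(mapping, dict):
        mapping = read_mapping_table(mapping)
    unmapped = [g for g in ids if g not in mapping]
    if unmapped:
        logger.info("map_gene_ids: %d/%d ids unmapped, passed through "
                    "(first: %s)", len(unmapped), len(ids), unmapped[:3])
    return [mapping.get(g, g) for g in ids]


# ---------------------------------------------------------------------------
# JSON helpers

def _dump_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )


# ---------------------------------------------------------------------------
# feature lists

def write_feature_list(ranked: RankedFeatureList, path) -> None:
    pd.DataFrame(ranked.entries, columns=["gene_id", "score"]).to_csv(
        path, index=False
    )


def read_feature_list(path, ranker_name: str | None = None) -> RankedFeatureList:
    df = pd.read_csv(path)
    name = ranker_name or Path(path).stem
    return RankedFeatureList(
        ranker_name=name,
        entries=[(str(g), float(s)) for g, s in zip(df["gene_id"], df["score"])],
    )


# ---------------------------------------------------------------------------
# IFS curves

def curve_to_frame(curve: IFSCurve) -> pd.DataFrame:
    rows = []
    for rec in curve.records:
        row = {
            "ranker": curve.ranker_name,
            "classifier": curve.classifier_name,
            "k": rec.k,
            "weighted_f1": rec.report.weighted_f1,
            "macro_f1": rec.report.macro_f1,
            "acc": rec.report.acc,
            "mcc": rec.report.mcc,
        }
        for cls, f1 in zip(rec.report.class_names, rec.report.f1_per_class):
            row[f"f1_{cls}"] = f1
        rows.append(row)
    return pd.DataFrame(rows)


def write_curve(curve: IFSCurve, path) -> None:
    curve_to_frame(curve).to_csv(path, index=False, float_format="%.10g")


def read_curve(path) -> IFSCurve:
    df = pd.read_csv(path)
    records = []
    class_cols = [c for c in df.columns if c.startswith("f1_")]
    classes = [c[3:] for c in class_cols]
    for _, row in df.iterrows():
        report = MetricReport(
            weighted_f1=float(row["weighted_f1"]),
            macro_f1=float(row["macro_f1"]),
            acc=float(row["acc"]),
            mcc=float(row["mcc"]),
            class_names=classes,
            f1_per_class=[float(row[c]) for c in class_cols],
        )
        records.append(IFSRecord(
            k=int(row["k"]), classifier_name=str(row["classifier"]),
            report=report,
        ))
    return IFSCurve(
        ranker_name=str(df["ranker"].iloc[0]),
        classifier_name=str(df["classifier"].iloc[0]),
        records=records,
    )


# ---------------------------------------------------------------------------
# essential subsets / consensus / rules

def write_essential_subset(subset: EssentialSubset, path) -> None:
    pd.DataFrame({
        "gene_id": subset.gene_ids,
        "rank": range(1, subset.k + 1),
    }).to_csv(path, index=False)


def essential_subsets_to_json(subsets: list[EssentialSubset]) -> list[dict]:
    return [
        {
            "ranker": s.ranker_name,
            "classifier": s.classifier_name,
            "point_kind": s.point_kind,
            "k": s.k,
            "score": round(s.score, 10),
            "gene_ids": list(s.gene_ids),
        }
        for s in subsets
    ]


def write_consensus(table: ConsensusTable, csv_path, upset_json_path) -> None:
    pd.DataFrame(table.to_records()).to_csv(csv_path, index=False)
    _dump_json(
        {"+".join(combo): n for combo, n in table.upset_cells.items()},
        upset_json_path,
    )


def rules_to_json(rules: list[Rule]) -> list[dict]:
    return [
        {
            "rule_id": i,
            "predicates": [
                {"gene_id": p.gene_id, "operator": p.operator,
                 "threshold": round(p.threshold, 10)}
                for p in r.predicates
            ],
            "predicted_class": r.predicted_class,
            "training_support": r.training_support,
            "purity": round(r.purity, 10),
            "text": str(r),
        }
        for i, r in enumerate(rules)
    ]


def write_rules(rules: list[Rule], json_path, csv_path=None) -> None:
    _dump_json(rules_to_json(rules), json_path)
    if csv_path is not None:
        rows = []
        for i, r in enumerate(rules):
            if not r.predicates:
                rows.append({"rule_id": i, "gene_id": "", "operator": "",
                             "threshold": "", "predicted_class": r.predicted_class})
            for p in r.predicates:
                rows.append({
                    "rule_id": i, "gene_id": p.gene_id, "operator": p.operator,
                    "threshold": p.threshold, "predicted_class": r.predicted_class,
                })
        pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.10g")


def write_json_report(obj: dict, path) -> None:
    _dump_json(obj, path)
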