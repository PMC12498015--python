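"""Readers and writers for the pipeline's plain-text formats.

TSV dialect: tab-separated, UTF-8, header row, ``.`` for undefined
numerics.  Clinical status encoding: 0 = censored/alive, 1 = dead.
GMT: ``set_name<TAB>description<TAB>gene...`` per line.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["ParseError", "read_expression", "write_expression",
           "read_clinical", "write_clinical", "read_classes", "write_classes",
           "read_gmt", "write_gmt", "read_cohort", "write_cohort",
           "write_tsv", "NA_TOKEN"]

NA_TOKEN = "."


class ParseError(ValueError):
    """File-format error carrying path and line context."""

    def __init__(self, path, line: int | None, message: str):
        loc = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


def read_expression(path) -> pd.DataFrame:
    """Gene x sample matrix; first column holds gene ids."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(path, None, f"duplicate gene ids: {dup[:10]}")
    try:
        values = df.replace(NA_TOKEN, "nan").astype(float)
    except ValueError as exc:
        raise ParseError(path, None, f"non-numeric expression value: {exc}")
    values.index.name = "gene"
    return values


def write_expression(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def read_clinical(path) -> pd.DataFrame:
    """Clinical table: patient_id, time_days, status (0/1)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["patient_id", "time_days", "status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.status not in ("0", "1"):
            raise ParseError(path, i,
                             f"status must be 0 or 1, got {row.status!r}")
        try:
            t = float(row.time_days)
        except ValueError:
            raise ParseError(path, i,
                             f"non-numeric time_days {row.time_days!r}")
        if not np.isfinite(t) or t <= 0:
            raise ParseError(path, i, f"time_days must be > 0, got {t}")
        records.append((row.patient_id, t, int(row.status)))
    return pd.DataFrame(records, columns=required)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_classes(path) -> pd.Series:
    """Sample class table: sample_id, class in {tumor, normal}."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "class"]:
        raise ParseError(path, 1,
                         "expected columns: sample_id, class")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row[1] not in ("tumor", "normal"):
            raise ParseError(path, i, f"unknown class {row[1]!r}")
    if df["sample_id"].duplicated().any():
        raise ParseError(path, None, "duplicate sample ids")
    return pd.Series(df["class"].to_numpy(), index=df["sample_id"].to_numpy(),
                     name="class")


def write_classes(sample_class: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": sample_class.index,
                  "class": sample_class.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    path = Path(path)
    collection: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, i,
                                 "GMT line needs name, description, >= 1 gene")
            name = fields[0]
            if name in collection:
                raise ParseError(path, i, f"duplicate set name {name!r}")
            collection[name] = [g for g in fields[2:] if g]
    return collection


def write_gmt(collection: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_cohort(expression_path, clinical_path,
                classes_path=None) -> Cohort:
    expr = read_expression(expression_path)
    clin = read_clinical(clinical_path)
    classes = read_classes(classes_path) if classes_path else None
    return Cohort(expr, clin, classes)


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "clinical": out_dir / "clinical.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    if cohort.sample_class is not None:
        paths["classes"] = out_dir / "classes.tsv"
        write_classes(cohort.sample_class, paths["classes"])
    return paths


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def write_json(payload, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
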