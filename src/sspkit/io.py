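"""Readers and writers for the text formats the pipeline exchanges.

Everything is UTF-8 tab-delimited with "." decimals. Expression matrices are
supported both as plain TSV (gene id column + one column per sample) and as
GCT 1.2 (two preamble lines and a Description column). Floats are written
with 17 significant digits so read(write(m)) reproduces values bit-for-bit.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CALL_CATEGORIES,
    CLINICAL_FEATURES,
    NA_TOKEN,
    SUBTYPES,
    BatchDesign,
    CentroidSet,
    ClinicalRecord,
    ExpressionMatrix,
    GeneSignature,
    SubtypeCall,
    SurvivalRecord,
    ValidationError,
)

FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file; message names the offending line/cell."""


# ---------------------------------------------------------------------------
# expression matrices


def _parse_matrix_rows(
    rows: list[list[str]], path: str, header_line: int
) -> ExpressionMatrix:
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: line {header_line}: header must name at least one sample")
    sample_ids = header[1:]
    gene_ids: list[str] = []
    values: list[list[float]] = []
    for offset, row in enumerate(rows[1:], start=header_line + 1):
        if not row or (len(row) == 1 and not row[0]):
            continue
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {offset}: expected {len(header)} fields, got {len(row)}"
            )
        gene_ids.append(row[0])
        parsed = []
        for j, cell in enumerate(row[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: line {offset}: non-numeric value {cell!r} for gene "
                    f"{row[0]!r}, sample {sample_ids[j]!r}"
                ) from None
        values.append(parsed)
    if not gene_ids:
        raise ParseError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(values, dtype=float))


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or GCT 1.2."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if dialect == "tsv":
        return _parse_matrix_rows(rows, str(path), header_line=1)
    if dialect == "gct":
        if len(rows) < 3 or not rows[0] or not rows[0][0].startswith("#1.2"):
            raise ParseError(f"{path}: line 1: expected GCT version line '#1.2'")
        # rows[1] holds the gene/sample counts; trusted but not required.
        body = rows[2:]
        header = body[0]
        if len(header) < 3 or header[1].lower() != "description":
            raise ParseError(f"{path}: line 3: GCT header must be Name<TAB>Description<TAB>samples")
        stripped = [[header[0]] + header[2:]]
        for row in body[1:]:
            if not row or (len(row) == 1 and not row[0]):
                continue
            stripped.append([row[0]] + row[2:])
        return _parse_matrix_rows(stripped, str(path), header_line=3)
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'gct'")


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if dialect == "gct":
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for g, row in zip(matrix.gene_ids, matrix.values):
                cells = "\t".join(FLOAT_FMT % v for v in row)
                fh.write(f"{g}\tna\t{cells}\n")
        elif dialect == "tsv":
            fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
            for g, row in zip(matrix.gene_ids, matrix.values):
                cells = "\t".join(FLOAT_FMT % v for v in row)
                fh.write(f"{g}\t{cells}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'gct'")


# ---------------------------------------------------------------------------
# typed tables


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return frame


def _check_level(path, sample, feature, value, levels) -> str:
    if value != NA_TOKEN and value not in levels:
        raise ValidationError(
            f"{path}: sample {sample!r}: {feature}={value!r} not in "
            f"{tuple(levels) + (NA_TOKEN,)}"
        )
    return value


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    frame = _read_tsv(path, ["gene_symbol"])
    probe_map = None
    if "probe_id" in frame.columns:
        probe_map = dict(zip(frame["probe_id"], frame["gene_symbol"]))
        symbols = list(dict.fromkeys(frame["gene_symbol"]))
    else:
        symbols = list(frame["gene_symbol"])
    return GeneSignature(name or Path(path).stem, symbols, probe_map)


def read_centroids(path: str | Path, signature_name: str | None = None) -> CentroidSet:
    frame = _read_tsv(path, ["gene_symbol"])
    cols = [c for c in frame.columns if c != "gene_symbol"]
    if tuple(cols) != SUBTYPES:
        raise ValidationError(
            f"{path}: centroid columns must be exactly {list(SUBTYPES)}, got {cols}"
        )
    values = frame[list(SUBTYPES)].astype(float).to_numpy()
    return CentroidSet(signature_name or Path(path).stem, list(frame["gene_symbol"]), values)


def write_centroids(centroids: CentroidSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("gene_symbol\t" + "\t".join(SUBTYPES) + "\n")
        for g, row in zip(centroids.gene_ids, centroids.values):
            fh.write(g + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    frame = _read_tsv(path, ["sample_id"])
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for feature, levels in CLINICAL_FEATURES.items():
            if feature in frame.columns:
                kwargs[feature] = _check_level(
                    path, row["sample_id"], feature, row[feature], levels
                )
        records.append(ClinicalRecord(sample_id=row["sample_id"], **kwargs))
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    features = list(CLINICAL_FEATURES)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("sample_id\t" + "\t".join(features) + "\n")
        for r in records:
            fh.write(r.sample_id + "\t" + "\t".join(getattr(r, f) for f in features) + "\n")


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    frame = _read_tsv(path, ["sample_id", "time", "event"])
    records = []
    for _, row in frame.iterrows():
        try:
            time = float(row["time"])
            event = int(row["event"])
        except ValueError:
            raise ParseError(
                f"{path}: sample {row['sample_id']!r}: non-numeric time/event"
            ) from None
        records.append(SurvivalRecord(row["sample_id"], time, event))
    return records


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{FLOAT_FMT % r.time}\t{r.event}\n")


def read_batches(path: str | Path) -> BatchDesign:
    frame = _read_tsv(path, ["sample_id", "batch"])
    return BatchDesign(dict(zip(frame["sample_id"], frame["batch"])))


def write_batches(design: BatchDesign, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("sample_id\tbatch\n")
        for s, b in design.assignments.items():
            fh.write(f"{s}\t{b}\n")


_CALL_COLUMNS = ["sample_id", "label"] + [f"rho_{s}" for s in SUBTYPES] + [
    "threshold",
    "tie_flag",
]


def read_calls(path: str | Path) -> list[SubtypeCall]:
    frame = _read_tsv(path, _CALL_COLUMNS)
    calls = []
    for _, row in frame.iterrows():
        if row["label"] not in CALL_CATEGORIES:
            raise ValidationError(
                f"{path}: sample {row['sample_id']!r}: unknown label {row['label']!r}; "
                f"allowed {list(CALL_CATEGORIES)}"
            )
        calls.append(
            SubtypeCall(
                sample_id=row["sample_id"],
                label=row["label"],
                correlations=tuple(float(row[f"rho_{s}"]) for s in SUBTYPES),
                threshold=float(row["threshold"]),
                tie_flag=row["tie_flag"] in ("True", "true", "1"),
            )
        )
    return calls


def write_calls(calls: Iterable[SubtypeCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            rhos = "\t".join(FLOAT_FMT % r for r in c.correlations)
            fh.write(
                f"{c.sample_id}\t{c.label}\t{rhos}\t{FLOAT_FMT % c.threshold}\t{c.tie_flag}\n"
            )


_SCHEMAS = {
    "signature": read_signature,
    "centroids": read_centroids,
    "clinical": read_clinical,
    "survival": read_survival,
    "batch": read_batches,
    "calls": read_calls,
}


def read_table(path: str | Path, schema: str):
    """Dispatch to the typed reader for ``schema``."""
    try:
        reader = _SCHEMAS[schema]
    except KeyError:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(_SCHEMAS)}") from None
    return reader(path)
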