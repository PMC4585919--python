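"""Reading and writing the pipeline's plain-text formats.

Expression matrices are TSV with a ``gene_id`` header column followed by one
column per sample; sample labelings are two-column TSV (``sample_id``,
``subtype``) with an optional header; gene panels are one-ID-per-line text
files (see :mod:`sigdistill.panels`).  Write-then-read round-trips reproduce
content exactly (floats are serialized with ``repr`` precision).
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV expression matrix.

    Rejects duplicate gene or sample IDs, ragged rows and non-numeric cells,
    naming the offending line.
    """
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ParseError(f"{path}:1: duplicate sample IDs: {dups}")
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(row)}"
                )
            gene = row[0]
            if gene in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gene!r}")
            seen.add(gene)
            try:
                values = [float(x) for x in row[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            genes.append(gene)
            rows.append(values)
    if not genes:
        raise ParseError(f"{path}: no gene rows")
    return pd.DataFrame(rows, index=genes, columns=sample_ids)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", *expr.columns])
        for gene, row in zip(expr.index, expr.to_numpy()):
            writer.writerow([gene, *(repr(float(v)) for v in row)])


def read_labels(path: str | Path) -> pd.Series:
    """Read a sample -> subtype TSV (two columns; a header row is auto-detected)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, found {len(row)}")
            pairs.append((row[0], row[1]))
    if pairs and pairs[0] == ("sample_id", "subtype"):
        pairs = pairs[1:]
    if not pairs:
        raise ParseError(f"{path}: no label rows")
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample IDs: {dups}")
    return pd.Series([p[1] for p in pairs], index=ids, name="subtype")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "subtype"])
        for sample, subtype in labels.items():
            writer.writerow([sample, subtype])


def check_labels_cover(expr: pd.DataFrame, labels: pd.Series) -> None:
    """Raise if the labeling references samples absent from the matrix."""
    orphans = sorted(set(labels.index) - set(expr.columns))
    if orphans:
        raise ValueError(f"labels reference samples absent from the matrix: {orphans}")


def impute_gene_means(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by their gene's mean across observed samples."""
    return expr.apply(lambda row: row.fillna(row.mean()), axis=1)
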