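"""Annotated expression-study container and tab-delimited I/O.

A study is a genes x samples matrix of log2-scale intensities plus a
per-sample annotation table.  Values are assumed to be already normalized
and log-transformed (fRMA-like output); no transform is applied on read,
and missing values are rejected rather than imputed, since every merging
method downstream is defined on complete log-scale matrices.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "XmergeError",
    "FormatError",
    "ParseError",
    "ConsistencyError",
    "ExpressionStudy",
    "MergedExpressionSet",
    "read_expression_table",
    "write_expression_table",
    "intersect_genes",
    "validate_study",
]

#: number of significant digits used when serializing real values
FLOAT_DIGITS = 12
_FLOAT_FMT = "%.12g"


class XmergeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(XmergeError):
    """Structural problem in an input table (duplicate IDs, bad header)."""


class ParseError(XmergeError):
    """A cell could not be parsed as the expected type."""


class ConsistencyError(XmergeError):
    """Cross-table inconsistency (e.g. sample without annotation record)."""


@dataclass
class ExpressionStudy:
    """One gene-expression study.

    Parameters
    ----------
    study_id
        Identifier of the study (used as the batch label after merging).
    values
        DataFrame of shape (n_genes, n_samples); index = gene IDs,
        columns = sample IDs, entries = finite log2 intensities.
    annotations
        DataFrame indexed by sample ID (same set as ``values.columns``),
        one column per annotation key; values are opaque strings.
    """

    study_id: str
    values: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy(self) -> "ExpressionStudy":
        return ExpressionStudy(self.study_id, self.values.copy(), self.annotations.copy())

    def restrict_genes(self, genes: list[str]) -> "ExpressionStudy":
        """Return a copy restricted (and reordered) to ``genes``."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ConsistencyError(
                f"study {self.study_id!r}: genes not present: {missing[:5]}"
            )
        return ExpressionStudy(self.study_id, self.values.loc[genes].copy(), self.annotations.copy())

    def annotation_column(self, key: str) -> pd.Series:
        if key not in self.annotations.columns:
            raise ConsistencyError(
                f"study {self.study_id!r}: annotation key {key!r} not found "
                f"(available: {list(self.annotations.columns)})"
            )
        return self.annotations[key].reindex(self.values.columns)


@dataclass
class MergedExpressionSet(ExpressionStudy):
    """Concatenation of several studies on their common genes.

    ``annotations[batch_key]`` records each sample's study of origin;
    ``provenance`` records the source study IDs and the merging method.
    """

    batch_key: str = "Study"
    provenance: dict = field(default_factory=dict)

    @property
    def batches(self) -> pd.Series:
        return self.annotation_column(self.batch_key)

    def batch_sample_index(self) -> dict[str, np.ndarray]:
        """Column positions of each batch, in sample order."""
        labels = self.batches.to_numpy()
        return {b: np.flatnonzero(labels == b) for b in pd.unique(labels)}


# ---------------------------------------------------------------------------
# I/O — plain TSV, UTF-8, LF, 12 significant digits.
# Expression table: row 1 "GENE\t<sample>...", one row per gene.
# Annotation table: row 1 "SAMPLE\t<key>...", one row per sample.
# ---------------------------------------------------------------------------


def _read_tsv_header(path) -> list[str]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            return next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None


def _check_unique(ids, what: str, where) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"{where}: duplicate {what} ID {x!r}")
        seen.add(x)


def read_expression_table(path, annotations_path, study_id: str) -> ExpressionStudy:
    """Read one study from an expression TSV and an annotation TSV.

    The expression header row holds the sample IDs; the first column holds
    gene IDs.  Annotation rows are matched to samples by ID (extra
    annotation rows are ignored; a sample missing from the annotation
    table is an error).
    """
    header = _read_tsv_header(path)
    _check_unique(header[1:], "sample", path)
    try:
        expr = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        values = expr.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    _check_unique(values.index, "gene", path)
    values.index = pd.Index([str(g) for g in values.index])
    values.columns = pd.Index([str(s) for s in values.columns])

    annotations = pd.read_csv(annotations_path, sep="\t", index_col=0, dtype=str)
    annotations.index = pd.Index([str(s) for s in annotations.index])
    _check_unique(annotations.index, "sample", annotations_path)

    missing = [s for s in values.columns if s not in annotations.index]
    if missing:
        raise ConsistencyError(
            f"samples missing from annotation table {annotations_path}: {missing}"
        )
    annotations = annotations.loc[list(values.columns)].fillna("")

    study = ExpressionStudy(study_id, values.astype(float), annotations)
    findings = validate_study(study)
    if findings:
        raise FormatError(f"{path}: invalid study: " + "; ".join(findings))
    return study


def write_expression_table(study: ExpressionStudy, path, annotations_path) -> None:
    """Write a study to the TSV dialect that :func:`read_expression_table` reads.

    Reals are serialized with 12 significant digits, so a write/read
    round-trip reproduces values to better than 1e-9 relative error.
    Annotation values containing tabs or newlines are quoted (csv rules).
    """
    if study.n_samples == 0 or study.n_genes == 0:
        raise FormatError("refusing to write an empty study")
    findings = validate_study(study)
    if findings:
        raise FormatError("refusing to write invalid study: " + "; ".join(findings))
    values = study.values.copy()
    values.index.name = "GENE"
    values.to_csv(path, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n", encoding="utf-8")
    ann = study.annotations.copy()
    ann.index.name = "SAMPLE"
    ann.to_csv(annotations_path, sep="\t", lineterminator="\n", encoding="utf-8")


def intersect_genes(studies: list[ExpressionStudy]) -> list[ExpressionStudy]:
    """Restrict every study to the lexicographically sorted common gene set.

    Merging across platforms keeps only the features measured in every
    study; sample data are untouched.  The sort makes downstream merge
    output deterministic regardless of the input row orders.
    """
    if len(studies) < 2:
        raise XmergeError("need at least two studies to intersect")
    common = set(studies[0].genes)
    for s in studies[1:]:
        common &= set(s.genes)
    if not common:
        names = [s.study_id for s in studies]
        raise ConsistencyError(f"no genes are common to studies {names}")
    order = sorted(common)
    return [s.restrict_genes(order) for s in studies]


def validate_study(study: ExpressionStudy) -> list[str]:
    """Check the study invariants; return human-readable findings (empty = valid)."""
    findings: list[str] = []
    genes = list(study.values.index)
    samples = list(study.values.columns)
    if len(set(genes)) != len(genes):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        findings.append(f"duplicate gene IDs: {dup[:5]}")
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        findings.append(f"duplicate sample IDs: {dup[:5]}")
    mat = study.values.to_numpy()
    if mat.size and not np.isfinite(mat.astype(float)).all():
        bad = np.argwhere(~np.isfinite(mat.astype(float)))
        g, s = bad[0]
        findings.append(f"non-finite value at (gene {genes[g]!r}, sample {samples[s]!r})")
    for s in samples:
        if s not in study.annotations.index:
            findings.append(f"sample {s!r} has no annotation record")
    return findings


def study_to_text(study: ExpressionStudy) -> tuple[str, str]:
    """Serialize a study to (expression TSV text, annotation TSV text)."""
    buf_e, buf_a = io.StringIO(), io.StringIO()
    values = study.values.copy()
    values.index.name = "GENE"
    values.to_csv(buf_e, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n")
    ann = study.annotations.copy()
    ann.index.name = "SAMPLE"
    ann.to_csv(buf_a, sep="\t", lineterminator="\n")
    return buf_e.getvalue(), buf_a.getvalue()
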