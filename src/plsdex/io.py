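"""Tabular I/O and axis alignment for the expression-analysis pipeline.

All formats are plain tab-separated UTF-8 text with '.' decimals:

* expression matrix: header row of sample ids, first column probe ids;
* sample labels: two columns ``sample_id``, ``group`` with a header row;
* annotation: four columns ``gene_id``, ``term_id``, ``term_name``,
  ``term_class``;
* edge list: two columns ``gene_a``, ``gene_b`` (undirected).

Matrices are expected on the log2 scale, already normalized (e.g. RMA
output); probe-level normalization is out of scope for this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleLabels",
    "AnnotationMap",
    "EdgeList",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_annotation",
    "write_annotation",
    "read_edges",
    "write_edges",
    "read_gene_map",
    "align",
]


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 expression values.

    ``data`` is a DataFrame with probe ids on the index and sample ids on
    the columns; all values must be finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at probe "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleLabels:
    """Binary disease status per sample (1 = patient, 0 = control)."""

    status: pd.Series  # index: sample ids, values in {0, 1}
    group_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.status.index, "sample")
        vals = set(self.status.astype(int))
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be coded 0/1, got {sorted(vals)}")
        counts = self.status.value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError(
                "both classes must be present with at least 2 samples each; "
                f"got class counts {counts.to_dict()}"
            )
        self.status = self.status.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.index)

    @property
    def y(self) -> np.ndarray:
        return self.status.to_numpy(dtype=float)


@dataclass
class AnnotationMap:
    """Flat gene -> term annotation pairs with term metadata.

    ``table`` columns: gene_id, term_id, term_name, term_class. No
    (gene, term) pair appears twice; every term annotates at least one
    gene by construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene_id", "term_id", "term_name", "term_class"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        dup = self.table.duplicated(subset=["gene_id", "term_id"])
        if dup.any():
            row = self.table[dup].iloc[0]
            raise ValueError(
                f"duplicate annotation pair ({row.gene_id!r}, {row.term_id!r})"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene_id"])

    @property
    def terms(self) -> list[str]:
        return list(pd.unique(self.table["term_id"]))


@dataclass
class EdgeList:
    """Undirected interaction pairs, canonicalized and deduplicated.

    Self-loops are dropped and each pair is stored sorted so that
    duplicated or reversed records collapse to one edge.
    """

    table: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["gene_a", "gene_b"]:
            t = t.iloc[:, :2].set_axis(["gene_a", "gene_b"], axis=1)
        a = t["gene_a"].astype(str)
        b = t["gene_b"].astype(str)
        lo = a.where(a <= b, b)
        hi = b.where(a <= b, a)
        clean = pd.DataFrame({"gene_a": lo, "gene_b": hi})
        clean = clean[clean.gene_a != clean.gene_b]
        clean = clean.drop_duplicates(ignore_index=True)
        self.table = clean

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.table.itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(path: str | Path, impute_missing: bool = False) -> ExpressionMatrix:
    """Read a probes x samples TSV into an :class:`ExpressionMatrix`.

    Row and column order are preserved from the file. Duplicate ids,
    ragged rows and non-numeric cells raise ``ValueError`` with the
    offending coordinates. Missing (empty/NaN) cells are rejected unless
    ``impute_missing`` is set, in which case they are replaced by the
    per-probe mean (logged).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    n_fields = len(header)
    for lineno, ln in enumerate(lines[1:], start=2):
        if len(ln.split("\t")) != n_fields:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(ln.split(chr(9)))} fields, expected {n_fields})"
            )
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    probe_ids = []
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        probe_ids.append(fields[0])
        row = []
        for j, cell in enumerate(fields[1:]):
            if cell == "" or cell.upper() in ("NA", "NAN"):
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at probe "
                    f"{fields[0]!r} (line {lineno}), sample {sample_ids[j]!r}"
                ) from None
        rows.append(row)
    _check_unique(probe_ids, "probe")
    data = pd.DataFrame(rows, index=probe_ids, columns=sample_ids, dtype=float)
    if data.isna().any().any():
        if not impute_missing:
            r, c = np.argwhere(data.isna().to_numpy())[0]
            raise ValueError(
                f"{path}: missing value at probe {data.index[r]!r}, sample "
                f"{data.columns[c]!r} (pass impute_missing=True to mean-impute)"
            )
        n_missing = int(data.isna().to_numpy().sum())
        data = data.apply(lambda row: row.fillna(row.mean()), axis=1)
        logger.info("imputed %d missing values with per-probe means", n_missing)
    return ExpressionMatrix(data)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_labels(
    path: str | Path,
    case_label: str = "patient",
    control_label: str | None = None,
) -> SampleLabels:
    """Read a two-column (sample_id, group) TSV with a header row.

    The group string coded as 1 is named explicitly by ``case_label``;
    it is never inferred from file order or alphabetically. Exactly two
    distinct group tokens must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group)")
    df = df.iloc[:, :2].set_axis(["sample_id", "group"], axis=1)
    groups = list(pd.unique(df["group"]))
    if len(groups) < 2:
        raise ValueError(f"{path}: only one class present ({groups[0]!r})")
    if len(groups) > 2:
        raise ValueError(f"{path}: more than two group tokens: {sorted(groups)}")
    if case_label not in groups:
        raise ValueError(
            f"{path}: case label {case_label!r} not among group tokens {sorted(groups)}"
        )
    other = [g for g in groups if g != case_label][0]
    if control_label is not None and control_label != other:
        raise ValueError(
            f"{path}: unknown group token {other!r} (expected {case_label!r} or {control_label!r})"
        )
    status = df.set_index("sample_id")["group"].map({case_label: 1, other: 0})
    return SampleLabels(status, group_names={1: case_label, 0: other})


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    names = labels.group_names or {1: "patient", 0: "control"}
    df = pd.DataFrame(
        {
            "sample_id": labels.sample_ids,
            "group": [names[int(v)] for v in labels.status],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation(path: str | Path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationMap(df)


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_edges(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return EdgeList(df)


def write_edges(edges: EdgeList, path: str | Path) -> None:
    edges.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe_id, gene_id) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.iloc[:, :2].set_axis(["probe_id", "gene_id"], axis=1)
    return dict(zip(df.probe_id, df.gene_id))


# ---------------------------------------------------------------------------
# alignment


def align(matrix: ExpressionMatrix, labels: SampleLabels) -> tuple[ExpressionMatrix, SampleLabels]:
    """Align a matrix and labels to an identical sample ordering.

    Samples are matched by id, not position; the labels' order wins.
    Matrix samples without a label are dropped with a logged warning.
    """
    matrix_ids = set(matrix.sample_ids)
    keep = [s for s in labels.sample_ids if s in matrix_ids]
    if not keep:
        raise ValueError("no samples shared between matrix and labels")
    missing = [s for s in labels.sample_ids if s not in matrix_ids]
    if missing:
        raise ValueError(f"labels reference samples absent from matrix: {missing}")
    dropped = [s for s in matrix.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("dropping %d unlabeled matrix samples: %s", len(dropped), dropped)
    return (
        ExpressionMatrix(matrix.data.loc[:, keep]),
        SampleLabels(labels.status.loc[keep], group_names=labels.group_names),
    )
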