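"""Reading and writing association edge lists and named matrices.

The central object is :class:`BipartiteAssociations`: a binary matrix ``Y``
with diseases on the rows and microbes on the columns, ``y_ij = 1`` when
disease *i* has a recorded association with microbe *j*.  Edge lists are
two-column delimited text (disease, microbe); named matrices are delimited
text with a header row of column names and a first column of row names.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteAssociations",
    "load_associations",
    "write_associations",
    "read_matrix",
    "write_matrix",
]


def _canon(name: str) -> str:
    """Canonical form used for name matching: trimmed, internal whitespace
    collapsed, case-folded."""
    return " ".join(name.split()).casefold()


@dataclass
class BipartiteAssociations:
    """Named binary disease x microbe association matrix.

    Rows are diseases, columns are microbes; ``Y[i, j] == 1`` iff disease
    ``disease_names[i]`` is associated with microbe ``microbe_names[j]``.
    Names must be unique after trimming and case-folding, and at least two
    entities are required on each side (the similarity kernels are undefined
    otherwise).
    """

    disease_names: list[str]
    microbe_names: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        n, m = self.Y.shape
        if len(self.disease_names) != n or len(self.microbe_names) != m:
            raise ValueError("name lists do not match matrix shape")
        if n < 2 or m < 2:
            raise ValueError("need at least 2 diseases and 2 microbes")
        for label, names in (("disease", self.disease_names),
                             ("microbe", self.microbe_names)):
            canon = [_canon(x) for x in names]
            if len(set(canon)) != len(canon):
                raise ValueError(f"duplicate {label} names after case-folding")
        vals = np.unique(self.Y)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.Y = self.Y.astype(np.int8)

    @property
    def n_diseases(self) -> int:
        return self.Y.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.Y.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.Y.sum())

    def disease_index(self, name: str) -> int:
        try:
            return [_canon(x) for x in self.disease_names].index(_canon(name))
        except ValueError:
            raise KeyError(name) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Y, index=self.disease_names,
                            columns=self.microbe_names)


def _detect_delimiter(line: str, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "\t" if line.count("\t") >= line.count(",") else ","


def load_associations(path, dialect: str | None = None) -> BipartiteAssociations:
    """Read a 2-column disease/microbe edge list into a binary matrix.

    ``y_ij = 1`` iff the pair occurs at least once; duplicate lines collapse.
    Row and column order is first-appearance order.  Lines starting with ``#``
    are comments.  An optional single header line is detected when neither of
    its fields reappears in its own column.
    """
    with open(path, newline="") as fh:
        raw = [(i + 1, ln) for i, ln in enumerate(fh)
               if ln.strip() and not ln.lstrip().startswith("#")]
    if not raw:
        raise ValueError(f"{path}: no associations")
    delim = _detect_delimiter(raw[0][1], dialect)

    rows: list[tuple[int, str, str]] = []
    for lineno, line in raw:
        fields = next(csv.reader(io.StringIO(line), delimiter=delim))
        fields = [f.strip() for f in fields]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(
                f"{path}: line {lineno}: missing disease or microbe field")
        rows.append((lineno, fields[0], fields[1]))

    # Header heuristic: first line's fields never recur in their own column.
    if len(rows) > 1:
        d0, m0 = _canon(rows[0][1]), _canon(rows[0][2])
        d_rest = {_canon(r[1]) for r in rows[1:]}
        m_rest = {_canon(r[2]) for r in rows[1:]}
        if d0 not in d_rest and m0 not in m_rest:
            rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no associations")

    diseases: list[str] = []
    microbes: list[str] = []
    d_idx: dict[str, int] = {}
    m_idx: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    for _, d, m in rows:
        dc, mc = _canon(d), _canon(m)
        if dc not in d_idx:
            d_idx[dc] = len(diseases)
            diseases.append(d)
        if mc not in m_idx:
            m_idx[mc] = len(microbes)
            microbes.append(m)
        pairs.add((d_idx[dc], m_idx[mc]))

    Y = np.zeros((len(diseases), len(microbes)), dtype=np.int8)
    for i, j in pairs:
        Y[i, j] = 1
    return BipartiteAssociations(diseases, microbes, Y)


def write_associations(assoc: BipartiteAssociations, path,
                       dialect: str = "tsv") -> None:
    """Write the association matrix back out as a deduplicated edge list
    (one line per ``y_ij = 1``, row-major order)."""
    delim = "\t" if dialect == "tsv" else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        for i, j in zip(*np.nonzero(assoc.Y)):
            writer.writerow([assoc.disease_names[i], assoc.microbe_names[j]])


def write_matrix(M: pd.DataFrame, path, dialect: str = "tsv") -> None:
    """Write a named matrix as delimited text (header row = column names,
    first column = row names).  Floats use shortest-repr formatting, so a
    read/write round trip is bit-exact."""
    delim = "\t" if dialect == "tsv" else ","
    M.to_csv(path, sep=delim)


def read_matrix(path, dialect: str | None = None,
                square: bool = False) -> pd.DataFrame:
    """Read a named matrix written by :func:`write_matrix`.

    With ``square=True`` (similarity matrices) a non-square matrix, or one
    whose row and column names disagree, is an error.
    """
    with open(path) as fh:
        first = fh.readline()
    delim = _detect_delimiter(first, dialect)
    M = pd.read_csv(path, sep=delim, index_col=0)
    M.index = M.index.astype(str)
    M.columns = M.columns.astype(str)
    if square:
        if M.shape[0] != M.shape[1]:
            raise ValueError(f"{path}: expected a square matrix, "
                             f"got shape {M.shape}")
        if list(M.index) != list(M.columns):
            raise ValueError(f"{path}: row and column names differ")
    return M
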