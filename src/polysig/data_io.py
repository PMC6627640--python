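"""Readers, writers and validated in-memory types for the three table formats.

Every downstream stage of the pipeline operates on the types defined here:

* :class:`ExpressionMatrix` — a gene × sample numeric table carrying a
  ``value_kind`` tag (``counts``, ``logcpm`` or ``zscore``),
* :class:`GeneSetCollection` — an ordered collection of named gene sets
  (the GMT dialect used by MSigDB),
* :class:`ClinicalRecord` — per-patient disease-free-survival time (months)
  and recurrence status.

Gene identifiers are symbols, upper-cased on ingest, so membership tests
between expression rows and gene-set members never fail on case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALUE_KINDS = ("counts", "logcpm", "zscore")

__all__ = [
    "VALUE_KINDS",
    "ParseError",
    "normalize_symbol",
    "ExpressionMatrix",
    "GroupDesign",
    "GeneSet",
    "GeneSetCollection",
    "ClinicalRecord",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "read_design_tsv",
]


class ParseError(ValueError):
    """An on-disk table violates its format contract."""


def normalize_symbol(symbol: str) -> str:
    """Case-normalize a gene symbol (strip whitespace, upper-case).

    Idempotent; applied identically by the expression and GMT readers.
    """
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene × sample numeric table.

    Parameters
    ----------
    data
        DataFrame with gene symbols as index and sample names as columns.
        The index is case-normalized on construction.
    value_kind
        One of ``counts`` (non-negative integers), ``logcpm`` or ``zscore``.
    """

    data: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("degenerate matrix: need at least one gene and one sample")
        data = self.data.copy()
        data.index = pd.Index(
            [normalize_symbol(g) for g in data.index], name="gene"
        )
        data.columns = [str(c) for c in data.columns]
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after case-normalization: {dups[:5]}")
        if len(set(data.columns)) != len(data.columns):
            raise ValueError("duplicate sample names")
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression values: {exc}") from None
        if not np.all(np.isfinite(values)):
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing or non-finite value for gene {data.index[gi]!r} "
                f"sample {data.columns[si]!r}"
            )
        if self.value_kind == "counts":
            if (values < 0).any():
                gi, si = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count for gene {data.index[gi]!r} sample {data.columns[si]!r}"
                )
            if not np.array_equal(values, np.round(values)):
                gi, si = np.argwhere(values != np.round(values))[0]
                raise ValueError(
                    f"non-integral count for gene {data.index[gi]!r} "
                    f"sample {data.columns[si]!r}"
                )
        self.data = data.astype(float)

    # -- accessors ----------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``sample_ids`` (in that order)."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.value_kind)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given genes (case-normalized)."""
        wanted = [normalize_symbol(g) for g in gene_ids]
        missing = [g for g in wanted if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[wanted], self.value_kind)

    def equals(self, other: "ExpressionMatrix") -> bool:
        """Equality as decimal text at 10 significant digits (the on-disk form)."""
        if self.value_kind != other.value_kind:
            return False
        if self.gene_ids != other.gene_ids or self.sample_ids != other.sample_ids:
            return False
        a = np.vectorize(lambda v: format(v, ".10g"))(self.values)
        b = np.vectorize(lambda v: format(v, ".10g"))(other.values)
        return bool(np.array_equal(a, b))


@dataclass
class GroupDesign:
    """Two-group sample assignment for a differential comparison.

    ``reference_group`` is the baseline (e.g. the parental line) and
    ``test_group`` the condition contrasted against it (a resistant clone).
    """

    assignment: dict[str, str]
    reference_group: str
    test_group: str

    def __post_init__(self) -> None:
        if self.reference_group == self.test_group:
            raise ValueError("reference and test group labels must differ")
        labels = set(self.assignment.values())
        expected = {self.reference_group, self.test_group}
        if labels != expected:
            raise ValueError(
                f"assignment uses labels {sorted(labels)}, expected exactly {sorted(expected)}"
            )
        for group in expected:
            n = sum(1 for v in self.assignment.values() if v == group)
            if n < 2:
                raise ValueError(f"group {group!r} has {n} samples; need >= 2")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in self.assignment if s not in matrix.data.columns]
        if missing:
            raise ValueError(f"design samples absent from matrix: {missing}")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with case-normalized, de-duplicated members."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        normalized = frozenset(normalize_symbol(m) for m in self.members if str(m).strip())
        if not normalized:
            raise ValueError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", normalized)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dups}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# Clinical records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalRecord:
    """Disease-free-survival record: time in months, event 1 = recurred."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError(
                f"sample {self.sample_id!r}: time must be finite and positive, got {self.time}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event}"
            )


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

_KIND_COMMENT = "# value_kind="


def read_expression_tsv(path: str | Path, value_kind: str | None = None) -> ExpressionMatrix:
    """Read a tab-delimited gene × sample expression table.

    First column holds gene symbols, the header row sample names.  An
    optional leading ``# value_kind=<kind>`` comment records the value kind;
    the ``value_kind`` argument overrides/supplies it and must agree with the
    comment when both are present.  Duplicate gene symbols are collapsed by
    summation for counts and rejected otherwise.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        comment_kind = None
        if first.startswith("#"):
            stripped = first.strip()
            if stripped.startswith(_KIND_COMMENT.strip("=").split("=")[0]):
                try:
                    comment_kind = stripped.split("=", 1)[1].strip()
                except IndexError:
                    raise ParseError(f"{path}: malformed value_kind comment: {stripped!r}")
            header_line = fh.readline()
        else:
            header_line = first
        if not header_line.strip() or "\t" not in header_line:
            raise ParseError(f"{path}: malformed header (need gene column plus >=1 sample)")
        body = [header_line] + fh.readlines()

    kind = value_kind if value_kind is not None else comment_kind
    if kind is None:
        raise ParseError(f"{path}: value_kind not given and no '# value_kind=' comment")
    if comment_kind is not None and value_kind is not None and comment_kind != value_kind:
        raise ParseError(
            f"{path}: value_kind argument {value_kind!r} conflicts with file comment {comment_kind!r}"
        )
    if kind not in VALUE_KINDS:
        raise ParseError(f"{path}: unknown value_kind {kind!r}")

    from io import StringIO

    raw = pd.read_csv(
        StringIO("".join(body)), sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: malformed header (no sample columns)")
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().to_numpy()
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric value {raw.iloc[gi, si]!r} for gene "
            f"{raw.index[gi]!r} sample {raw.columns[si]!r}"
        )
    num.index = pd.Index([normalize_symbol(g) for g in num.index], name="gene")
    if kind == "counts":
        neg = (num.to_numpy() < 0)
        if neg.any():
            gi, si = np.argwhere(neg)[0]
            raise ParseError(
                f"{path}: negative count for gene {num.index[gi]!r} sample {num.columns[si]!r}"
            )
        if num.index.has_duplicates:
            num = num.groupby(level=0, sort=False).sum()
    elif num.index.has_duplicates:
        dups = num.index[num.index.duplicated()].unique().tolist()
        raise ParseError(
            f"{path}: duplicate gene rows {dups[:5]} not permitted for value_kind={kind}"
        )
    try:
        return ExpressionMatrix(num, kind)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write an expression matrix as TSV with a ``# value_kind=`` header comment.

    Values are written with 10 significant digits (counts as integers), so
    ``read_expression_tsv(write_expression_tsv(m))`` round-trips the decimal
    text exactly.
    """
    path = Path(path)
    is_counts = matrix.value_kind == "counts"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_KIND_COMMENT}{matrix.value_kind}\n")
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            if is_counts:
                cells = [str(int(round(v))) for v in row]
            else:
                cells = [format(v, ".10g") for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")
    return path


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (name TAB description TAB members...)."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; need >= 3"
                )
            name, description, *members = fields
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            members = [m for m in members if m.strip()]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets.append(GeneSet(name, description, frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection as GMT; members sorted lexicographically."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Clinical TSV
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ("sample_id", "dfs_months", "dfs_event")


def read_clinical_tsv(path: str | Path) -> tuple[list[ClinicalRecord], int]:
    """Read a clinical table with columns sample_id, dfs_months, dfs_event.

    Samples missing either the time or the event field are dropped (not
    imputed); the second return value counts the exclusions.  Negative or
    zero times and events outside {0, 1} are errors, not exclusions.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups[:5]}")
    records: list[ClinicalRecord] = []
    n_excluded = 0
    for _, row in df.iterrows():
        time, event = row["dfs_months"], row["dfs_event"]
        if pd.isna(time) or pd.isna(event):
            n_excluded += 1
            continue
        time = float(time)
        event = float(event)
        if not (math.isfinite(time) and time > 0):
            raise ParseError(
                f"{path}: sample {row['sample_id']!r}: dfs_months must be positive, got {time}"
            )
        if event not in (0.0, 1.0):
            raise ParseError(
                f"{path}: sample {row['sample_id']!r}: dfs_event must be 0 or 1, got {event}"
            )
        records.append(ClinicalRecord(str(row["sample_id"]), time, int(event)))
    return records, n_excluded


def write_clinical_tsv(records: Iterable[ClinicalRecord], path: str | Path) -> Path:
    """Write clinical records in the format read_clinical_tsv accepts."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tdfs_months\tdfs_event\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{format(r.time, '.10g')}\t{r.event}\n")
    return path


# ---------------------------------------------------------------------------
# Design TSV (CLI plumbing)
# ---------------------------------------------------------------------------


def read_design_tsv(
    path: str | Path, reference_group: str, test_group: str | None = None
) -> GroupDesign:
    """Read a two-column (sample_id, group) design table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    assignment = dict(zip(df["sample_id"], df["group"]))
    labels = set(assignment.values())
    if test_group is None:
        others = labels - {reference_group}
        if len(others) != 1:
            raise ParseError(
                f"{path}: cannot infer test group from labels {sorted(labels)}"
            )
        test_group = others.pop()
    return GroupDesign(assignment, reference_group, test_group)
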