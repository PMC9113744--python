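"""Readers and writers for every on-disk artifact the pipeline touches.

Canonical count-matrix dialect: genes as rows, first column ``gene_id``,
tab-separated, no quoting (the shape produced by htseq-count style counters).
Gene identifiers are symbols throughout; no automatic translation is applied,
but an optional two-column alias map may be supplied by callers.

Missing values are never permitted inside count matrices.  External per-study
DE summary tables may carry missing log2FC / p entries (published supplements
routinely omit non-significant genes); such rows are retained and flagged
untestable rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("thermatlas")

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_design",
    "read_gmt",
    "write_gmt",
    "read_study_table",
    "write_study_table",
    "read_gene_list",
    "write_gene_list",
]


class FormatError(ValueError):
    """An on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids :
        Unique gene symbols, one per row.
    sample_ids :
        Unique sample identifiers, one per column.
    counts :
        ``(n_genes, n_samples)`` integer array, all entries >= 0.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if np.isnan(counts.astype(float)).any():
                r, c = np.argwhere(np.isnan(counts.astype(float)))[0]
                raise FormatError(
                    f"NaN count at gene {self.gene_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )
            rounded = np.rint(counts.astype(float))
            if not np.array_equal(rounded, counts.astype(float)):
                r, c = np.argwhere(rounded != counts.astype(float))[0]
                raise FormatError(
                    f"non-integer count {counts[r, c]!r} at gene "
                    f"{self.gene_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            r, c = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count {counts[r, c]} at gene "
                f"{self.gene_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {kind} id {i!r}")
                seen.add(i)
        self.counts = counts

    # -- convenience views ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def library_sizes(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids, name="lib_size")

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.counts[:, idx])


def read_counts(path: str | Path, orientation: str = "genes_by_samples") -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket.

    ``path`` ending in ``.mtx`` selects MatrixMarket mode, which expects the
    sidecar files ``<stem>.genes.txt`` and ``<stem>.samples.txt`` next to the
    matrix.  ``orientation`` declares whether rows are genes
    (``genes_by_samples``) or samples (``samples_by_genes``).
    """
    path = Path(path)
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise FormatError(f"unknown orientation {orientation!r}")
    if path.suffix == ".mtx":
        genes_path = path.with_suffix(".genes.txt")
        samples_path = path.with_suffix(".samples.txt")
        for companion in (genes_path, samples_path):
            if not companion.exists():
                raise FileNotFoundError(
                    f"MatrixMarket companion file missing: {companion}"
                )
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = genes_path.read_text().split()
        samples = samples_path.read_text().split()
        if orientation == "samples_by_genes":
            mat = mat.T
        return CountMatrix(genes, samples, np.asarray(mat))

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None:
        raise FormatError(f"{path}: missing header row")
    if orientation == "samples_by_genes":
        df = df.T
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric count {bad.iloc[0]!r} at gene "
                f"{bad.index[0]!r}, sample {col!r}"
            )
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise FormatError(f"{path}: NaN count at gene {gene!r}, sample {col!r}")
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write the canonical TSV dialect (byte-stable; round-trips exactly)."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(cm.sample_ids) + "\n")
        for gene, row in zip(cm.gene_ids, cm.counts):
            fh.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_counts_mtx(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
    # mmwrite appends .mtx if absent; normalise
    if path.suffix != ".mtx":
        path = path.with_suffix(path.suffix + ".mtx")
    path.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
    path.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "tissue", "temperature_c", "pool_size"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s) {missing}")
    df = df[SAMPLE_SHEET_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["tissue"] = df["tissue"].astype(str)
    df["temperature_c"] = df["temperature_c"].astype(float)
    df["pool_size"] = df["pool_size"].astype(int)
    if (df["pool_size"] < 1).any():
        raise FormatError(f"{path}: pool_size must be a positive integer")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet[SAMPLE_SHEET_COLUMNS].copy()
    out["temperature_c"] = out["temperature_c"].map(
        lambda t: format(t, "g")
    )
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(SAMPLE_SHEET_COLUMNS) + "\n")
        for _, row in out.iterrows():
            fh.write("\t".join(str(v) for v in row) + "\n")


def validate_design(cm: CountMatrix, sheet: pd.DataFrame, min_group: int = 2) -> None:
    """Check the sample sheet against its companion count matrix.

    Every sheet sample must exist in the matrix, carry a non-empty library,
    and every tissue x temperature group must have at least ``min_group``
    samples (two are needed for any DE contrast).
    """
    known = set(cm.sample_ids)
    missing = [s for s in sheet["sample_id"] if s not in known]
    if missing:
        raise FormatError(f"sample sheet ids absent from count matrix: {missing}")
    libs = cm.library_sizes()
    empty = [s for s in sheet["sample_id"] if libs[s] == 0]
    if empty:
        raise FormatError(f"zero library size for sample(s): {empty}")
    sizes = sheet.groupby(["tissue", "temperature_c"]).size()
    small = sizes[sizes < min_group]
    if len(small):
        raise FormatError(
            f"groups with fewer than {min_group} samples: {list(small.index)}"
        )


# ---------------------------------------------------------------------------
# Gene sets (GMT) and marker panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Flat term -> member-genes map (no ontology DAG semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def filter_terms(self, predicate: Callable[[GeneSet], bool]) -> "GeneSetCollection":
        return GeneSetCollection({t: s for t, s in self.sets.items() if predicate(s)})

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self:
            out.update(s.genes)
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``term_id TAB description TAB member1 TAB ...``.

    Duplicate members within a line are deduplicated with a logged warning;
    first occurrence order is preserved.
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), needs >= 3"
                )
            term_id, name, *members = fields
            members = [m for m in members if m]
            unique: list[str] = []
            seen: set[str] = set()
            for m in members:
                if m in seen:
                    logger.warning(
                        "GMT %s:%d: duplicate member %r in set %s", path, lineno, m, term_id
                    )
                    continue
                seen.add(m)
                unique.append(m)
            if not unique:
                raise FormatError(f"{path}:{lineno}: set {term_id} has no members")
            if term_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id}")
            sets[term_id] = GeneSet(term_id, name, tuple(unique))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for s in collection:
            fh.write("\t".join([s.term_id, s.name, *s.genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; ``#`` comments and blank lines are ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# External per-study DE summary tables
# ---------------------------------------------------------------------------

STUDY_TABLE_COLUMNS = ["gene", "log2fc", "pvalue"]


def read_study_table(
    path: str | Path, alpha: float = 0.05
) -> pd.DataFrame:
    """Read a per-study DE summary (columns ``gene``, ``log2fc``, ``pvalue``).

    Lines starting with ``#`` before the header are treated as a study
    metadata block and skipped.  Rows with missing log2FC or p are retained
    but flagged ``testable=False``; ``significant`` is ``p < alpha`` among
    testable rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in STUDY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: study table missing column(s) {missing}")
    df = df[STUDY_TABLE_COLUMNS].copy()
    df["gene"] = df["gene"].astype(str)
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
    df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    df["testable"] = df["log2fc"].notna() & df["pvalue"].notna()
    df["significant"] = df["testable"] & (df["pvalue"] < alpha)
    return df


def write_study_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[STUDY_TABLE_COLUMNS]
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
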