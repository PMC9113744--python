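"""Cross-condition and cross-study comparison of regulation direction.

Covers four activities: direction concordance between two contrasts of the
same tissue (e.g. cold-vs-control against warm-vs-control, where genes
tracking the temperature gradient flip sign), construction of biomarker
panels from gene-set annotation plus literature lists, recurrence selection
of markers replicated across published studies, and grouping of gene symbols
into nomenclature families (Elovl1..Elovl7 -> "Elovl").

"Commonly changed" genes between two contrasts are, by default, genes called
significant (up or down) in BOTH; a relaxed mode admits genes significant in
one and merely reported in the other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection
from .normalization_de import DETable

__all__ = [
    "ConcordanceReport",
    "direction_concordance",
    "MarkerPanel",
    "build_marker_panel",
    "StudyComparison",
    "recurrent_markers",
    "cross_study_matrix",
    "gene_family_groups",
]


# ---------------------------------------------------------------------------
# Direction concordance between two contrasts
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    contrast_a: tuple
    contrast_b: tuple
    per_gene: pd.DataFrame  # index gene; log2fc_a, log2fc_b, cls in {same, opposite}

    @property
    def common_genes(self) -> list[str]:
        return list(self.per_gene.index)

    @property
    def n_same(self) -> int:
        return int((self.per_gene["cls"] == "same").sum())

    @property
    def n_opposite(self) -> int:
        return int((self.per_gene["cls"] == "opposite").sum())

    @property
    def pct_opposite(self) -> float:
        n = len(self.per_gene)
        return 100.0 * self.n_opposite / n if n else float("nan")

    @property
    def pct_same(self) -> float:
        n = len(self.per_gene)
        return 100.0 * self.n_same / n if n else float("nan")


def direction_concordance(
    de_a: DETable,
    de_b: DETable,
    require_both_significant: bool = True,
) -> ConcordanceReport:
    """Classify genes common to two contrasts as same- or opposite-direction.

    Common genes are those called DE (up or down) in both tables; with
    ``require_both_significant=False``, genes called in one table and merely
    tested in the other also qualify.  Classification is by log2FC sign
    disagreement; called genes cannot carry a zero log2FC (the fold-change
    threshold excludes it).
    """
    called_a = set(de_a.genes_called("up")) | set(de_a.genes_called("down"))
    called_b = set(de_b.genes_called("up")) | set(de_b.genes_called("down"))
    if require_both_significant:
        common = called_a & called_b
    else:
        common = (called_a & set(de_b.tested_genes())) | (
            called_b & set(de_a.tested_genes())
        )
    common = sorted(common)
    lfc_a = de_a.table.loc[common, "log2fc"]
    lfc_b = de_b.table.loc[common, "log2fc"]
    cls = np.where(np.sign(lfc_a) != np.sign(lfc_b), "opposite", "same")
    per_gene = pd.DataFrame(
        {"log2fc_a": lfc_a, "log2fc_b": lfc_b, "cls": cls}, index=pd.Index(common, name="gene")
    )
    return ConcordanceReport(de_a.contrast, de_b.contrast, per_gene)


# ---------------------------------------------------------------------------
# Marker panels and cross-study recurrence
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """Named gene panel with per-gene provenance (``go_term`` or ``literature``)."""

    name: str
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def __contains__(self, gene: str) -> bool:
        return gene in self.provenance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "provenance": [self.provenance[g] for g in self.genes]}
        )


def build_marker_panel(
    collection: GeneSetCollection,
    term_filter: str | Callable,
    literature_list: Sequence[str] = (),
    name: str = "panel",
) -> MarkerPanel:
    """Union of members of annotation terms matching a filter plus a
    literature list.

    ``term_filter`` is either a case-insensitive substring matched against
    term ids and names (e.g. ``"thermogen"``) or a predicate on
    :class:`GeneSet`.  Literature provenance wins when a gene arrives from
    both sources.
    """
    if callable(term_filter):
        pred = term_filter
    else:
        needle = str(term_filter).lower()

        def pred(s):  # noqa: ANN001 - tiny closure
            return needle in s.term_id.lower() or needle in s.name.lower()

    matched = [s for s in collection if pred(s)]
    if not matched and not literature_list:
        raise ValueError("no terms matched the filter and the literature list is empty")
    provenance: dict[str, str] = {}
    for s in matched:
        for g in s.genes:
            provenance.setdefault(g, "go_term")
    for g in literature_list:
        provenance[g] = "literature"
    return MarkerPanel(name, provenance)


@dataclass
class StudyComparison:
    """Per-study DE summaries in one long table.

    ``long`` has one row per (gene, study) actually reported: columns
    ``gene``, ``study``, ``log2fc``, ``significant``.  A gene a study did
    not report has no row — absence of evidence stays distinct from zero.
    ``metadata`` optionally records per-study conditions (temperatures,
    duration, exposure type).
    """

    long: pd.DataFrame
    metadata: pd.DataFrame | None = None

    @classmethod
    def from_tables(
        cls,
        tables: Mapping[str, pd.DataFrame],
        metadata: pd.DataFrame | None = None,
    ) -> "StudyComparison":
        """Assemble from per-study DataFrames as returned by
        ``io_formats.read_study_table``."""
        frames = []
        for study, df in tables.items():
            sub = df[df["testable"]] if "testable" in df.columns else df
            frames.append(
                pd.DataFrame(
                    {
                        "gene": sub["gene"].astype(str),
                        "study": study,
                        "log2fc": sub["log2fc"].astype(float),
                        "significant": sub["significant"].astype(bool),
                    }
                )
            )
        long = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["gene", "study", "log2fc", "significant"]
        )
        return cls(long, metadata)

    @property
    def studies(self) -> list[str]:
        return sorted(self.long["study"].unique())


def recurrent_markers(
    panel: MarkerPanel, studies: StudyComparison, min_studies: int
) -> MarkerPanel:
    """Sub-panel of genes significantly regulated in >= ``min_studies`` studies.

    Unreported (gene, study) cells never count toward recurrence.
    """
    if min_studies < 1:
        raise ValueError("min_studies must be >= 1")
    sig = studies.long[studies.long["significant"]]
    counts = sig.groupby("gene")["study"].nunique()
    keep = {
        g: prov
        for g, prov in panel.provenance.items()
        if counts.get(g, 0) >= min_studies
    }
    return MarkerPanel(f"{panel.name}_min{min_studies}", keep)


def cross_study_matrix(
    studies: StudyComparison, genes: Sequence[str]
) -> pd.DataFrame:
    """Long (gene, study, log2fc, significant) export for a gene panel.

    One row per reported cell only; omissions stay explicit by absence.
    Row order: gene (input order), then study name.
    """
    order = {g: i for i, g in enumerate(genes)}
    sub = studies.long[studies.long["gene"].isin(order)].copy()
    sub = sub.sort_values(
        ["gene", "study"], key=lambda s: s.map(order) if s.name == "gene" else s
    )
    return sub.reset_index(drop=True)[["gene", "study", "log2fc", "significant"]]


# ---------------------------------------------------------------------------
# Gene-family grouping by nomenclature prefix
# ---------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^([A-Za-z]+)\d")


def gene_family_groups(symbols: Iterable[str]) -> dict[str, list[str]]:
    """Group gene symbols into nomenclature families of size >= 2.

    The family key of a numbered symbol is its maximal leading alphabetic
    prefix before the first digit (case preserved); an unnumbered symbol
    keys on its full name, so ``Ucp`` would join the family of ``Ucp1`` but
    a lone ``Ucp1`` forms no family.  Singleton groups are dropped.
    """
    symbols = list(symbols)
    if not symbols:
        raise ValueError("symbol list is empty")
    groups: dict[str, list[str]] = {}
    for sym in symbols:
        m = _PREFIX_RE.match(sym)
        key = m.group(1) if m else sym
        groups.setdefault(key, []).append(sym)
    return {
        k: sorted(v) for k, v in sorted(groups.items()) if len(v) >= 2
    }
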