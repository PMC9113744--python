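"""Direction-split gene-set over-representation and cross-tissue term logic.

The enrichment engine is classic one-sided Fisher/hypergeometric
over-representation on a flat term -> genes collection: no ontology DAG, no
elim/weight decorrelation.  Tests are run separately for up- and for
down-regulated gene lists, per tissue, with the universe being the genes
tested in that tissue's contrast (not the global union), which keeps
low-complexity tissues from inflating enrichment.

Cross-condition term classes are assigned with the precedence
cross_condition_opposite > cross_condition_same > shared_mixed >
shared_same_direction > tissue_specific, making the classes exhaustive and
mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneSet, GeneSetCollection
from .normalization_de import ContrastSet

__all__ = [
    "fisher_ora",
    "EnrichmentTable",
    "enrich_all",
    "aggregate_term_counts",
    "rank_terms",
    "classify_terms",
    "venn_decomposition",
    "TERM_CLASSES",
]

TERM_CLASSES = (
    "cross_condition_opposite",
    "cross_condition_same",
    "shared_mixed",
    "shared_same_direction",
    "tissue_specific",
)


def fisher_ora(
    de_genes: Iterable[str],
    universe: Iterable[str],
    gene_set: Iterable[str],
) -> tuple[float, float, list[str]]:
    """One-sided hypergeometric over-representation test.

    Returns ``(p_value, gene_ratio, overlap)`` where the gene ratio is
    |DE in set| / |universe in set| and p is the upper-tail probability of
    drawing at least the observed overlap when sampling |DE| genes from the
    universe.  The set is intersected with the universe before testing; an
    empty post-intersection set yields p = 1 and ratio 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("DE genes must be a subset of the universe")
    members = set(gene_set) & universe
    if not members:
        return 1.0, 0.0, []
    overlap = sorted(de & members)
    k = len(overlap)
    p = float(hypergeom.sf(k - 1, len(universe), len(members), len(de)))
    return min(p, 1.0), k / len(members), overlap


@dataclass
class EnrichmentTable:
    """Retained over-representation results per (tissue, direction, term).

    ``table`` columns: tissue, direction, term_id, term_name, p_value,
    n_de_in_set, n_universe_in_set, gene_ratio, genes (semicolon-joined
    DE driver genes).
    """

    table: pd.DataFrame
    p_select: float
    treatment_temp: float | None = None

    def term_counts(self) -> pd.DataFrame:
        """Per-tissue counts of retained up/down terms (study-table shape)."""
        if self.table.empty:
            return pd.DataFrame(columns=["tissue", "n_up_terms", "n_down_terms"])
        pivot = (
            self.table.groupby(["tissue", "direction"])["term_id"]
            .count()
            .unstack(fill_value=0)
        )
        out = pd.DataFrame(
            {
                "tissue": pivot.index,
                "n_up_terms": pivot.get("up", pd.Series(0, index=pivot.index)),
                "n_down_terms": pivot.get("down", pd.Series(0, index=pivot.index)),
            }
        ).reset_index(drop=True)
        return out

    def drivers(self, term_id: str, tissue: str) -> set[str]:
        sub = self.table[
            (self.table["term_id"] == term_id) & (self.table["tissue"] == tissue)
        ]
        out: set[str] = set()
        for g in sub["genes"]:
            if g:
                out.update(g.split(";"))
        return out


def enrich_all(
    contrasts: ContrastSet,
    collection: GeneSetCollection,
    p_select: float = 0.01,
) -> EnrichmentTable:
    """Run the direction-split ORA for every tissue in a contrast family.

    For each tissue, the universe is that tissue's tested genes and the up-
    and down-regulated call lists are tested separately against every term;
    rows with p < ``p_select`` are retained.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    rows = []
    temps = {det.treatment_temp for det in contrasts}
    for det in contrasts:
        universe = set(det.tested_genes())
        if not universe:
            continue
        for direction in ("up", "down"):
            de = set(det.genes_called(direction))
            for s in collection:
                p, ratio, overlap = fisher_ora(de, universe, s.genes)
                if p < p_select:
                    rows.append(
                        (
                            det.tissue,
                            direction,
                            s.term_id,
                            s.name,
                            p,
                            len(overlap),
                            len(set(s.genes) & universe),
                            ratio,
                            ";".join(overlap),
                        )
                    )
    table = pd.DataFrame(
        rows,
        columns=[
            "tissue",
            "direction",
            "term_id",
            "term_name",
            "p_value",
            "n_de_in_set",
            "n_universe_in_set",
            "gene_ratio",
            "genes",
        ],
    )
    temp = temps.pop() if len(temps) == 1 else None
    return EnrichmentTable(table, p_select, temp)


def aggregate_term_counts(term_counts: pd.DataFrame) -> dict[str, int]:
    """Collective up/down retained-term totals from a per-tissue count table.

    Accepts any table with ``n_up_terms`` / ``n_down_terms`` columns; rows
    with missing counts (tissues absent from a condition) contribute zero.
    """
    return {
        "n_up_terms": int(term_counts["n_up_terms"].fillna(0).sum()),
        "n_down_terms": int(term_counts["n_down_terms"].fillna(0).sum()),
    }


def rank_terms(enrichment: EnrichmentTable, top_n: int = 50) -> pd.DataFrame:
    """Order retained terms: ascending p, ties by descending gene ratio,
    then term id; the ``top_n`` head is returned per direction."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    df = enrichment.table.sort_values(
        ["direction", "p_value", "gene_ratio", "term_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return (
        df.groupby("direction", group_keys=False)
        .head(top_n)
        .reset_index(drop=True)
    )


def _term_profile(enr: EnrichmentTable) -> dict[str, dict[str, set[str]]]:
    prof: dict[str, dict[str, set[str]]] = {}
    for _, row in enr.table.iterrows():
        d = prof.setdefault(row["term_id"], {"up": set(), "down": set()})
        d[row["direction"]].add(row["tissue"])
    return prof


def classify_terms(
    enrich_cold: EnrichmentTable, enrich_warm: EnrichmentTable
) -> pd.DataFrame:
    """Classify every retained term by its cross-tissue, cross-condition
    direction profile.

    Output columns: term_id, tissues_up_cold, tissues_down_cold,
    tissues_up_warm, tissues_down_warm (semicolon-joined) and ``cls``.
    A term significant under both conditions is ``cross_condition_opposite``
    if any direction flips between conditions, else
    ``cross_condition_same``; a single-condition term hit in exactly one
    tissue and one direction is ``tissue_specific``; broader
    single-condition terms are ``shared_same_direction`` or
    ``shared_mixed``.
    """
    cold = _term_profile(enrich_cold)
    warm = _term_profile(enrich_warm)
    rows = []
    for term in sorted(set(cold) | set(warm)):
        c = cold.get(term, {"up": set(), "down": set()})
        w = warm.get(term, {"up": set(), "down": set()})
        in_cold = bool(c["up"] or c["down"])
        in_warm = bool(w["up"] or w["down"])
        if in_cold and in_warm:
            flips = (c["up"] and w["down"]) or (c["down"] and w["up"])
            cls = "cross_condition_opposite" if flips else "cross_condition_same"
        else:
            side = c if in_cold else w
            n_hits = len(side["up"]) + len(side["down"])
            if n_hits == 1:
                cls = "tissue_specific"
            elif side["up"] and side["down"]:
                cls = "shared_mixed"
            else:
                cls = "shared_same_direction"
        rows.append(
            (
                term,
                ";".join(sorted(c["up"])),
                ";".join(sorted(c["down"])),
                ";".join(sorted(w["up"])),
                ";".join(sorted(w["down"])),
                cls,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "tissues_up_cold",
            "tissues_down_cold",
            "tissues_up_warm",
            "tissues_down_warm",
            "cls",
        ],
    ).set_index("term_id")


def venn_decomposition(
    term_id: str,
    enrichment: EnrichmentTable,
    tissues: Sequence[str],
) -> dict[tuple[str, ...], list[str]]:
    """Partition a shared term's DE driver genes into Venn compartments.

    Keys are tissue subsets (tuples, in input order); each driver gene lands
    in exactly one compartment — the full subset of tissues whose driver
    list contains it.  The term must be retained (either direction) in at
    least two of the requested tissues.
    """
    drivers = {t: enrichment.drivers(term_id, t) for t in tissues}
    present = [t for t in tissues if drivers[t]]
    if len(present) < 2:
        raise ValueError(
            f"term {term_id!r} retained in {len(present)} of the requested tissues; "
            "need >= 2"
        )
    compartments: dict[tuple[str, ...], list[str]] = {}
    for r in range(len(tissues), 0, -1):
        for subset in combinations(tissues, r):
            inside = set.intersection(*(drivers[t] for t in subset)) if subset else set()
            outside = set().union(
                *(drivers[t] for t in tissues if t not in subset)
            ) if len(subset) < len(tissues) else set()
            compartments[subset] = sorted(inside - outside)
    return compartments
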