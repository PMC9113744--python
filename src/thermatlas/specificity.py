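"""Cross-tissue regulation-breadth and expression-breadth classification.

A gene's DE breadth is the number of tissues where it is called up or down
in a given contrast family, irrespective of direction consistency; breadth 1
defines a tissue-specific profile.  Genes untested in a tissue (removed by
the expression filter there) contribute no call for that tissue — they are
unobserved, not "not DE" — and the per-gene number of tested tissues is
recorded alongside.

Percentages in the per-tissue summary use that tissue's own up (resp. down)
call totals as denominator and are displayed rounded to whole percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .normalization_de import ContrastSet, DETable

__all__ = [
    "de_breadth",
    "SpecificitySummary",
    "specificity_summary",
    "aggregate_specific_counts",
    "BreadthDistribution",
    "expression_breadth",
    "shared_signatures",
    "expression_vs_regulation",
    "percent",
]


def percent(n: float, d: float) -> float:
    """Whole-number percentage ``round(100 * n / d)``; NaN for empty denominators."""
    if d == 0:
        return float("nan")
    return float(round(100.0 * n / d))


def _direction_maps(contrasts: ContrastSet) -> tuple[dict, dict, dict]:
    """Per tissue: sets of up-called, down-called, and tested genes."""
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    tested: dict[str, set[str]] = {}
    for det in contrasts:
        if det.tissue in up:
            raise ValueError(f"duplicate tissue key {det.tissue!r} in contrast set")
        up[det.tissue] = set(det.genes_called("up"))
        down[det.tissue] = set(det.genes_called("down"))
        tested[det.tissue] = set(det.tested_genes())
    return up, down, tested


def de_breadth(contrasts: ContrastSet) -> pd.DataFrame:
    """Per-gene DE breadth and direction map across a contrast family.

    Returns a DataFrame indexed by gene with ``breadth`` (tissues DE in any
    direction), semicolon-joined ``up_tissues`` / ``down_tissues``,
    ``n_tested`` (tissues where the gene was tested), and ``inverse``
    (up somewhere and down elsewhere).  Only genes tested in >= 1 tissue
    appear.
    """
    up, down, tested = _direction_maps(contrasts)
    genes = sorted(set().union(*tested.values())) if tested else []
    tissues = sorted(tested)
    rows = []
    for g in genes:
        ups = [t for t in tissues if g in up[t]]
        downs = [t for t in tissues if g in down[t]]
        rows.append(
            (
                g,
                len(ups) + len(downs),
                ";".join(ups),
                ";".join(downs),
                sum(g in tested[t] for t in tissues),
                bool(ups and downs),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "breadth", "up_tissues", "down_tissues", "n_tested", "inverse"],
    ).set_index("gene")


@dataclass
class SpecificitySummary:
    """Per-gene breadth table plus the per-tissue tissue-specific tally.

    ``per_tissue`` has one row per tissue plus a ``Total`` row; counts are
    genes whose *only* DE tissue is that one (in the given direction), and
    percentages are taken against the tissue's full up/down call totals.
    The totals-row percentages use the number of distinct genes up-
    (resp. down-) regulated anywhere as denominator.
    """

    per_gene: pd.DataFrame
    per_tissue: pd.DataFrame


def specificity_summary(contrasts: ContrastSet) -> SpecificitySummary:
    up, down, _ = _direction_maps(contrasts)
    breadth = de_breadth(contrasts)
    tissues = sorted(up)
    spec = breadth[breadth["breadth"] == 1]
    rows = []
    for t in tissues:
        n_up_total = len(up[t])
        n_down_total = len(down[t])
        spec_up = int(((spec["up_tissues"] == t)).sum())
        spec_down = int(((spec["down_tissues"] == t)).sum())
        rows.append(
            (
                t,
                n_up_total,
                n_down_total,
                spec_up,
                spec_down,
                percent(spec_up, n_up_total),
                percent(spec_down, n_down_total),
            )
        )
    per_tissue = pd.DataFrame(
        rows,
        columns=[
            "tissue",
            "n_up_total",
            "n_down_total",
            "n_specific_up",
            "n_specific_down",
            "pct_specific_up",
            "pct_specific_down",
        ],
    )
    any_up = set().union(*up.values()) if up else set()
    any_down = set().union(*down.values()) if down else set()
    totals = aggregate_specific_counts(per_tissue)
    total_row = pd.DataFrame(
        [
            (
                "Total",
                len(any_up),
                len(any_down),
                totals["n_specific_up"],
                totals["n_specific_down"],
                percent(totals["n_specific_up"], len(any_up)),
                percent(totals["n_specific_down"], len(any_down)),
            )
        ],
        columns=per_tissue.columns,
    )
    per_tissue = pd.concat([per_tissue, total_row], ignore_index=True)
    return SpecificitySummary(breadth, per_tissue)


def aggregate_specific_counts(per_tissue: pd.DataFrame) -> dict[str, int]:
    """Collective totals of per-tissue tissue-specific up/down counts.

    Works on any table with ``n_specific_up`` / ``n_specific_down`` columns
    (a ``Total`` row, if present, is excluded); because tissue-specific sets
    are pairwise disjoint, the totals are plain integer sums.
    """
    body = per_tissue
    if "tissue" in body.columns:
        body = body[body["tissue"] != "Total"]
    return {
        "n_specific_up": int(body["n_specific_up"].sum()),
        "n_specific_down": int(body["n_specific_down"].sum()),
    }


@dataclass
class BreadthDistribution:
    """Histogram over k = number of tissues, plus per-tissue exclusive counts."""

    distribution: pd.Series  # index k, value gene count
    exclusive_by_tissue: pd.Series  # index tissue, value count of k==1 genes

    @property
    def n_genes(self) -> int:
        return int(self.distribution.sum())


def expression_breadth(expressed_flags: pd.DataFrame) -> BreadthDistribution:
    """Distribution of genes over the number of tissues expressing them.

    ``expressed_flags`` is the gene x tissue boolean table from
    ``flag_expressed``; genes expressed nowhere are excluded.  Exclusive
    genes (k = 1) are attributed to their single tissue.
    """
    k = expressed_flags.sum(axis=1)
    k = k[k > 0]
    dist = k.value_counts().sort_index()
    dist.index.name = "n_tissues"
    excl_genes = k.index[k == 1]
    excl = expressed_flags.loc[excl_genes].idxmax(axis=1).value_counts()
    excl = excl.reindex(expressed_flags.columns, fill_value=0)
    excl.index.name = "tissue"
    return BreadthDistribution(dist, excl)


def de_breadth_distribution(breadth: pd.DataFrame) -> pd.Series:
    """Histogram of DE breadth over genes DE in >= 1 tissue."""
    k = breadth.loc[breadth["breadth"] >= 1, "breadth"]
    dist = k.value_counts().sort_index()
    dist.index.name = "n_tissues"
    return dist


def shared_signatures(
    contrasts: ContrastSet, direction: str, min_tissues: int = 2
) -> pd.DataFrame:
    """Genes ordered by how many tissues share a same-direction call.

    Descending by shared-tissue count, ties broken lexicographically by gene
    id (the broadest signatures — e.g. a gene falling in 7 of 11 tissues —
    sort first).
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    up, down, _ = _direction_maps(contrasts)
    calls = up if direction == "up" else down
    tissues = sorted(calls)
    count: dict[str, list[str]] = {}
    for t in tissues:
        for g in calls[t]:
            count.setdefault(g, []).append(t)
    rows = [
        (g, len(ts), ";".join(sorted(ts)))
        for g, ts in count.items()
        if len(ts) >= min_tissues
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "n_tissues", "tissues"]).set_index("gene")


def expression_vs_regulation(
    expressed_flags: pd.DataFrame,
    contrasts: ContrastSet,
    panel: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Contrast where a marker panel is expressed against where it is regulated.

    For each panel gene present in the expression universe: number of tissues
    expressing it, number of tissues calling it DE, and the per-tissue log2FC
    for the DE tissues (``tissue:log2fc`` pairs, semicolon-joined).  Genes
    absent from the universe are returned separately, not fatal.
    """
    universe = set(expressed_flags.index)
    missing = [g for g in panel if g not in universe]
    present = [g for g in panel if g in universe]
    up, down, _ = _direction_maps(contrasts)
    tissues = sorted(up)
    lfc = {
        det.tissue: det.table["log2fc"] for det in contrasts
    }
    rows = []
    for g in present:
        n_expr = int(expressed_flags.loc[g].sum())
        de_tissues = [t for t in tissues if g in up[t] or g in down[t]]
        detail = ";".join(
            f"{t}:{lfc[t].get(g, float('nan')):.3f}" for t in de_tissues
        )
        rows.append((g, n_expr, len(de_tissues), detail))
    table = pd.DataFrame(
        rows, columns=["gene", "n_tissues_expressed", "n_tissues_de", "de_log2fc"]
    ).set_index("gene")
    return table, missing
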