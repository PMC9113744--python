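"""Library-size normalization, expression filtering, NB dispersion estimation,
and an exact conditional test for two-group count comparison.

The differential-expression engine is a negative-binomial exact test in the
edgeR tradition: library sizes are equalized by rescaling counts to their
geometric-mean depth, per-gene group totals are conditioned on, and the
p-value is the summed probability of every split of the conditioned total at
most as probable as the observed one.  At dispersion 0 this reduces exactly
to the conditional binomial (Fisher-style) test.  The common dispersion is
estimated by maximizing the conditional likelihood on equalized pseudo-counts
(qCML), with a method-of-moments fallback.

Default calling thresholds follow the two-group study convention:
|FC| > 1.5 and raw p <= 0.05, no multiple-testing correction (Benjamini-
Hochberg is available via ``adjust="bh"`` and recommended for new analyses).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import ttest_ind

from .io_formats import CountMatrix

logger = logging.getLogger("thermatlas")

__all__ = [
    "compute_cpm",
    "filter_analysis_genes",
    "flag_expressed",
    "equalize_library_sizes",
    "estimate_dispersion",
    "DispersionEstimate",
    "exact_test",
    "t_test_log_cpm",
    "call_de",
    "bh_adjust",
    "DETable",
    "ContrastSet",
    "de_table",
    "contrast_set",
    "FC_THRESHOLD_DEFAULT",
    "P_THRESHOLD_DEFAULT",
]

FC_THRESHOLD_DEFAULT = 1.5
P_THRESHOLD_DEFAULT = 0.05
PRIOR_COUNT = 0.5  # pseudo-count per group protecting log fold changes


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.to_frame()
    return counts


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def compute_cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column rescaled so it sums to 1e6."""
    df = _as_frame(counts)
    libs = df.sum(axis=0)
    zero = libs[libs == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    return df / libs * 1e6


def filter_analysis_genes(
    values: pd.DataFrame,
    group_labels: Mapping[str, Sequence[str]],
    rule: str = "logcpm_positive",
    min_count: int = 5,
) -> pd.Series:
    """Boolean keep-mask over genes for a two-group contrast.

    ``logcpm_positive``: keep genes with CPM > 1 (log-CPM > 0) in at least
    half the samples of *each* compared group; ``values`` must then be a CPM
    matrix.  ``min_raw_counts``: keep genes with >= ``min_count`` raw counts
    in at least one sample of either group; ``values`` must be raw counts.
    """
    if rule == "logcpm_positive":
        keep = pd.Series(True, index=values.index)
        for _, samples in group_labels.items():
            sub = values[list(samples)]
            keep &= (sub > 1).sum(axis=1) >= len(samples) / 2
        return keep
    if rule == "min_raw_counts":
        samples = [s for ss in group_labels.values() for s in ss]
        return (values[samples] >= min_count).any(axis=1)
    raise ValueError(f"unknown filter rule {rule!r}")


def flag_expressed(
    counts: CountMatrix | pd.DataFrame,
    tissue_groups: Mapping[str, Sequence[str]],
    min_count: int = 5,
) -> pd.DataFrame:
    """Gene x tissue table: expressed iff >= ``min_count`` raw counts in at
    least one sample of that tissue."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    df = _as_frame(counts)
    out = {}
    for tissue, samples in tissue_groups.items():
        samples = list(samples)
        if not samples:
            raise ValueError(f"tissue {tissue!r} has zero samples")
        out[tissue] = (df[samples] >= min_count).any(axis=1)
    return pd.DataFrame(out, index=df.index)


def equalize_library_sizes(df: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Rescale every column to the geometric-mean library size.

    Returns the (non-integer) pseudo-count matrix and the common depth.
    """
    libs = df.sum(axis=0).astype(float)
    if (libs == 0).any():
        raise ValueError(f"zero library size for sample {libs.index[libs == 0][0]!r}")
    common = float(np.exp(np.log(libs).mean()))
    return df * (common / libs), common


# ---------------------------------------------------------------------------
# Dispersion estimation (qCML on equalized pseudo-counts)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionEstimate:
    common: float
    method: str  # "qCML" or "moments"

    def __float__(self) -> float:
        return self.common


def _conditional_loglik(phi: float, group_counts: list[np.ndarray]) -> float:
    """Summed NB conditional log-likelihood over genes and groups.

    Each element of ``group_counts`` is a genes x samples array of equalized
    pseudo-counts for one group; conditioning on per-gene group totals
    removes the mean and leaves phi identifiable.
    """
    r = 1.0 / phi
    total = 0.0
    for y in group_counts:
        n = y.shape[1]
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r))
            + np.sum(gammaln(n * r) - gammaln(z + n * r))
            - y.shape[0] * n * gammaln(r)
        )
    return total


def _moments_dispersion(group_counts: list[np.ndarray]) -> float:
    num, den = 0.0, 0.0
    for y in group_counts:
        if y.shape[1] < 2:
            continue
        m = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        ok = m > 0
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    return max(num / den, 0.0) if den > 0 else 0.0


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood (qCML).

    Library sizes are equalized first; genes with zero total in every group
    carry no information and are dropped.  Falls back to a pooled
    method-of-moments estimate (with a logged warning) if the optimizer
    fails.
    """
    df = _as_frame(counts)
    if not any(len(ss) >= 2 for ss in groups.values()):
        raise ValueError("dispersion needs >= 2 samples in some group")
    pseudo, _ = equalize_library_sizes(df)
    gc = []
    for _, samples in groups.items():
        y = pseudo[list(samples)].to_numpy(dtype=float)
        gc.append(y)
    keep = np.zeros(len(df), dtype=bool)
    for y in gc:
        keep |= y.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("all genes have zero counts; dispersion unidentifiable")
    gc = [y[keep] for y in gc]
    try:
        res = minimize_scalar(
            lambda lg: -_conditional_loglik(10.0**lg, gc),
            bounds=(-8.0, 1.0),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if not res.success:
            raise RuntimeError(res.message)
        return DispersionEstimate(float(10.0**res.x), "qCML")
    except Exception as exc:  # pragma: no cover - defensive fallback
        logger.warning("qCML dispersion optimization failed (%s); using moments", exc)
        return DispersionEstimate(_moments_dispersion(gc), "moments")


# ---------------------------------------------------------------------------
# Exact conditional test
# ---------------------------------------------------------------------------

def _conditional_logpmf(t: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(SumA = s | SumA + SumB = t) over s = 0..t for NB group sums.

    SumA ~ NB(size r_a), SumB ~ NB(size r_b) with a common success
    probability; the conditional law is negative-hypergeometric.
    """
    s = np.arange(t + 1, dtype=float)
    return (
        gammaln(s + r_a)
        - gammaln(s + 1.0)
        + gammaln(t - s + r_b)
        - gammaln(t - s + 1.0)
        - (gammaln(t + r_a + r_b) - gammaln(t + 1.0))
        + gammaln(r_a + r_b)
        - gammaln(r_a)
        - gammaln(r_b)
    )


def _binomial_logpmf(t: int, p: float) -> np.ndarray:
    s = np.arange(t + 1, dtype=float)
    return (
        gammaln(t + 1.0)
        - gammaln(s + 1.0)
        - gammaln(t - s + 1.0)
        + s * math.log(p)
        + (t - s) * math.log1p(-p)
    )


_TIE_REL = 1e-10  # probabilities within this relative band count as ties


def _exact_pvalue(s_obs: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional p: total probability of splits no more likely
    than the observed one."""
    if t == 0:
        return 1.0
    if phi < 1e-12:
        logpmf = _binomial_logpmf(t, n_a / (n_a + n_b))
    else:
        logpmf = _conditional_logpmf(t, n_a / phi, n_b / phi)
    pmf = np.exp(logpmf - logpmf.max())
    obs = pmf[s_obs]
    p = pmf[pmf <= obs * (1.0 + _TIE_REL)].sum() / pmf.sum()
    return min(float(p), 1.0)


def exact_test(
    counts: CountMatrix | pd.DataFrame,
    group_control: Sequence[str],
    group_treatment: Sequence[str],
    dispersion: float,
) -> pd.DataFrame:
    """NB exact test of treatment vs control for every gene.

    Counts are equalized to a common library size; per-gene group totals are
    rounded and conditioned on.  Returns a DataFrame indexed by gene with
    ``log2fc`` (treatment over control, prior count 0.5 per group mean),
    ``p_value``, and ``mean_logcpm``.
    """
    group_control = list(group_control)
    group_treatment = list(group_treatment)
    if set(group_control) & set(group_treatment):
        raise ValueError("control and treatment groups overlap")
    if not group_control or not group_treatment:
        raise ValueError("both groups must be non-empty")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    df = _as_frame(counts)[group_control + group_treatment]
    pseudo, common = equalize_library_sizes(df)
    n_a, n_b = len(group_control), len(group_treatment)
    sum_a = np.rint(pseudo[group_control].sum(axis=1).to_numpy()).astype(np.int64)
    sum_b = np.rint(pseudo[group_treatment].sum(axis=1).to_numpy()).astype(np.int64)

    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    log2fc = np.log2(mean_b + PRIOR_COUNT) - np.log2(mean_a + PRIOR_COUNT)
    mean_cpm = (sum_a + sum_b) / (n_a + n_b) / common * 1e6
    mean_logcpm = np.log2(mean_cpm + 1.0)

    pvals = np.ones(len(df))
    for i, (sa, sb) in enumerate(zip(sum_a, sum_b)):
        pvals[i] = _exact_pvalue(int(sa), int(sa + sb), n_a, n_b, dispersion)

    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "mean_logcpm": mean_logcpm},
        index=df.index,
    )


def t_test_log_cpm(
    counts: CountMatrix | pd.DataFrame,
    group_control: Sequence[str],
    group_treatment: Sequence[str],
) -> pd.DataFrame:
    """Secondary method: two-tailed unpaired t-test on log2(CPM + 1).

    Provided for completeness; the exact test is the default DE engine.
    """
    cpm = compute_cpm(counts)
    log_a = np.log2(cpm[list(group_control)] + 1.0)
    log_b = np.log2(cpm[list(group_treatment)] + 1.0)
    stat = ttest_ind(log_b, log_a, axis=1)
    return pd.DataFrame(
        {
            "log2fc": log_b.mean(axis=1) - log_a.mean(axis=1),
            "p_value": stat.pvalue,
        },
        index=cpm.index,
    )


# ---------------------------------------------------------------------------
# Calling and contrast containers
# ---------------------------------------------------------------------------

def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through untouched."""
    from statsmodels.stats.multitest import multipletests

    ok = p.notna()
    q = pd.Series(np.nan, index=p.index)
    if ok.any():
        q[ok] = multipletests(p[ok].to_numpy(dtype=float), method="fdr_bh")[1]
    return q


def call_de(
    table: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    adjust: str = "none",
) -> pd.DataFrame:
    """Assign up/down/ns/untested calls given fold-change and p thresholds.

    ``adjust="bh"`` compares Benjamini-Hochberg adjusted p-values against
    ``p_threshold`` instead of raw p.  Genes with missing p (removed by the
    expression filter) are called ``untested``.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjust mode {adjust!r}")
    out = table.copy()
    out["p_adj"] = bh_adjust(out["p_value"])
    crit_p = out["p_adj"] if adjust == "bh" else out["p_value"]
    lfc_cut = math.log2(fc_threshold)
    call = pd.Series("ns", index=out.index, dtype=object)
    tested = out["p_value"].notna()
    call[~tested] = "untested"
    sig = tested & (crit_p <= p_threshold)
    call[sig & (out["log2fc"] >= lfc_cut)] = "up"
    call[sig & (out["log2fc"] <= -lfc_cut)] = "down"
    out["call"] = call
    return out


@dataclass
class DETable:
    """Per-gene DE results for one tissue x temperature contrast."""

    tissue: str
    treatment_temp: float
    control_temp: float
    table: pd.DataFrame  # index gene; log2fc, p_value, p_adj, mean_logcpm, call
    dispersion: float | None = None

    @property
    def contrast(self) -> tuple[str, float, float]:
        return (self.tissue, self.treatment_temp, self.control_temp)

    def genes_called(self, direction: str) -> pd.Index:
        return self.table.index[self.table["call"] == direction]

    def tested_genes(self) -> pd.Index:
        return self.table.index[self.table["call"] != "untested"]

    def summary(self) -> dict[str, int]:
        vc = self.table["call"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns", "untested")}


@dataclass
class ContrastSet:
    """Keyed collection of DETables sharing one control temperature."""

    tables: dict[tuple[str, float], DETable] = field(default_factory=dict)

    def add(self, det: DETable) -> None:
        key = (det.tissue, det.treatment_temp)
        if key in self.tables:
            raise ValueError(f"duplicate contrast key {key}")
        if self.tables:
            ctrl = next(iter(self.tables.values())).control_temp
            if det.control_temp != ctrl:
                raise ValueError(
                    f"control temperature {det.control_temp} != family control {ctrl}"
                )
        self.tables[key] = det

    def __iter__(self):
        return iter(self.tables.values())

    def __len__(self) -> int:
        return len(self.tables)

    def subset(self, treatment_temp: float) -> "ContrastSet":
        cs = ContrastSet()
        for det in self:
            if det.treatment_temp == treatment_temp:
                cs.add(det)
        return cs

    def tissues(self) -> list[str]:
        return sorted({t for t, _ in self.tables})

    def get(self, tissue: str, treatment_temp: float) -> DETable:
        return self.tables[(tissue, treatment_temp)]


def de_table(
    counts: CountMatrix | pd.DataFrame,
    sheet: pd.DataFrame,
    tissue: str,
    treatment_temp: float,
    control_temp: float = 22.0,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    adjust: str = "none",
    filter_rule: str = "logcpm_positive",
    dispersion: float | None = None,
) -> DETable:
    """Run the full per-tissue two-group DE workflow and return a DETable.

    Genes failing the expression filter appear with call ``untested`` and
    missing statistics; the dispersion is estimated from this contrast's own
    samples unless supplied.
    """
    df = _as_frame(counts)
    sub = sheet[sheet["tissue"] == tissue]
    ctrl = list(sub.loc[sub["temperature_c"] == float(control_temp), "sample_id"])
    treat = list(sub.loc[sub["temperature_c"] == float(treatment_temp), "sample_id"])
    if len(ctrl) < 2 or len(treat) < 2:
        raise ValueError(
            f"{tissue}: need >= 2 samples per group "
            f"(control {len(ctrl)}, treatment {len(treat)})"
        )
    groups = {"control": ctrl, "treatment": treat}
    cols = ctrl + treat
    if filter_rule == "min_raw_counts":
        keep = filter_analysis_genes(df[cols], groups, rule="min_raw_counts")
    else:
        keep = filter_analysis_genes(compute_cpm(df[cols]), groups, rule=filter_rule)
    kept = df.loc[keep, cols]
    if dispersion is None:
        dispersion = estimate_dispersion(kept, groups).common
    res = exact_test(kept, ctrl, treat, dispersion)
    full = res.reindex(df.index)
    full = call_de(full, fc_threshold, p_threshold, adjust)
    return DETable(tissue, float(treatment_temp), float(control_temp), full, dispersion)


def contrast_set(
    counts: CountMatrix | pd.DataFrame,
    sheet: pd.DataFrame,
    treatment_temp: float,
    control_temp: float = 22.0,
    tissues: Iterable[str] | None = None,
    **kwargs,
) -> ContrastSet:
    """Build the per-tissue DETable family for one treatment temperature."""
    if tissues is None:
        has_treat = sheet.loc[
            sheet["temperature_c"] == float(treatment_temp), "tissue"
        ].unique()
        has_ctrl = sheet.loc[
            sheet["temperature_c"] == float(control_temp), "tissue"
        ].unique()
        tissues = sorted(set(has_treat) & set(has_ctrl))
    cs = ContrastSet()
    for tissue in tissues:
        cs.add(
            de_table(counts, sheet, tissue, treatment_temp, control_temp, **kwargs)
        )
    return cs
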