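"""Normality-gated comparisons, effect sizes and report tables.

Noise robustness is assessed per feature by a paired comparison of the
original and noisy values of the same 68 segments: Shapiro–Wilk on the
paired differences decides between the paired t-test (with Cohen's d)
and the Wilcoxon signed-rank test (with Cliff's delta).  The nausea
effect uses the unpaired analogue: per-group Shapiro–Wilk, then Welch's
t (fractional df) or the Mann–Whitney U test.  Categorical entropy
features get a Pearson chi-square with a Monte-Carlo p under fixed
margins.  No multiple-testing correction is applied by default; a Holm
option exists.

Conventions: the signed-rank statistic V is the sum of ranks of the
positive differences (zeros discarded); the U statistic counts pairs
where the first group exceeds the second (+½ per tie); the Monte-Carlo
p uses the (1 + exceedances)/(n_sim + 1) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .io import FEATURE_COLUMNS

__all__ = [
    "StatResult",
    "paired_compare",
    "unpaired_compare",
    "cliffs_delta",
    "cohens_d_paired",
    "cohens_d_pooled",
    "chi_square_sim",
    "interpret_effect",
    "holm_adjust",
    "robustness_report",
    "nausea_report",
    "categorical_report",
]


@dataclass
class StatResult:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p: float
    effect_type: str | None = None
    effect_value: float | None = None
    df: float | None = None
    normality_p: tuple[float, ...] = ()
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "effect_type": self.effect_type,
            "effect_value": self.effect_value,
            "significant": self.significant,
        }


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Exact Cliff's delta: (#{x_i > y_j} − #{x_i < y_j}) / (|x|·|y|)."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    gt = np.count_nonzero(x > y)
    lt = np.count_nonzero(x < y)
    return (gt - lt) / (x.size * y.size)


def cohens_d_paired(diffs: np.ndarray) -> float:
    """mean(diffs) / SD(diffs) with the n−1 denominator."""
    diffs = np.asarray(diffs, dtype=float)
    sd = np.std(diffs, ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation of differences")
    return float(np.mean(diffs) / sd)


def cohens_d_pooled(g0: np.ndarray, g1: np.ndarray) -> float:
    """(mean0 − mean1) / pooled SD (n−1 variances)."""
    g0 = np.asarray(g0, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    n0, n1 = g0.size, g1.size
    pooled = np.sqrt(
        ((n0 - 1) * np.var(g0, ddof=1) + (n1 - 1) * np.var(g1, ddof=1)) / (n0 + n1 - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((g0.mean() - g1.mean()) / pooled)


def _wilcoxon_v(diffs: np.ndarray) -> float:
    """R-style V: sum of ranks of positive differences over nonzero |d|."""
    d = diffs[diffs != 0]
    ranks = sst.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def paired_compare(orig: np.ndarray, noisy: np.ndarray, alpha: float = 0.05) -> StatResult:
    """Normality-gated paired comparison (original vs noisy values).

    Shapiro–Wilk on the paired differences: normal → paired t + Cohen's d;
    otherwise Wilcoxon signed-rank (statistic V) + Cliff's delta between
    the two samples.  All-zero differences return a degenerate result
    with p = 1.
    """
    orig = np.asarray(orig, dtype=float)
    noisy = np.asarray(noisy, dtype=float)
    if orig.shape != noisy.shape or orig.size < 3:
        raise ValueError("need equal-length paired samples of size >= 3")
    d = orig - noisy
    if np.all(d == 0):
        return StatResult("paired_t", 0.0, 1.0, "cohens_d", 0.0,
                          alpha=alpha, degenerate=True)
    if np.ptp(d) == 0:
        # constant nonzero shift: normality/SD undefined, rank test applies
        w = sst.wilcoxon(orig, noisy, zero_method="wilcox")
        return StatResult("wilcoxon_signed_rank", _wilcoxon_v(d), float(w.pvalue),
                          "cliffs_delta", cliffs_delta(orig, noisy), alpha=alpha)
    sw_p = float(sst.shapiro(d).pvalue)
    if sw_p > alpha:
        t = sst.ttest_rel(orig, noisy)
        return StatResult("paired_t", float(t.statistic), float(t.pvalue),
                          "cohens_d", cohens_d_paired(d), df=float(orig.size - 1),
                          normality_p=(sw_p,), alpha=alpha)
    w = sst.wilcoxon(orig, noisy, zero_method="wilcox")
    return StatResult("wilcoxon_signed_rank", _wilcoxon_v(d), float(w.pvalue),
                      "cliffs_delta", cliffs_delta(orig, noisy),
                      normality_p=(sw_p,), alpha=alpha)


def unpaired_compare(g0: np.ndarray, g1: np.ndarray, alpha: float = 0.05) -> StatResult:
    """Normality-gated two-group comparison.

    Per-group Shapiro–Wilk: both normal → Welch t (fractional df) with
    pooled-SD Cohen's d; otherwise Mann–Whitney U (statistic W = pairs
    with g0 > g1, +½ ties) with Cliff's delta.
    """
    g0 = np.asarray(g0, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    if g0.size < 2 or g1.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(g0) == 0 or np.ptp(g1) == 0:
        # constant group: normality undefined, rank test applies
        u = sst.mannwhitneyu(g0, g1, alternative="two-sided")
        return StatResult("mann_whitney_u", float(u.statistic), float(u.pvalue),
                          "cliffs_delta", cliffs_delta(g0, g1), alpha=alpha)
    sw = (float(sst.shapiro(g0).pvalue), float(sst.shapiro(g1).pvalue))
    if min(sw) > alpha:
        t = sst.ttest_ind(g0, g1, equal_var=False)
        return StatResult("welch_t", float(t.statistic), float(t.pvalue),
                          "cohens_d", cohens_d_pooled(g0, g1), df=float(t.df),
                          normality_p=sw, alpha=alpha)
    u = sst.mannwhitneyu(g0, g1, alternative="two-sided")
    return StatResult("mann_whitney_u", float(u.statistic), float(u.pvalue),
                      "cliffs_delta", cliffs_delta(g0, g1),
                      normality_p=sw, alpha=alpha)


def _pearson_chi2(obs: np.ndarray) -> float:
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def chi_square_sim(
    table: np.ndarray, n_sim: int = 2000, seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> StatResult:
    """Pearson chi-square with a Monte-Carlo p under fixed margins.

    Tables are sampled by Patefield's algorithm; the p-value is
    (1 + #{simulated χ² ≥ observed}) / (n_sim + 1), never exactly zero.
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("contingency table must hold non-negative integers")
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("contingency table has a zero margin")
    stat = _pearson_chi2(obs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sims = sst.random_table(row.astype(int), col.astype(int)).rvs(
        n_sim, method="patefield", random_state=rng
    )
    sim_stats = np.array([_pearson_chi2(s) for s in sims])
    p = (1 + np.count_nonzero(sim_stats >= stat - 1e-12)) / (n_sim + 1)
    return StatResult("chi_square_sim", stat, float(p), alpha=alpha)


_D_BANDS = (0.2, 0.5, 0.8)
_DELTA_BANDS = (0.147, 0.33, 0.474)


def interpret_effect(value: float, effect_type: str, style: str = "standard") -> str:
    """Magnitude label for an effect size.

    Cohen's d bands |d| ≥ 0.2/0.5/0.8 → small/medium/large.  Cliff's
    delta uses the conventional 0.147/0.33/0.474 cut-points, or the same
    0.2/0.5/0.8 bands under ``style='paper'``.  Boundaries are inclusive
    upward.
    """
    if effect_type == "cohens_d" or style == "paper":
        bands = _D_BANDS
    elif effect_type == "cliffs_delta":
        bands = _DELTA_BANDS
    else:
        raise ValueError(f"unknown effect type {effect_type!r}")
    v = abs(value)
    if v >= bands[2]:
        return "large"
    if v >= bands[1]:
        return "medium"
    if v >= bands[0]:
        return "small"
    return "negligible"


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in the reports)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (p.size - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _sorted_rows(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(["subject_id", "condition"]).reset_index(drop=True)


def robustness_report(
    original: pd.DataFrame, noisy_tables: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Paired original-vs-noisy comparison per (feature, SNR condition).

    Rows are aligned by (subject_id, condition); a cell is flagged
    ``robust`` when the noise leaves the feature statistically unchanged
    (p > alpha).
    """
    orig = _sorted_rows(original)
    rows = []
    for tag, noisy in noisy_tables.items():
        noisy = _sorted_rows(noisy)
        if not (orig["subject_id"].equals(noisy["subject_id"])
                and orig["condition"].equals(noisy["condition"])):
            raise ValueError(f"row keys of table {tag!r} do not match the original table")
        for feat in FEATURE_COLUMNS:
            res = paired_compare(orig[feat].to_numpy(), noisy[feat].to_numpy(), alpha)
            rows.append({"feature": feat, "snr_tag": tag, **res.to_dict(),
                         "robust": not res.significant})
    return pd.DataFrame(rows)


def nausea_report(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Unpaired nausea-vs-regular comparison per feature.

    Group 0 is the non-nausea segments, group 1 the nausea segments, so
    a negative Cliff's delta means larger values under nausea.
    """
    g0 = table[table["nausea"] == 0]
    g1 = table[table["nausea"] == 1]
    rows = []
    for feat in FEATURE_COLUMNS:
        res = unpaired_compare(g0[feat].to_numpy(), g1[feat].to_numpy(), alpha)
        rows.append({
            "feature": feat, **res.to_dict(),
            "effect_magnitude": interpret_effect(res.effect_value, res.effect_type),
        })
    return pd.DataFrame(rows)


def categorical_report(
    table: pd.DataFrame, threshold: float = 10.0, n_sim: int = 2000,
    seed: int = 0, alpha: float = 0.05,
) -> pd.DataFrame:
    """Low/high proportions of the categorical time-domain entropies plus
    the simulated-p chi-square association with nausea.

    For each SampEntT feature, values are split at ``threshold``; the
    report gives the low/high proportions within the nausea and regular
    groups and the chi-square test on the 2×2 nausea × level table.
    """
    rows = []
    for i, feat in enumerate(("SampEntT_m2", "SampEntT_m3", "SampEntT_m4")):
        low = (table[feat] < threshold).to_numpy()
        nausea = (table["nausea"] == 1).to_numpy()
        counts = np.array([
            [np.sum(nausea & low), np.sum(nausea & ~low)],
            [np.sum(~nausea & low), np.sum(~nausea & ~low)],
        ])
        row = {
            "feature": feat,
            "nausea_low": counts[0, 0] / max(counts[0].sum(), 1),
            "nausea_high": counts[0, 1] / max(counts[0].sum(), 1),
            "regular_low": counts[1, 0] / max(counts[1].sum(), 1),
            "regular_high": counts[1, 1] / max(counts[1].sum(), 1),
        }
        try:
            res = chi_square_sim(counts, n_sim=n_sim, seed=seed + i, alpha=alpha)
            row.update(chi2=res.statistic, p=res.p, significant=res.significant)
        except ValueError:  # all segments on one side of the split
            row.update(chi2=np.nan, p=np.nan, significant=False)
        rows.append(row)
    return pd.DataFrame(rows)


def to_markdown(df: pd.DataFrame, float_fmt: str = "{:.3f}") -> str:
    """Minimal GitHub-style markdown rendering of a report table."""
    def fmt(v):
        return float_fmt.format(v) if isinstance(v, float) else str(v)
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *body])
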