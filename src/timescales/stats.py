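"""Statistical conventions used throughout the analysis.

Paired two-sided t tests compare per-subject state means; multiple
comparisons are handled by the multiply-by-n Bonferroni convention
(``p_bonf = min(1, p_raw * n)``), which preserves the usual 0.05/0.01/0.001
significance thresholds instead of lowering them.  Parametric assumptions
are screened with Shapiro-Wilk (normality, per state) and Levene
(homogeneity of variance, across states).  Model simulations are compared
per region with the Wilcoxon signed-rank test.

Sign convention of the paired t: ``paired_t(a, b)`` computes
``t = mean(a - b) / SE``, so a negative t means the second state is larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StateComparison",
    "paired_t",
    "bonferroni",
    "stars",
    "assumption_checks",
    "wilcoxon_signed_rank",
    "ac_mf_correlation",
    "compare_states",
]


@dataclass
class StateComparison:
    """Paired contrast between two states of per-subject means."""

    label: str
    mean_a: float
    mean_b: float
    t: float
    p_raw: float
    p_bonf: float
    n_comparisons: int
    direction: str

    def __post_init__(self) -> None:
        assert np.isclose(self.p_bonf, min(1.0, self.p_raw * self.n_comparisons))


@dataclass
class AssumptionReport:
    """Shapiro-Wilk p per state plus the cross-state Levene p."""

    shapiro_p: dict
    levene_p: float
    alpha: float = 0.05

    @property
    def shapiro_pass(self) -> dict:
        return {k: (np.isnan(v) or v > self.alpha) for k, v in self.shapiro_p.items()}

    @property
    def levene_pass(self) -> bool:
        return bool(np.isnan(self.levene_p) or self.levene_p > self.alpha)

    @property
    def all_pass(self) -> bool:
        return all(self.shapiro_pass.values()) and self.levene_pass


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Student t test; returns ``(t, p_raw)``.

    Identical samples return ``(0, 1)`` by convention; constant non-zero
    differences (zero variance, non-zero mean) are an error since t is
    unbounded there.
    """

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero variance of differences: t statistic undefined")
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def bonferroni(p_raw: float, n: int = 2) -> float:
    """Multiply-by-n Bonferroni correction, capped at 1."""

    if not 0 <= p_raw <= 1:
        raise ValueError("p value must be in [0, 1]")
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    return min(1.0, p_raw * n)


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""

    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def assumption_checks(samples: dict[str, np.ndarray], alpha: float = 0.05) -> AssumptionReport:
    """Shapiro-Wilk per state and Levene across states.

    Uses the mean-centred (classical) Levene statistic.  A constant sample
    is flagged with a NaN p value rather than raising.
    """

    shapiro_p: dict[str, float] = {}
    for name, x in samples.items():
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            raise ValueError(f"state {name!r} needs at least 3 observations")
        if np.ptp(x) == 0:
            shapiro_p[name] = float("nan")
            continue
        shapiro_p[name] = float(sps.shapiro(x).pvalue)
    arrays = [np.asarray(x, dtype=float) for x in samples.values()]
    if len(arrays) >= 2 and all(np.ptp(x) > 0 for x in arrays):
        levene_p = float(sps.levene(*arrays, center="mean").pvalue)
    else:
        levene_p = float("nan")
    return AssumptionReport(shapiro_p=shapiro_p, levene_p=levene_p, alpha=alpha)


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, zero_method: str = "wilcox"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped by default (``zero_method="pratt"`` keeps
    them in the ranking).  All-zero differences are an error.
    """

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all zero differences: signed-rank test undefined")
    if np.count_nonzero(d) < 5 and zero_method == "wilcox":
        raise ValueError("need at least 5 non-zero differences")
    res = sps.wilcoxon(a, b, zero_method=zero_method, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def ac_mf_correlation(acw_means: np.ndarray, mf_means: np.ndarray) -> tuple[float, float, float]:
    """Across-subject Pearson correlation between ACW and MF means.

    Returns ``(r, r_squared, p)``.  The two metrics move in opposite
    directions for band-limited signals, so r is expected negative.
    """

    acw_means = np.asarray(acw_means, dtype=float)
    mf_means = np.asarray(mf_means, dtype=float)
    if acw_means.shape != mf_means.shape or acw_means.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if acw_means.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(acw_means) == 0 or np.ptp(mf_means) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(acw_means, mf_means)
    return float(r), float(r * r), float(p)


def compare_states(
    a: np.ndarray, b: np.ndarray, label: str = "", n_comparisons: int = 2
) -> StateComparison:
    """Paired contrast with Bonferroni correction and a direction label."""

    t, p_raw = paired_t(a, b)
    diff = float(np.mean(np.asarray(b, dtype=float) - np.asarray(a, dtype=float)))
    direction = "b > a" if diff > 0 else ("b < a" if diff < 0 else "b = a")
    return StateComparison(
        label=label,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        t=t,
        p_raw=p_raw,
        p_bonf=bonferroni(p_raw, n_comparisons),
        n_comparisons=n_comparisons,
        direction=direction,
    )
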