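"""Validation-cohort statistics: summaries, hypothesis tests, rank correlation.

The inferential toolkit mirrors standard practice for cohort-level AUC
summaries: Student-t confidence intervals for means, a one-sample t-test of
"mean validation AUC = 0.5" (random classification), a Shapiro-Wilk
normality gate routing two-sample comparisons to Student's t or the
Mann-Whitney U test, and Spearman rank correlation between the
train∪filtration ranking criterion and validation performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedCorrelationError

NORMALITY_ALPHA = 0.05  # Shapiro-Wilk gate for t- vs U-test routing
_EXACT_U_MAX_N = 20  # exact U enumeration below this, tie-corrected normal above


@dataclass
class ValidationReport:
    """Per-tuple validation metrics plus their summary statistics."""

    frame: pd.DataFrame  # one row per tuple: probesets, auc, sensitivity, specificity
    mean_auc: float
    median_auc: float
    ci_low: float
    ci_high: float
    n: int

    def summary(self) -> str:
        lines = [
            f"validation tuples      {self.n}",
            f"mean AUC               {self.mean_auc:.3f}",
            f"95% CI for mean        ({self.ci_low:.3f}, {self.ci_high:.3f})",
            f"median AUC             {self.median_auc:.3f}",
        ]
        return "\n".join(lines)


def t_confidence_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Student-t interval for the mean (zero width for constant samples)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("confidence interval needs at least 2 values")
    if np.all(x == x[0]):  # constant sample: zero-width interval
        return float(x[0]), float(x[0])
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1)) / np.sqrt(len(x))
    q = sps.t.ppf(0.5 + level / 2.0, df=len(x) - 1)
    return m - q * se, m + q * se


def summarize_validation(tuples) -> ValidationReport:
    """Mean, median and 95% t-CI of validation AUCs over scored tuples."""
    if len(tuples) < 2:
        raise InsufficientDataError("need at least 2 scored tuples")
    rows = []
    for st in tuples:
        m = st.per_dataset["validation"]
        rows.append(
            {
                "probesets": ",".join(st.probesets),
                "auc": m.auc,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "mean_auc_tf": st.mean_auc_tf,
            }
        )
    frame = pd.DataFrame(rows)
    aucs = frame["auc"].to_numpy()
    lo, hi = t_confidence_interval(aucs)
    return ValidationReport(
        frame=frame,
        mean_auc=float(np.mean(aucs)),
        median_auc=float(np.median(aucs)),
        ci_low=lo,
        ci_high=hi,
        n=len(aucs),
    )


def test_mean_auc_above_random(validation_aucs) -> tuple[float, float]:
    """One-sample t-test of "mean validation AUC equals 0.5" (two-tailed).

    A zero-variance sample is degenerate: p → 0 when the common value differs
    from 0.5, p = 1 otherwise.
    """
    x = np.asarray(validation_aucs, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("one-sample t-test needs at least 2 values")
    if np.all(x == x[0]):
        if x[0] == 0.5:
            return 0.0, 1.0
        return float(np.sign(x[0] - 0.5) * np.inf), 0.0
    t, p = sps.ttest_1samp(x, 0.5)
    return float(t), float(p)


def compare_tuple_sizes(
    aucs_a, aucs_b, normality_check: bool = True
) -> tuple[str, float, float]:
    """Compare two AUC samples; returns (test name, statistic, two-tailed p).

    Shapiro-Wilk is run on each sample; only when both look normal (p >
    0.05) is Student's two-sample t-test used, otherwise the Mann-Whitney
    U test (exact enumeration for small tie-free samples, tie-corrected
    normal approximation beyond n = 20).
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    use_t = False
    if normality_check and len(a) >= 3 and len(b) >= 3:
        if np.std(a) > 0 and np.std(b) > 0:
            use_t = (
                sps.shapiro(a).pvalue > NORMALITY_ALPHA
                and sps.shapiro(b).pvalue > NORMALITY_ALPHA
            )
    if use_t:
        t, p = sps.ttest_ind(a, b)
        return "t-test", float(t), float(p)
    has_ties = len(np.unique(np.r_[a, b])) < len(a) + len(b)
    method = (
        "exact"
        if max(len(a), len(b)) <= _EXACT_U_MAX_N and not has_ties
        else "asymptotic"
    )
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return "u-test", float(u), float(p)


def rank_correlation(mean_auc_tf, validation_auc) -> tuple[float, float]:
    """Spearman rho (two-tailed p) between ranking criterion and validation AUC."""
    x = np.asarray(mean_auc_tf, dtype=float)
    y = np.asarray(validation_auc, dtype=float)
    if len(x) != len(y):
        raise InsufficientDataError("paired samples must align")
    if len(x) < 3:
        raise InsufficientDataError("rank correlation needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
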