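"""Repeated-measures analysis of the listeners x conditions threshold table.

One-way within-subject ANOVA (subjects as the blocking factor, uncorrected
degrees of freedom), post-hoc paired t-tests, and Holm's sequential
Bonferroni step-down correction, plus the per-condition mean ± SEM summary.
Thresholds are analyzed in µs as-is (no log transform).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "as_table",
    "AnovaResult",
    "rm_anova",
    "PairwiseResult",
    "paired_t",
    "holm_adjust",
    "pairwise_with_holm",
    "summarize",
]


def as_table(table) -> pd.DataFrame:
    """Coerce to a complete listeners x conditions DataFrame of thresholds."""
    df = pd.DataFrame(table)
    if df.isna().any().any():
        raise ValueError("threshold table has missing cells (no imputation)")
    if (df.to_numpy(dtype=float) <= 0).any():
        raise ValueError("thresholds must be positive")
    return df.astype(float)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    gg_epsilon: float | None = None  # set when the GG correction is applied

    @property
    def ss_total(self) -> float:
        return self.ss_condition + self.ss_subject + self.ss_error


def rm_anova(table, correction: str | None = None) -> AnovaResult:
    """One-way repeated-measures ANOVA over conditions (columns).

    Decomposes total variability into condition, subject and residual sums
    of squares; ``F = MS_condition / MS_error`` on ``(k-1, (k-1)(n-1))``
    degrees of freedom. With the study design (n = 6 listeners, k = 3
    conditions) the df are (2, 10). Uncorrected df are the default;
    ``correction='gg'`` applies the Greenhouse–Geisser epsilon to the
    p-value's degrees of freedom (F itself is unchanged). A zero residual
    mean square (perfectly additive table) leaves F undefined and raises.
    """
    df = as_table(table)
    y = df.to_numpy(dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = y.mean()
    ss_cond = n * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = max(ss_err, 0.0) / df2
    tiny = 1e-12 * max(ss_total, 1.0)
    if ms_err <= tiny:
        if ss_cond <= tiny:  # no condition effect and no residual: F := 0
            return AnovaResult(F=0.0, df1=df1, df2=df2, p=1.0,
                               ss_condition=ss_cond, ss_subject=ss_subj,
                               ss_error=ss_err)
        raise ZeroDivisionError(
            "residual mean square is zero; F is undefined for an additive table"
        )
    F = (ss_cond / df1) / ms_err
    eps = None
    if correction == "gg":
        eps = _gg_epsilon(y)
        p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    elif correction is None:
        p = float(sps.f.sf(F, df1, df2))
    else:
        raise ValueError(f"unknown sphericity correction: {correction!r}")
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p,
                       ss_condition=ss_cond, ss_subject=ss_subj,
                       ss_error=ss_err, gg_epsilon=eps)


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the double-centered covariance."""
    k = y.shape[1]
    S = np.cov(y, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * float((Sc**2).sum())
    return float(num / den)


@dataclass(frozen=True)
class PairwiseResult:
    label: str
    t: float
    df: int
    p: float
    p_holm: float | None = None
    reject: bool | None = None


def paired_t(a, b, label: str = "") -> PairwiseResult:
    """Two-sided paired t-test: ``t = mean(d) / (sd(d) / sqrt(n))``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length vectors")
    d = a - b
    n = d.size
    if n < 2:
        raise ValueError("need at least two pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:  # identical samples: no evidence either way
            return PairwiseResult(label=label, t=0.0, df=n - 1, p=1.0)
        raise ZeroDivisionError("zero-variance differences: t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairwiseResult(label=label, t=t, df=n - 1, p=p)


def holm_adjust(pvals, alpha: float = 0.05):
    """Holm step-down decisions and adjusted p-values.

    Sorted ascending, ``p_(i)`` is compared with ``alpha / (m - i)`` (0-based);
    the first failure stops all later rejections. Adjusted p-values are the
    running maxima of ``(m - i) * p_(i)`` clipped at 1, so
    ``reject == (p_holm <= alpha)``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    reject = adj <= alpha
    return reject, adj


def pairwise_with_holm(table, alpha: float = 0.05) -> list[PairwiseResult]:
    """All condition-pair paired t-tests with Holm-corrected decisions."""
    df = as_table(table)
    cols = list(df.columns)
    raw = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            raw.append(
                paired_t(df[cols[i]], df[cols[j]], f"{cols[i]} vs {cols[j]}")
            )
    reject, adj = holm_adjust([r.p for r in raw], alpha)
    return [
        PairwiseResult(label=r.label, t=r.t, df=r.df, p=r.p,
                       p_holm=float(a), reject=bool(rj))
        for r, a, rj in zip(raw, adj, reject)
    ]


def summarize(table) -> pd.DataFrame:
    """Per-condition mean and standard error of the mean (sd / sqrt(n))."""
    df = as_table(table)
    n = df.shape[0]
    return pd.DataFrame(
        {"mean": df.mean(axis=0), "sem": df.std(axis=0, ddof=1) / np.sqrt(n)}
    )
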