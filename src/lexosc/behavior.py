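"""Behavioral aggregation and group-level inference.

RTs of correct trials are trimmed to the subject-condition mean +- 2 SD
(single pass); accuracy is the correct-trial proportion.  Inference uses the
2x2 within-subject ANOVA (Task x Cognate Status) with subject-by-effect
error terms, planned paired/one-sample t-tests with Cohen's d = t / sqrt(n),
JZS Bayes factors (Cauchy prior on the standardized effect, scale 0.707,
numerical integration), Holm adjustment within planned-comparison families,
and Bonferroni control (alpha = 0.0125 for four one-sample tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "ANOVAResult", "trim_and_aggregate", "rm_anova_2x2",
    "paired_t_cohen_bf", "one_sample_t_bonferroni", "pearson_r",
    "jzs_bf10", "holm_adjust", "cohen_d_from_t", "two_tailed_p",
]


def cohen_d_from_t(t: float, n: int) -> float:
    """Cohen's d for a paired or one-sample t statistic: d = t / sqrt(n)."""
    return float(t / np.sqrt(n))


def two_tailed_p(t: float, df: int) -> float:
    """Two-tailed p-value of a t statistic with ``df`` degrees of freedom."""
    from scipy import stats as _st

    return float(2.0 * _st.t.sf(abs(t), df))


class BehaviorError(ValueError):
    pass


@dataclass
class ANOVAResult:
    effects: dict  # name -> dict(F, df1, df2, p, eta_p2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"effect": k, **v} for k, v in self.effects.items()])


def trim_and_aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject-condition accuracy and 2-SD-trimmed mean RT.

    Expects columns subject, task, cognate, correct, rt_ms; returns one row
    per subject-condition with accuracy and mean_rt_ms.
    """
    required = {"subject", "task", "cognate", "correct", "rt_ms"}
    missing = required - set(table.columns)
    if missing:
        raise BehaviorError(f"missing column(s): {', '.join(sorted(missing))}")
    rows = []
    for (subj, task, cog), grp in table.groupby(["subject", "task", "cognate"],
                                                sort=True):
        correct = grp[grp["correct"].astype(bool)]
        if len(correct) < 2:
            raise BehaviorError(
                f"subject {subj}, condition {task}/{cog}: fewer than 2 "
                "correct trials")
        rt = correct["rt_ms"].to_numpy(float)
        m, s = rt.mean(), rt.std(ddof=1)
        kept = rt[(rt >= m - 2 * s) & (rt <= m + 2 * s)]
        rows.append({
            "subject": subj, "task": task, "cognate": cog,
            "accuracy": len(correct) / len(grp),
            "mean_rt_ms": kept.mean(),
            "n_trials": len(grp), "n_correct": len(correct),
            "n_rt_trimmed": len(rt) - len(kept),
        })
    return pd.DataFrame(rows)


def rm_anova_2x2(cells: np.ndarray, factor_names=("task", "cognate")) -> ANOVAResult:
    """Two-way fully within-subject ANOVA on a subjects x 2 x 2 array.

    F = MS_effect / MS_(effect x subject); partial eta squared =
    SS_effect / (SS_effect + SS_error).
    """
    y = np.asarray(cells, float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise BehaviorError("cells must be subjects x 2 x 2")
    if not np.all(np.isfinite(y)):
        raise BehaviorError("missing cell in the design")
    n = y.shape[0]
    if n < 2:
        raise BehaviorError("need at least 2 subjects")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))           # subject means
    m_a = y.mean(axis=(0, 2))           # factor A level means
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)               # cell means
    m_sa = y.mean(axis=2)               # subject x A
    m_sb = y.mean(axis=1)

    ss_a = 2 * n * ((m_a - grand) ** 2).sum()
    ss_b = 2 * n * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = 2 * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (y - m_ab[None] - m_sa[:, :, None] - m_sb[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
             - grand)
    ss_abs = (resid ** 2).sum()

    effects = {}
    tiny = 1e-12 * max(float(((y - grand) ** 2).sum()), 1.0)
    for name, ss_eff, ss_err in (
        (factor_names[0], ss_a, ss_as),
        (factor_names[1], ss_b, ss_bs),
        (f"{factor_names[0]} x {factor_names[1]}", ss_ab, ss_abs),
    ):
        df1, df2 = 1, n - 1
        ms_err = ss_err / df2
        if ss_eff <= tiny:
            F = 0.0
        elif ms_err > 0:
            F = ss_eff / df1 / ms_err
        else:
            F = np.inf
        p = 1.0 if F == 0 else float(stats.f.sf(F, df1, df2))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > tiny else 0.0
        effects[name] = {"F": float(F), "df1": df1, "df2": df2,
                         "p": p, "eta_p2": float(eta)}
    return ANOVAResult(effects=effects)


def jzs_bf10(t: float, n: int, rscale: float = 0.707) -> float:
    """JZS Bayes factor for a one-sample / paired t statistic.

    Cauchy prior with scale ``rscale`` on the standardized effect size,
    integrated numerically (Gaussian quadrature over the prior's inverse-
    chi-square mixture representation).
    """
    if n < 2:
        raise BehaviorError("need n >= 2")
    nu = n - 1

    def h0_like():
        return (1 + t ** 2 / nu) ** (-(nu + 1) / 2)

    def integrand(g):
        return ((1 + n * g * rscale ** 2) ** -0.5 *
                (1 + t ** 2 / ((1 + n * g * rscale ** 2) * nu)) ** (-(nu + 1) / 2) *
                (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1.0 / (2 * g)))

    m1, err = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(m1 / h0_like())


def holm_adjust(p_values) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    return multipletests(p, method="holm")[1]


def paired_t_cohen_bf(x, y) -> dict:
    """Paired t with Cohen's d (= t / sqrt(n)) and JZS BF10."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise BehaviorError("x and y must be matching 1-D arrays")
    n = x.size
    if n < 2:
        raise BehaviorError("need at least 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        raise BehaviorError("zero variance of the paired differences")
    t, p = stats.ttest_rel(x, y)
    return {"t": float(t), "df": n - 1, "p": float(p),
            "d": float(t / np.sqrt(n)), "bf10": jzs_bf10(float(t), n)}


def one_sample_t_bonferroni(values, mu: float = 0.0, n_tests: int = 4,
                            alpha: float = 0.05) -> dict:
    """One-sample two-tailed t with Bonferroni-corrected significance flag
    (threshold alpha / n_tests, e.g. 0.0125 for four tests)."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise BehaviorError("need at least 2 values")
    if v.std(ddof=1) == 0:
        raise BehaviorError("zero variance")
    t, p = stats.ttest_1samp(v, mu)
    threshold = alpha / n_tests
    return {"t": float(t), "df": v.size - 1, "p": float(p),
            "d": float(t / np.sqrt(v.size)),
            "bf10": jzs_bf10(float(t), v.size),
            "alpha_corrected": threshold,
            "significant": bool(p < threshold)}


def pearson_r(x, y) -> dict:
    """Product-moment correlation with t-transform p (n-2 df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise BehaviorError("need matching vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise BehaviorError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise BehaviorError("zero variance")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}
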