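"""Two-group contrasts: moderated, pooled (Student) and Welch t-tests.

All tests operate on log2(RPM + pseudocount) per feature.  The moderated test
shrinks each feature's sample variance toward a prior estimated by empirical
Bayes: per-feature variances are modelled as scaled F draws around a prior
variance s0^2 with d0 prior degrees of freedom, and (d0, s0^2) are recovered
by matching the first two moments of log s^2 (digamma/trigamma inversion).
The moderated statistic is

    t = (mean_a - mean_b) / sqrt(s_tilde^2 * (1/n_a + 1/n_b)),
    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),   d = n_a + n_b - 2,

with a t reference distribution on d0 + d degrees of freedom.  d0 = 0
recovers the ordinary pooled t-test exactly; d0 -> infinity tests every
feature against the common variance s0^2.

Fold changes are reported as log2 of the ratio of linear group means (with a
pseudocount), and multiple testing is controlled per contrast with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ContrastConfig",
    "ModerationPrior",
    "log2_fold_change",
    "estimate_prior",
    "moderated_t",
    "student_t",
    "welch_t",
    "bh_adjust",
    "de_filter",
]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ContrastConfig:
    """Gates of one differential contrast (linear-scale fold change)."""

    test: str = "moderated"
    fc_threshold: float = 2.0
    alpha: float = 0.05
    correction: str = "benjamini-hochberg"
    log_base: int = 2

    def __post_init__(self):
        if self.test not in ("moderated", "student", "welch"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0^2 > 0."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if self.d0 < 0 or not self.s0_sq > 0:
            raise ValueError("require d0 >= 0 and s0_sq > 0")


def log2_fold_change(mean_a, mean_b, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2((mean_a + pc) / (mean_b + pc)); antisymmetric in the groups."""
    return np.log2((np.asarray(mean_a, float) + pseudocount) / (np.asarray(mean_b, float) + pseudocount))


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior(s2, df) -> ModerationPrior:
    """Method-of-moments prior from per-feature variances with ``df`` residual df.

    Matches mean and variance of log s^2 to the scaled-F model.  Features with
    non-positive variance are ignored.  If the observed dispersion of log s^2
    does not exceed what ``df`` alone explains, the prior degrees of freedom
    are infinite and s0^2 is the (bias-corrected) geometric mean variance.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least 2 features with positive variance")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if math.isfinite(d0):
            s0_sq = math.exp(
                float(np.mean(e)) + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
            )
            return ModerationPrior(d0, s0_sq)
    return ModerationPrior(math.inf, math.exp(float(np.mean(e))))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min over j >= i (in the sorted order) of m * p_(j) / j, clipped to 1.
    Adjusted values are monotone in the raw p-values and never smaller.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _log_transform(rpm: pd.DataFrame, pseudocount: float) -> pd.DataFrame:
    return np.log2(rpm + pseudocount)


def _as_rpm_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return data.rpm  # ExpressionMatrix


def _two_sided_p(t: np.ndarray, df) -> np.ndarray:
    df = np.broadcast_to(np.asarray(df, float), t.shape).copy()
    finite = np.isfinite(df)
    p = np.empty_like(t, dtype=float)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df[finite])
    p[~finite] = 2.0 * stats.norm.sf(np.abs(t[~finite]))
    return np.clip(p, 0.0, 1.0)


def _assemble(labels, log_fc, t, df, p) -> pd.DataFrame:
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "label": labels,
            "log_fc": log_fc,
            "t_stat": t,
            "df": df,
            "p": p,
            "p_adj": p_adj,
            "regulation": np.where(np.asarray(log_fc) > 0, "up", "down"),
        }
    ).set_index("label")


def _group_arrays(data, samples_a, samples_b, pseudocount):
    rpm = _as_rpm_frame(data)
    a = list(samples_a)
    b = list(samples_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    y = _log_transform(rpm, pseudocount)
    ya = y[a].to_numpy()
    yb = y[b].to_numpy()
    lfc = log2_fold_change(rpm[a].mean(axis=1), rpm[b].mean(axis=1), pseudocount)
    return rpm.index.to_numpy(), ya, yb, np.asarray(lfc)


def moderated_t(
    data,
    samples_a,
    samples_b,
    prior: ModerationPrior | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test on log2(RPM + pc).

    If no prior is given it is estimated from the data's per-feature pooled
    variances.  Features with zero shrunk variance and equal means get
    t = 0, p = 1; unequal means over zero variance give |t| = inf, p = 0.
    """
    labels, ya, yb, lfc = _group_arrays(data, samples_a, samples_b, pseudocount)
    na, nb = ya.shape[1], yb.shape[1]
    d = na + nb - 2
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / d
    if prior is None:
        prior = estimate_prior(s2, d)
    d0, s0 = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0 + d * s2) / (d0 + d)
        df_total = d0 + d
    diff = ya.mean(axis=1) - yb.mean(axis=1)
    denom = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[(denom == 0) & (diff == 0)] = 0.0
    p = _two_sided_p(t, df_total)
    p[(denom == 0) & (diff == 0)] = 1.0
    return _assemble(labels, lfc, t, np.full(t.shape, df_total), p)


def student_t(data, samples_a, samples_b, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Ordinary pooled-variance two-sample t-test (moderated test with d0 = 0)."""
    return moderated_t(
        data, samples_a, samples_b, prior=ModerationPrior(0.0, 1.0), pseudocount=pseudocount
    )


def welch_t(data, samples_a, samples_b, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Welch unequal-variance t-test with Welch-Satterthwaite df."""
    labels, ya, yb, lfc = _group_arrays(data, samples_a, samples_b, pseudocount)
    na, nb = ya.shape[1], yb.shape[1]
    va = ya.var(axis=1, ddof=1)
    vb = yb.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ya.mean(axis=1) - yb.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    zero = se2 == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff != 0)] = np.where(diff[zero & (diff != 0)] > 0, np.inf, -np.inf)
    df[zero] = na + nb - 2
    p = _two_sided_p(t, df)
    p[zero & (diff == 0)] = 1.0
    return _assemble(labels, lfc, t, df, p)


def de_filter(records: pd.DataFrame, config: ContrastConfig) -> pd.DataFrame:
    """Keep records with |linear fold change| > threshold and p_adj < alpha
    (both strict); the fold-change gate is applied to the linear group-mean
    ratio, i.e. |log_fc| > log2(threshold)."""
    mask = (np.abs(records["log_fc"]) > np.log2(config.fc_threshold)) & (
        records["p_adj"] < config.alpha
    )
    return records[mask]
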