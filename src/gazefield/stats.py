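"""Inferential statistics for balanced mixed (split-plot) designs.

The experiment's designs are one between-subjects factor (group: expert vs
novice) crossed with one or two within-subjects factors (viewing condition;
RT-quintile bin).  For balanced complete data the sums of squares decompose
exactly over the factorial strata, and every effect is tested against its
proper error stratum:

    group                 vs  subjects-within-group
    A, group x A          vs  A x subjects-within-group
    B, group x B          vs  B x subjects-within-group
    A x B, group x A x B  vs  A x B x subjects-within-group

Sums of squares are computed by inclusion-exclusion over marginal means
(the closed form for balanced designs), after relabelling subjects within
group so the layout is a complete array; nested terms are then pooled
(e.g. SS[subjects-within-group] = SS[S] + SS[G x S]).

The effect size reported is generalized eta squared:
SS_effect / (SS_effect + sum of all subject-variance and error strata),
appropriate for designs whose only measured factor is the subject.

Also provided: Welch's two-sample t from summary statistics (mean, SE, n)
with Welch-Satterthwaite degrees of freedom, a paired t-test, and the
minimal detectable Cohen's d for a two-sample t-test at given n, alpha and
power via the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import f as f_dist
from scipy.stats import nct, t as t_dist


@dataclass(frozen=True)
class AnovaResult:
    """ANOVA table plus the error strata needed for effect sizes."""

    table: pd.DataFrame  # effect, SS, df, MS, F, p, ges
    error_strata: dict[str, tuple[float, int]]  # name -> (SS, df)

    def effect(self, name: str) -> pd.Series:
        sub = self.table[self.table["effect"] == name]
        if sub.empty:
            raise KeyError(f"no effect named {name!r}")
        return sub.iloc[0]

    def __str__(self) -> str:  # plain-text ANOVA table
        lines = [self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}")]
        for name, (ss, df) in self.error_strata.items():
            lines.append(f"error [{name}]: SS={ss:.4f}, df={df}")
        return "\n".join(lines)


def _subset_ss(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Balanced-design SS of the pure interaction among ``axes`` via
    inclusion-exclusion over marginal means."""
    ndim = y.ndim
    effect = np.zeros([1] * ndim)
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            reduce_over = tuple(i for i in range(ndim) if i not in sub)
            m = y.mean(axis=reduce_over, keepdims=True) if reduce_over else y
            effect = effect + ((-1) ** (len(axes) - len(sub))) * m
    reps = y.size / effect.size
    return float(np.sum(effect**2) * reps)


def _to_array(
    df: pd.DataFrame, dv: str, between: str, within: Sequence[str], subject: str
):
    """Pivot a tidy table into a complete (G, S, W1[, W2]) array; errors on
    unbalanced data."""
    groups = sorted(df[between].unique())
    within_levels = [sorted(df[w].unique()) for w in within]
    subj_group = df.groupby(subject)[between].nunique()
    if (subj_group > 1).any():
        raise ValueError("each subject must belong to exactly one group")
    subj_by_group = {
        g: sorted(df.loc[df[between] == g, subject].unique()) for g in groups
    }
    ns = {g: len(s) for g, s in subj_by_group.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(f"unbalanced design: group sizes {ns}")
    n = next(iter(ns.values()))
    if n < 2:
        raise ValueError("need at least 2 subjects per group")
    n_cells = int(np.prod([len(l) for l in within_levels])) if within else 1
    shape = (len(groups), n) + tuple(len(l) for l in within_levels)
    y = np.full(shape, np.nan)
    idx = {w: {lv: i for i, lv in enumerate(levels)} for w, levels in zip(within, within_levels)}
    for gi, g in enumerate(groups):
        for si, s in enumerate(subj_by_group[g]):
            sub = df[(df[between] == g) & (df[subject] == s)]
            if len(sub) != n_cells:
                raise ValueError(
                    f"unbalanced design: subject {s!r} has {len(sub)} rows, "
                    f"expected {n_cells} (one per within-cell)"
                )
            for row in sub.itertuples(index=False):
                d = row._asdict()
                pos = (gi, si) + tuple(idx[w][d[w]] for w in within)
                y[pos] = d[dv]
    if np.isnan(y).any():
        raise ValueError("unbalanced design: missing within-cells")
    return y, groups, within_levels


def mixed_anova(
    df: pd.DataFrame,
    dv: str,
    between: str,
    within: str | Sequence[str],
    subject: str,
) -> AnovaResult:
    """Balanced split-plot ANOVA with one between factor and 1-2 within
    factors (0 within factors degrade to a one-way between-subjects ANOVA).

    ``df`` holds one row per subject x within-cell (cell means).  Raises on
    unbalanced data; no sphericity correction is applied (use
    :func:`greenhouse_geisser_epsilon` to adjust externally if desired).
    """
    if isinstance(within, str):
        within = [within]
    within = list(within)
    if len(within) > 2:
        raise ValueError("at most two within factors are supported")
    y, groups, within_levels = _to_array(df, dv, between, within, subject)
    g = len(groups)
    n = y.shape[1]
    sizes = [len(l) for l in within_levels]

    # axis indices: 0=G, 1=S, 2=A, 3=B
    ss = {T: _subset_ss(y, T) for r in range(1, y.ndim + 1)
          for T in combinations(range(y.ndim), r)}

    strata: dict[str, tuple[float, int]] = {}
    strata["subjects"] = (ss[(1,)] + ss.get((0, 1), 0.0), g * (n - 1))
    rows = [dict(effect=between, SS=ss[(0,)], df=g - 1, error="subjects")]
    names = within
    for k, w in enumerate(names):
        a = sizes[k]
        ax = 2 + k
        err = f"{w} x subjects"
        strata[err] = (ss[(1, ax)] + ss[(0, 1, ax)], g * (n - 1) * (a - 1))
        rows.append(dict(effect=w, SS=ss[(ax,)], df=a - 1, error=err))
        rows.append(
            dict(effect=f"{between} x {w}", SS=ss[(0, ax)], df=(g - 1) * (a - 1), error=err)
        )
    if len(names) == 2:
        a, b = sizes
        err = f"{names[0]} x {names[1]} x subjects"
        strata[err] = (
            ss[(1, 2, 3)] + ss[(0, 1, 2, 3)],
            g * (n - 1) * (a - 1) * (b - 1),
        )
        rows.append(
            dict(
                effect=f"{names[0]} x {names[1]}",
                SS=ss[(2, 3)],
                df=(a - 1) * (b - 1),
                error=err,
            )
        )
        rows.append(
            dict(
                effect=f"{between} x {names[0]} x {names[1]}",
                SS=ss[(0, 2, 3)],
                df=(g - 1) * (a - 1) * (b - 1),
                error=err,
            )
        )

    denom_all = sum(s for s, _ in strata.values())  # subject-variance + error SS
    out = []
    for r in rows:
        err_ss, err_df = strata[r["error"]]
        ms = r["SS"] / r["df"] if r["df"] else np.nan
        mse = err_ss / err_df if err_df else np.nan
        F = ms / mse if mse > 0 else (0.0 if r["SS"] == 0 else np.inf)
        p = float(f_dist.sf(F, r["df"], err_df)) if np.isfinite(F) else 0.0
        denom = r["SS"] + denom_all
        ges = r["SS"] / denom if denom > 0 else np.nan
        out.append(
            dict(effect=r["effect"], SS=r["SS"], df=r["df"], MS=ms, F=F, p=p, ges=ges)
        )
    return AnovaResult(table=pd.DataFrame(out), error_strata=strata)


def generalized_eta_sq(result: AnovaResult, effect: str) -> float:
    """Generalized eta squared for one effect of a fitted ANOVA:
    SS_effect / (SS_effect + sum of subject and error strata SS)."""
    row = result.effect(effect)
    denom = row["SS"] + sum(s for s, _ in result.error_strata.values())
    if denom <= 0:
        return float("nan")
    return float(row["SS"] / denom)


def greenhouse_geisser_epsilon(
    df: pd.DataFrame, dv: str, within: str, subject: str
) -> float:
    """Greenhouse-Geisser sphericity epsilon for a single within factor,
    from the sample covariance of the subject x level matrix.  Provided as
    an optional adjustment; the ANOVA itself reports uncorrected dfs."""
    wide = df.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("unbalanced data")
    S = np.cov(wide.to_numpy(), rowvar=False, ddof=1)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * grand**2)
    return float(num / den)


@dataclass(frozen=True)
class SummaryGroup:
    """Group summary: mean, standard error of the mean, and sample size."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def welch_t(a: SummaryGroup, b: SummaryGroup) -> TTestResult:
    """Welch's two-sample t-test from summary statistics.

    t = (mean_a - mean_b) / sqrt(se_a^2 + se_b^2); df by Welch-Satterthwaite
    with (n-1) denominators; two-sided p from the t distribution.
    """
    va, vb = a.se**2, b.se**2
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TTestResult(t=float(t), df=float(df), p=p)


def paired_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Paired t-test: one-sample t on the differences, df = n - 1,
    two-sided p.  Zero-variance differences raise (rather than yield NaN)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("differences have zero variance; t is undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(t_dist.sf(abs(t), n - 1))
    return TTestResult(t=float(t), df=float(n - 1), p=p)


def two_sample_power(d: float, n_per_group: int, alpha: float) -> float:
    """Power of the two-sided two-sample t-test at effect size d (Cohen),
    equal group sizes, via the noncentral t distribution."""
    df = 2 * n_per_group - 2
    crit = t_dist.ppf(1 - alpha / 2, df)
    ncp = d * np.sqrt(n_per_group / 2.0)
    upper = nct.sf(crit, df, ncp)
    lower = nct.cdf(-crit, df, ncp)
    # scipy's noncentral t underflows to NaN in the far tail; the true mass
    # there is numerically zero
    return float(np.nan_to_num(upper) + np.nan_to_num(lower))


def min_detectable_d(
    n_per_group: int, alpha: float, power: float, tol: float = 1e-6
) -> float:
    """Smallest Cohen's d detectable with the given n/alpha at the target
    power (two-sided two-sample t-test), root-found on the noncentral-t
    power function to ``tol``."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if power <= alpha:
        return 0.0  # the test achieves its size at d = 0
    f = lambda d: two_sample_power(d, n_per_group, alpha) - power
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("requested power unreachable")
    return float(optimize.brentq(f, 0.0, hi, xtol=tol))
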