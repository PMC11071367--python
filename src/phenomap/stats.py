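"""Statistics toolbox: ANOVAs, post hoc tests, t-tests, ROUT outliers, behavior indices.

The toolbox mirrors the conventions of GraphPad-style group analyses: one-way
ANOVA with Tukey / Dunnett / Fisher-LSD post hocs, paired and unpaired t-tests,
a two-way (sex x group) ANOVA reporting the interaction, and the ROUT robust
outlier procedure specialised to one-sample (constant-model) data.

All tests report a :class:`TestResult` with the statistic, degrees of freedom,
and a two-sided p-value; p-values are floored at ``P_FLOOR`` and never reported
as exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

P_FLOOR = 1e-300

__all__ = [
    "TestResult",
    "Comparison",
    "OutlierReport",
    "one_way_anova",
    "posthoc",
    "t_test",
    "two_way_anova_interaction",
    "rout_outliers",
    "olfactory_discrimination_index",
    "sucrose_preference_index",
]


@dataclass
class Comparison:
    """One post hoc contrast: point estimate, test statistic, adjusted p."""

    estimate: float
    statistic: float
    p: float


@dataclass
class TestResult:
    method: str
    statistic: float
    df: tuple[float, ...] | float
    p: float
    comparisons: dict[str, Comparison] | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
        }
        if self.comparisons is not None:
            d["comparisons"] = {
                k: vars(c).copy() for k, c in self.comparisons.items()
            }
        if self.extras:
            d["extras"] = self.extras
        return d


@dataclass
class OutlierReport:
    values: np.ndarray
    flagged: np.ndarray  # indices into values
    q: float
    location: float
    scale: float

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(len(self.values), dtype=bool)
        m[self.flagged] = True
        return m


def _floor_p(p: float) -> float:
    return float(min(max(p, P_FLOOR), 1.0))


def _as_groups(sample: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {str(k): np.asarray(v, dtype=float) for k, v in sample.items()}
    for name, v in groups.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in group {name!r}")
    return groups


def one_way_anova(sample: Mapping[str, Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA across k groups.

    F = MS_between / MS_within with df = (k-1, N-k).
    """
    groups = _as_groups(sample)
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(v) for v in groups.values()])
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    N = int(ns.sum())
    means = np.array([v.mean() for v in groups.values()])
    grand = float(np.concatenate(list(groups.values())).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    df1, df2 = k - 1, N - k
    if ssw == 0.0 and ssb == 0.0:
        raise ValueError("all values identical: F undefined")
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0.0:
        return TestResult("one_way_anova", float("inf"), (df1, df2), P_FLOOR)
    F = msb / msw
    p = _floor_p(sps.f.sf(F, df1, df2))
    return TestResult(
        "one_way_anova",
        float(F),
        (df1, df2),
        p,
        extras={"ms_within": msw, "group_means": dict(zip(groups, means))},
    )


# fixed internal seed so Dunnett multivariate-t integration is reproducible
_DUNNETT_SEED = 19680801


def _dunnett_adjusted_p(t_abs: float, corr: np.ndarray, df: int) -> float:
    """Familywise-adjusted two-sided p for |t| under the many-to-one setup.

    P(max_j |T_j| > t) for T ~ multivariate t(df) with correlation ``corr``,
    evaluated by scipy's quasi-Monte-Carlo integration with a fixed seed.
    """
    m = corr.shape[0]
    if m == 1:
        return 2.0 * float(sps.t.sf(t_abs, df))
    rng = np.random.default_rng(_DUNNETT_SEED)
    central = sps.multivariate_t.cdf(
        np.full(m, t_abs),
        loc=np.zeros(m),
        shape=corr,
        df=df,
        lower_limit=np.full(m, -t_abs),
        random_state=rng,
        maxpts=20_000 * m,
    )
    return 1.0 - float(central)


def posthoc(
    sample: Mapping[str, Sequence[float]],
    method: str = "tukey",
    control_label: str | None = None,
) -> TestResult:
    """Post hoc pairwise comparisons after a one-way ANOVA.

    - ``tukey``: Tukey(-Kramer) via the studentized range distribution.
    - ``dunnett``: many-to-one versus ``control_label`` via the equicorrelated
      multivariate-t; the single-comparison (k=2) case is exact.
    - ``fisher_lsd``: unadjusted pairwise t on the pooled within-group MS.
    """
    groups = _as_groups(sample)
    anova = one_way_anova(groups)
    msw = anova.extras["ms_within"]
    df2 = int(anova.df[1])
    k = len(groups)
    names = list(groups)
    ns = {g: len(groups[g]) for g in names}
    means = {g: float(groups[g].mean()) for g in names}
    comps: dict[str, Comparison] = {}

    if method == "tukey":
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                diff = means[a] - means[b]
                se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
                q = abs(diff) / se
                p = _floor_p(sps.studentized_range.sf(q, k, df2))
                comps[f"{a} vs {b}"] = Comparison(diff, float(q), p)
    elif method == "dunnett":
        if control_label is None or control_label not in groups:
            raise ValueError("dunnett requires a control_label present in the sample")
        others = [g for g in names if g != control_label]
        n0 = ns[control_label]
        lam = np.array([ns[g] / (ns[g] + n0) for g in others])
        corr = np.sqrt(np.outer(lam, lam))
        np.fill_diagonal(corr, 1.0)
        for j, g in enumerate(others):
            diff = means[g] - means[control_label]
            se = np.sqrt(msw * (1.0 / ns[g] + 1.0 / n0))
            t = diff / se
            p = _floor_p(_dunnett_adjusted_p(abs(t), corr, df2))
            comps[f"{g} vs {control_label}"] = Comparison(diff, float(t), p)
    elif method == "fisher_lsd":
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                diff = means[a] - means[b]
                se = np.sqrt(msw * (1.0 / ns[a] + 1.0 / ns[b]))
                t = diff / se
                p = _floor_p(2.0 * sps.t.sf(abs(t), df2))
                comps[f"{a} vs {b}"] = Comparison(diff, float(t), p)
    else:
        raise ValueError(f"unknown post hoc method {method!r}")

    p_min = min(c.p for c in comps.values())
    return TestResult(f"posthoc_{method}", float("nan"), df2, p_min, comparisons=comps)


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    pooled: bool = False,
) -> TestResult:
    """Two-sided t-test; Welch by default for unpaired data (``pooled=True``
    gives the classic equal-variance test)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length samples")
        if len(x) < 2:
            raise ValueError("need n >= 2 pairs")
        d = x - y
        n = len(d)
        if np.std(d, ddof=1) == 0.0:
            if d.mean() == 0.0:
                return TestResult("paired_t", 0.0, float(n - 1), 1.0)
            raise ValueError("zero variance of differences with nonzero mean")
        res = sps.ttest_rel(x, y)
        return TestResult(
            "paired_t",
            float(res.statistic),
            float(n - 1),
            _floor_p(res.pvalue),
            extras={"mean_diff": float(d.mean())},
        )
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per sample")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestResult(
        "pooled_t" if pooled else "welch_t",
        float(res.statistic),
        float(res.df),
        _floor_p(res.pvalue),
        extras={"mean_diff": float(x.mean() - y.mean())},
    )


def two_way_anova_interaction(
    values: Sequence[float],
    group: Sequence[str],
    sex: Sequence[str],
) -> TestResult:
    """Two-factor ANOVA (group x sex); the interaction F/p is the headline
    result, main effects ride along in ``extras``.

    Type-II sums of squares are used so mildly unbalanced designs remain
    interpretable.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": list(group), "s": list(sex)})
    if df["g"].nunique() < 2 or df["s"].nunique() < 2:
        raise ValueError("need >= 2 levels per factor")
    counts = df.groupby(["g", "s"]).size()
    if len(counts) < df["g"].nunique() * df["s"].nunique():
        raise ValueError("empty factor cells: interaction inestimable")
    model = smf.ols("y ~ C(g) * C(s)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = table.loc["C(g):C(s)"]
    df1 = float(inter["df"])
    df2 = float(table.loc["Residual", "df"])
    F = float(inter["F"])
    p = _floor_p(float(inter["PR(>F)"]))
    extras = {}
    for row, label in (("C(g)", "group"), ("C(s)", "sex")):
        extras[f"{label}_F"] = float(table.loc[row, "F"])
        extras[f"{label}_p"] = _floor_p(float(table.loc[row, "PR(>F)"]))
    return TestResult("two_way_anova_interaction", F, (df1, df2), p, extras=extras)


def rout_outliers(values: Sequence[float], q: float = 0.05, max_iter: int = 20) -> OutlierReport:
    """One-sample ROUT outlier identification.

    The regression-based procedure specialises to a constant model for a plain
    sample: robust location = median; robust scale = RSDR, the 68.27th
    percentile of absolute residuals with the small-n correction
    ``RSDR = P68 * n/(n - K)`` (K = 1 fitted parameter).  Residual t-scores are
    screened with Benjamini-Hochberg FDR control at ``q`` and the fit is
    iterated on the unflagged points until the flag set stabilises.  Flagged
    values are reported, never removed.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need n >= 5 for outlier screening")
    if not 0.0 < q < 1.0:
        raise ValueError("Q must lie in (0, 1)")
    keep = np.ones(n, dtype=bool)
    med = float(np.median(x))
    rsdr = np.nan
    for _ in range(max_iter):
        med = float(np.median(x[keep]))
        resid = x - med
        m = int(keep.sum())
        p68 = float(np.percentile(np.abs(resid[keep]), 68.27))
        rsdr = p68 * m / max(m - 1, 1)
        if rsdr <= 0.0:
            if np.any(resid[keep] != 0.0):
                raise ValueError("zero robust scale with nonzero residuals")
            keep_new = np.ones(n, dtype=bool)
        else:
            t = np.abs(resid) / rsdr
            pvals = 2.0 * sps.t.sf(t, df=max(m - 1, 1))
            order = np.argsort(pvals)
            thresh_rank = 0
            for rank, idx in enumerate(order, start=1):
                if pvals[idx] <= q * rank / n:
                    thresh_rank = rank
            flagged = np.zeros(n, dtype=bool)
            flagged[order[:thresh_rank]] = True
            keep_new = ~flagged
        if np.array_equal(keep_new, keep):
            break
        keep = keep_new
    flagged_idx = np.flatnonzero(~keep)
    return OutlierReport(x, flagged_idx, q, med, float(rsdr))


def olfactory_discrimination_index(t_attractive: float, t_aversive: float) -> float:
    """Fraction of corner time spent with the attractive odor; NaN if no time."""
    if t_attractive < 0 or t_aversive < 0:
        raise ValueError("corner times must be nonnegative")
    total = t_attractive + t_aversive
    if total == 0:
        return float("nan")
    return float(t_attractive / total)


def sucrose_preference_index(sucrose_ml: float, water_ml: float) -> float:
    """Percent of total intake that was sucrose water; NaN if no intake."""
    if sucrose_ml < 0 or water_ml < 0:
        raise ValueError("intake volumes must be nonnegative")
    total = sucrose_ml + water_ml
    if total == 0:
        return float("nan")
    return float(100.0 * sucrose_ml / total)
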