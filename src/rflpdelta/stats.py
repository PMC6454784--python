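"""Regression families, unbalanced ANOVA, Tukey-Kramer, Lilliefors, and
the theoretical-vs-actual delta report.

The comparison layer of the pipeline follows the classical toolkit of
the fingerprinting literature: band-count-vs-community-size curves are
fitted with four regression families (linear, exponential, logarithmic,
geometric/power); treatment data sets of unequal sizes are compared by
unbalanced one-way ANOVA with Tukey-Kramer pairwise contrasts; normality
is screened with the Lilliefors variant of the Kolmogorov-Smirnov test
(parameters estimated from the sample, null distribution by seeded Monte
Carlo); and the headline quantity — the fold-loss of detectable bands
between pre-assembly (theoretical) and post-assembly (actual) data — is
reported per community size with its overall range.

Exponential and geometric fits default to log-linearization, the method
of the era's desktop statistics packages; exact nonlinear least squares
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "RegressionFit",
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "DeltaReport",
    "REGRESSION_FAMILIES",
    "fit_regression",
    "best_fit",
    "unbalanced_anova",
    "tukey_kramer",
    "lilliefors",
    "delta_report",
]

REGRESSION_FAMILIES = ("linear", "exponential", "logarithmic", "geometric")


@dataclass
class RegressionFit:
    """One fitted curve.

    ``a`` is the slope-like coefficient (reported as "regression
    coefficient" in the fingerprinting literature; note the term is ambiguous
    there), ``b`` the second parameter:

    * linear: ``y = a*x + b``
    * logarithmic: ``y = a*ln(x) + b``
    * exponential: ``y = a*exp(b*x)``
    * geometric (power): ``y = a*x**b``

    ``r_squared`` is computed on the original scale; for the log-
    linearized families ``r_squared_linearized`` is the squared Pearson
    correlation of the transformed variables.
    """

    family: str
    a: float
    b: float
    r_squared: float
    r_squared_linearized: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "linear":
            return self.a * x + self.b
        if self.family == "logarithmic":
            return self.a * np.log(x) + self.b
        if self.family == "exponential":
            return self.a * np.exp(self.b * x)
        return self.a * x ** self.b


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_regression(
    x: Sequence[float],
    y: Sequence[float],
    family: str,
    nonlinear: bool = False,
) -> RegressionFit:
    """Fit one regression family to (x, y).

    Log-requiring families validate positivity: x > 0 for logarithmic and
    geometric, y > 0 for exponential and geometric. With
    ``nonlinear=True`` the exponential and geometric families are refit
    by Levenberg-Marquardt least squares initialized at the log-linear
    estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if family not in REGRESSION_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family in ("logarithmic", "geometric") and np.any(x <= 0):
        raise ValueError(f"{family} regression requires x > 0")
    if family in ("exponential", "geometric") and np.any(y <= 0):
        raise ValueError(f"{family} regression requires y > 0")

    if family == "linear":
        a, b = np.polyfit(x, y, 1)
        r2_lin = _corr_r2(x, y)
    elif family == "logarithmic":
        a, b = np.polyfit(np.log(x), y, 1)
        r2_lin = _corr_r2(np.log(x), y)
    elif family == "exponential":
        slope, intercept = np.polyfit(x, np.log(y), 1)
        a, b = float(np.exp(intercept)), float(slope)
        r2_lin = _corr_r2(x, np.log(y))
    else:  # geometric / power law
        slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
        a, b = float(np.exp(intercept)), float(slope)
        r2_lin = _corr_r2(np.log(x), np.log(y))

    if nonlinear and family in ("exponential", "geometric"):
        fn = (
            (lambda xx, aa, bb: aa * np.exp(bb * xx))
            if family == "exponential"
            else (lambda xx, aa, bb: aa * xx ** bb)
        )
        try:
            (a, b), _ = optimize.curve_fit(fn, x, y, p0=[a, b], maxfev=10000)
        except RuntimeError:
            pass  # keep the log-linear estimate

    fit = RegressionFit(family, float(a), float(b), 0.0, float(r2_lin), n)
    fit.r_squared = _r2(y, fit.predict(x))
    return fit


def _corr_r2(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return 1.0
    return float(np.corrcoef(u, v)[0, 1] ** 2)


def best_fit(x, y, families: Sequence[str] = REGRESSION_FAMILIES) -> RegressionFit:
    """Fit every applicable family and return the highest original-scale
    R^2 (families whose positivity preconditions fail are skipped)."""
    fits = []
    for fam in families:
        try:
            fits.append(fit_regression(x, y, fam))
        except ValueError:
            continue
    if not fits:
        raise ValueError("no regression family applicable to these data")
    return max(fits, key=lambda f: f.r_squared)


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA on possibly unequal group sizes."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: list[float]
    group_ns: list[int]
    ms_within: float


def unbalanced_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Standard one-way F test; group sizes may differ."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in arrs):
        raise ValueError("every group needs n >= 2")
    f_stat, p = sps.f_oneway(*arrs)
    ns = [len(g) for g in arrs]
    n_total = sum(ns)
    k = len(arrs)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in arrs)
    msw = ssw / (n_total - k)
    if not np.isfinite(f_stat):  # all groups identical constants
        f_stat, p = 0.0, 1.0
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p),
        group_means=[float(g.mean()) for g in arrs],
        group_ns=ns,
        ms_within=msw,
    )


@dataclass
class TukeyPair:
    group_i: str
    group_j: str
    mean_difference: float
    q_statistic: float
    p_value: float
    significant: bool


@dataclass
class TukeyResult:
    alpha: float
    pairs: list[TukeyPair]

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(p.group_i, p.group_j) for p in self.pairs if p.significant]


def tukey_kramer(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """All pairwise comparisons by the Tukey-Kramer procedure.

    For unequal group sizes the standard error of a pair (i, j) is
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))``; the q statistic is referred to the
    studentized range distribution with k groups and the within-groups
    degrees of freedom.
    """
    anova = unbalanced_anova(groups)
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    msw, df = anova.ms_within, anova.df_within
    pairs: list[TukeyPair] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = anova.group_means[i] - anova.group_means[j]
            se = np.sqrt(
                msw / 2.0 * (1.0 / anova.group_ns[i] + 1.0 / anova.group_ns[j])
            )
            q = abs(diff) / se if se > 0 else 0.0
            p = float(sps.studentized_range.sf(q, k, df)) if se > 0 else 1.0
            pairs.append(
                TukeyPair(labels[i], labels[j], float(diff), float(q), p, p < alpha)
            )
    return TukeyResult(alpha=alpha, pairs=pairs)


_LILLIEFORS_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_d(sample: np.ndarray) -> float:
    x = np.sort(sample)
    n = len(x)
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("Lilliefors test is undefined for a constant sample")
    cdf = sps.norm.cdf((x - x.mean()) / s)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def _lilliefors_null(n: int, n_draws: int, seed: int) -> np.ndarray:
    key = (n, n_draws, seed)
    if key not in _LILLIEFORS_NULL_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
        draws = rng.standard_normal((n_draws, n))
        draws.sort(axis=1)
        m = draws.mean(axis=1, keepdims=True)
        s = draws.std(axis=1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf((draws - m) / s)
        i = np.arange(1, n + 1)
        d = np.maximum(i / n - cdf, cdf - (i - 1) / n).max(axis=1)
        _LILLIEFORS_NULL_CACHE[key] = np.sort(d)
    return _LILLIEFORS_NULL_CACHE[key]


def lilliefors(
    sample: Sequence[float],
    mode: str = "monte_carlo",
    n_draws: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Lilliefors normality test: KS distance to a normal with estimated
    mean and SD.

    ``mode="monte_carlo"`` (default) draws the null distribution of D for
    this sample size with a fixed seed (the null is cached per (n,
    n_draws, seed)); ``mode="table"`` uses the published-table
    interpolation of ``statsmodels``. Returns ``(D, p)``.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    d = _lilliefors_d(x)
    if mode == "table":
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        _, p = sm_lilliefors(x, dist="norm", pvalmethod="table")
        return d, float(p)
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    null = _lilliefors_null(len(x), n_draws, seed)
    n_ge = len(null) - int(np.searchsorted(null, d, side="left"))
    # add-one correction keeps p in (0, 1]
    return d, (n_ge + 1) / (len(null) + 1)


@dataclass
class DeltaReport:
    """Per-group-size theoretical vs actual band counts and fold-losses."""

    table: pd.DataFrame  # group_size, theoretical_bands, actual_bands, fold_loss
    fold_min: float
    fold_max: float
    undefined_groups: list[int] = field(default_factory=list)


def _as_series(summary) -> pd.Series:
    if isinstance(summary, pd.DataFrame):
        return summary.set_index("group_size")["mean_bands"].astype(float)
    return pd.Series(dict(summary), dtype=float).sort_index()


def delta_report(theoretical, actual) -> DeltaReport:
    """Fold-loss of detectable bands, theoretical / actual, per group size.

    Both inputs are either summary frames (``group_size``/``mean_bands``
    columns, as produced by :func:`rflpdelta.communities.summarize_groups`)
    or mappings group_size -> mean band count, over matching group sizes.
    Groups with zero actual bands are flagged, not divided.
    """
    th = _as_series(theoretical)
    ac = _as_series(actual)
    if list(th.index) != list(ac.index):
        raise ValueError("theoretical and actual summaries must share group sizes")
    fold = th / ac.replace(0, np.nan)
    table = pd.DataFrame(
        {
            "group_size": th.index,
            "theoretical_bands": th.values,
            "actual_bands": ac.values,
            "fold_loss": fold.values,
        }
    ).reset_index(drop=True)
    defined = fold.dropna()
    if defined.empty:
        raise ValueError("fold-loss undefined for every group (actual all zero)")
    return DeltaReport(
        table=table,
        fold_min=float(defined.min()),
        fold_max=float(defined.max()),
        undefined_groups=[int(g) for g in fold.index[fold.isna()]],
    )
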