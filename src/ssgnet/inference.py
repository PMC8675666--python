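"""Mixed-effects inference: LRTs, local Cohen's f², bootstrap CIs.

Every model in this package has the same shape: a numeric response, a
handful of categorical fixed effects (pitch size, game type, maturation
band), and a single random intercept that absorbs the covariance between
repeated observations on the same player (individual metrics) or the
same team composition (team metrics),

    y_gi = x_gi' beta + u_g + e_gi,   u_g ~ N(0, s2_u),  e_gi ~ N(0, s2_e).

Fits are maximum likelihood (not REML) throughout so that log-likelihoods
are comparable across fixed-effect structures in likelihood-ratio tests.
For this one-random-intercept family the ML problem reduces to a
one-dimensional profiled likelihood in the variance ratio
lambda = s2_u / s2_e: given lambda, the GLS estimate of beta and the
residual variance are closed-form, so :func:`fit_lmm` optimises a scalar
function — fast, deterministic, and exact at the lambda = 0 boundary.

Effect sizes follow the local-f² construction for mixed models: with
R²(m) = 1 - s2_e(m) / s2_e(null) measured against the intercept-plus-
random-intercept null,

    f² = (R²_full - R²_reduced) / (1 - R²_full),

i.e. the variance uniquely explained by the tested effect relative to
the variance the full model leaves unexplained.  Confidence intervals
come from a cluster bootstrap: whole players (or team compositions) are
resampled with replacement so the repeated-measures covariance survives
resampling.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SingularFitWarning",
    "ModelSpec",
    "LMMFit",
    "EffectTest",
    "build_design",
    "fit_lmm",
    "lrt",
    "local_f2",
    "bootstrap_ci",
    "categorize_f2",
    "analyze_metric",
    "F2_THRESHOLDS",
    "F2_THRESHOLDS_TABLE",
]

#: Effect-size category cut points (small, medium, large).
F2_THRESHOLDS = (0.02, 0.13, 0.26)
#: Alternative cut points sometimes used for f²-style effect sizes
#: (reported alongside, never silently swapped in).
F2_THRESHOLDS_TABLE = (0.02, 0.15, 0.35)

F2_CATEGORIES = ("negligible", "small", "medium", "large")


class SingularFitWarning(UserWarning):
    """Raised (as a warning) when the random-intercept variance is
    estimated at the zero boundary."""


@dataclass
class ModelSpec:
    """Declarative description of one mixed model.

    ``population`` restricts the rows before fitting: ``pooled`` keeps
    everything, ``early_only`` / ``late_only`` keep one maturity band
    (in which case ``maturation`` may not appear among the fixed
    effects — it would be constant).
    """

    response: str
    fixed: tuple = ()
    group: str = "player_id"
    population: str = "pooled"

    def __post_init__(self):
        if self.population not in ("pooled", "early_only", "late_only"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.population != "pooled" and "band" in self.fixed:
            raise ValueError(
                "maturation can only be a fixed effect in the pooled "
                "population")

    def select(self, rows: pd.DataFrame) -> pd.DataFrame:
        if self.population == "early_only":
            return rows.loc[rows["band"] == "Early"]
        if self.population == "late_only":
            return rows.loc[rows["band"] == "Late"]
        return rows


@dataclass
class LMMFit:
    """A fitted random-intercept linear mixed model (ML)."""

    response: str
    fixed: tuple
    group: str
    exog_names: list
    params: pd.Series
    llf: float
    sigma2_resid: float
    sigma2_group: float
    n_obs: int
    k_fixed: int
    converged: bool = True

    @property
    def lam(self) -> float:
        return self.sigma2_group / self.sigma2_resid


def build_design(rows: pd.DataFrame, fixed,
                 ref_levels: dict | None = None):
    """Treatment-coded design matrix for categorical fixed effects.

    Each factor's reference level is ``ref_levels[factor]`` when given,
    else its first level in sorted order.  Returns ``(X, names)``.
    """
    ref_levels = ref_levels or {}
    n = len(rows)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for factor in fixed:
        levels = sorted(map(str, rows[factor].unique()))
        ref = str(ref_levels.get(factor, levels[0]))
        if ref not in levels:
            # e.g. no Early/Early games in a Late-only subset; the tests
            # and effect sizes are invariant to the parametrisation
            ref = levels[0]
        vals = rows[factor].astype(str).to_numpy()
        for lev in levels:
            if lev == ref:
                continue
            cols.append((vals == lev).astype(float))
            names.append(f"{factor}[{lev}]")
    return np.column_stack(cols), names


def _profile_nll(lam, y, X, group_idx, n_groups):
    """Negative profiled ML log-likelihood at variance ratio lam.

    Uses the Woodbury form of the block inverse: within a group of size
    n_g, V^-1 = (1/s2_e) (I - lam/(1 + lam n_g) J).
    """
    n, k = X.shape
    n_g = np.bincount(group_idx, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * n_g)  # per-group shrinkage of the group sum

    Xs = np.zeros((n_groups, k))
    for j in range(k):
        Xs[:, j] = np.bincount(group_idx, weights=X[:, j],
                               minlength=n_groups)
    ys = np.bincount(group_idx, weights=y, minlength=n_groups)

    XtVX = X.T @ X - (Xs * c[:, None]).T @ Xs
    XtVy = X.T @ y - Xs.T @ (c * ys)
    beta, *_ = np.linalg.lstsq(XtVX, XtVy, rcond=None)
    r = y - X @ beta
    rs = np.bincount(group_idx, weights=r, minlength=n_groups)
    quad = float(r @ r - c @ (rs * rs))
    sigma2 = quad / n
    if sigma2 <= 0:
        return np.inf, beta, sigma2
    logdet = float(np.sum(np.log1p(lam * n_g)))
    llf = -0.5 * (n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)
    return -llf, beta, sigma2


def fit_lmm(rows: pd.DataFrame, spec: ModelSpec | None = None, *,
            response: str | None = None, fixed=(), group: str = "player_id",
            ref_levels: dict | None = None) -> LMMFit:
    """ML fit of ``response ~ fixed effects + (1 | group)``.

    Either pass a :class:`ModelSpec` or the keyword pieces.  Rows with a
    missing response are dropped.  The variance ratio is profiled out and
    optimised by bounded scalar search; a boundary estimate (zero group
    variance) triggers :class:`SingularFitWarning` and returns the
    documented boundary fit, which coincides with ordinary least squares.
    """
    if spec is not None:
        response, fixed, group = spec.response, spec.fixed, spec.group
        rows = spec.select(rows)
    if response is None:
        raise TypeError("response is required")
    fixed = tuple(fixed)
    rows = rows.loc[rows[response].notna()]
    if not len(rows):
        raise ValueError("no rows with a non-missing response")
    y = rows[response].to_numpy(dtype=float)
    X, names = build_design(rows, fixed, ref_levels)
    codes, uniques = pd.factorize(rows[group], sort=True)
    n_groups = len(uniques)

    if np.allclose(y, y[0]):
        # degenerate constant response: zero variance components
        beta = np.zeros(X.shape[1])
        beta[0] = y[0]
        return LMMFit(response, fixed, group, names,
                      pd.Series(beta, index=names), llf=math.inf,
                      sigma2_resid=0.0, sigma2_group=0.0, n_obs=len(y),
                      k_fixed=int(np.linalg.matrix_rank(X)))

    # coarse deterministic grid on lambda (0 and log-spaced), then refine
    grid = np.concatenate([[0.0], np.logspace(-6, 4, 41)])
    vals = [_profile_nll(l, y, X, codes, n_groups)[0] for l in grid]
    best = int(np.argmin(vals))
    if best == 0:
        lam_hat = 0.0
    else:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda l: _profile_nll(l, y, X, codes, n_groups)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        lam_hat = float(res.x)
        if _profile_nll(0.0, y, X, codes, n_groups)[0] <= res.fun:
            lam_hat = 0.0
    nll_hat, beta, sigma2 = _profile_nll(lam_hat, y, X, codes, n_groups)
    if lam_hat == 0.0:
        warnings.warn(
            "random-intercept variance estimated at the zero boundary; "
            "fit coincides with OLS", SingularFitWarning, stacklevel=2)
    return LMMFit(
        response=response, fixed=fixed, group=group, exog_names=names,
        params=pd.Series(beta, index=names), llf=-nll_hat,
        sigma2_resid=sigma2, sigma2_group=lam_hat * sigma2,
        n_obs=len(y), k_fixed=int(np.linalg.matrix_rank(X)))


def lrt(full: LMMFit, reduced: LMMFit):
    """Generalized likelihood-ratio test of nested ML fits.

    Returns ``(stat, df, p)`` with the statistic clipped at zero and the
    p-value from the chi-squared upper tail with df = difference in the
    number of fixed-effect parameters.
    """
    if full.n_obs != reduced.n_obs or full.response != reduced.response:
        raise ValueError("models must be fitted to identical rows")
    if not set(reduced.exog_names) <= set(full.exog_names):
        raise ValueError(
            f"models are not nested: {set(reduced.exog_names) - set(full.exog_names)} "
            "only in the reduced model")
    df = full.k_fixed - reduced.k_fixed
    if math.isinf(full.llf) and math.isinf(reduced.llf):
        stat = 0.0  # degenerate constant-response fits
    else:
        stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def local_f2(full: LMMFit, reduced: LMMFit, null: LMMFit) -> float:
    """Local Cohen's f² of the effect dropped between full and reduced.

    Residual-variance R² is measured against the intercept + random
    intercept null; the result is clipped at zero.  A saturated full
    model (zero residual variance) yields ``math.inf``.
    """
    if null.sigma2_resid <= 0:
        return 0.0
    r2_full = 1.0 - full.sigma2_resid / null.sigma2_resid
    r2_red = 1.0 - reduced.sigma2_resid / null.sigma2_resid
    denom = 1.0 - r2_full
    if denom <= 0:
        return math.inf
    return max(0.0, (r2_full - r2_red) / denom)


def _fit_triplet(rows, response, fixed, effect, group, ref_levels=None):
    fixed = tuple(fixed)
    if effect not in fixed:
        raise ValueError(f"effect {effect!r} not among fixed terms {fixed}")
    reduced_fixed = tuple(f for f in fixed if f != effect)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SingularFitWarning)
        full = fit_lmm(rows, response=response, fixed=fixed, group=group,
                       ref_levels=ref_levels)
        reduced = fit_lmm(rows, response=response, fixed=reduced_fixed,
                          group=group, ref_levels=ref_levels)
        null = fit_lmm(rows, response=response, fixed=(), group=group)
    return full, reduced, null


def bootstrap_ci(rows: pd.DataFrame, response: str, fixed, effect: str,
                 group: str = "player_id", B: int = 1000,
                 seed: int = 0, ref_levels: dict | None = None):
    """Percentile 95% CI for local f² by cluster bootstrap.

    Whole groups (players / team compositions) are resampled with
    replacement, carrying all their rows; each resampled cluster gets a
    fresh label so repeated draws stay distinct.  Resamples whose fit
    fails are skipped and counted; more than 10% failures aborts.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(seed)
    rows = rows.loc[rows[response].notna()]
    ids = np.sort(rows[group].unique())
    by_group = {g: sub for g, sub in rows.groupby(group, sort=True)}
    if len(ids) < 2:
        warnings.warn("degenerate bootstrap: fewer than 2 clusters",
                      UserWarning, stacklevel=2)
    stats_ = []
    failures = 0
    for b in range(B):
        draw = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for k, g in enumerate(draw):
            part = by_group[g].copy()
            part[group] = f"{g}#{k}"
            parts.append(part)
        sample = pd.concat(parts, ignore_index=True)
        try:
            full, reduced, null = _fit_triplet(
                sample, response, fixed, effect, group, ref_levels)
            stats_.append(local_f2(full, reduced, null))
        except (np.linalg.LinAlgError, ValueError):
            failures += 1
    if failures > 0.1 * B:
        raise RuntimeError(
            f"cluster bootstrap failed in {failures}/{B} resamples")
    lo, hi = np.percentile(np.asarray(stats_), [2.5, 97.5])
    return float(lo), float(hi)


def categorize_f2(f2: float, thresholds=F2_THRESHOLDS) -> str:
    """Label an f² value negligible / small / medium / large.

    Bins are left-closed: ``small <= f2 < medium`` is "small", etc.
    """
    if f2 < 0:
        raise ValueError("f2 must be non-negative")
    small, medium, large = thresholds
    if f2 < small:
        return "negligible"
    if f2 < medium:
        return "small"
    if f2 < large:
        return "medium"
    return "large"


@dataclass
class EffectTest:
    """One fixed effect's complete inferential summary."""

    metric: str
    population: str
    effect: str
    lrt_stat: float
    df: int
    p_value: float
    f2: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    category: str = ""

    def to_row(self) -> dict:
        return dataclasses.asdict(self)


def analyze_metric(rows: pd.DataFrame, response: str, fixed,
                   group: str = "player_id", population: str = "pooled",
                   effects=None, bootstrap_B: int = 0, seed: int = 0,
                   thresholds=F2_THRESHOLDS,
                   ref_levels: dict | None = None) -> list:
    """Run the full effect-by-effect analysis of one metric.

    For each tested effect the full model (all fixed terms) is compared
    with the model dropping that effect (LRT p-value, local f²); with
    ``bootstrap_B > 0`` a cluster-bootstrap CI is added.  Returns a list
    of :class:`EffectTest`.
    """
    spec = ModelSpec(response=response, fixed=tuple(fixed), group=group,
                     population=population)
    rows = spec.select(rows)
    effects = list(effects) if effects is not None else list(fixed)
    out = []
    for effect in effects:
        full, reduced, null = _fit_triplet(
            rows, response, fixed, effect, group, ref_levels)
        stat, df, p = lrt(full, reduced)
        f2 = local_f2(full, reduced, null)
        ci_low = ci_high = math.nan
        if bootstrap_B:
            ci_low, ci_high = bootstrap_ci(
                rows, response, fixed, effect, group=group, B=bootstrap_B,
                seed=seed, ref_levels=ref_levels)
        out.append(EffectTest(
            metric=response, population=population, effect=effect,
            lrt_stat=stat, df=df, p_value=p, f2=f2,
            ci_low=ci_low, ci_high=ci_high,
            category=categorize_f2(min(f2, 1e9), thresholds)))
    return out
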