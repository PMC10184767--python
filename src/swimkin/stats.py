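"""Treatment statistics for the trial table.

Each kinematic variable is fitted to a linear mixed model — swimming speed
as covariate, viscosity, light and lateral-line condition as fixed factors,
individual fish as a random intercept — optionally with a distinct residual
variance per level of a grouping factor (the varIdent-style weighting used
when treatments also change the noise level).  Treatment effects are then
compared through estimated marginal means on the full factorial reference
grid with Bonferroni-adjusted pairwise contrasts, and pectoral fin-state
counts are compared with a two-sided exact test on the margin-conditioned
table distribution.

The mixed model is fitted by restricted maximum likelihood directly: with a
random intercept per fish the per-fish covariance block is
``V_i = σ_b² 11' + diag(σ²_g)``, which inverts in closed form
(Sherman–Morrison), so the profile REML criterion over the variance
parameters is cheap to optimize even for hundreds of replicate fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats as sstats

from .exceptions import SwimkinError

__all__ = [
    "MixedModelFit",
    "ContrastResult",
    "validate_trial_table",
    "fit_variable_model",
    "emmeans_contrasts",
    "fisher_exact",
    "screen_outliers",
]

FACTORS = ("viscosity", "light", "lateral_line")
COVARIATE = "swim_speed_U"
GROUPING = "fish_id"


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the trial table carries the design columns with legal levels."""
    needed = {GROUPING, *FACTORS}
    missing = needed - set(table.columns)
    if missing:
        raise SwimkinError(f"trial table lacks columns: {sorted(missing)}")
    from .synthetic import FACTOR_LEVELS

    for factor, levels in FACTOR_LEVELS.items():
        bad = set(table[factor].unique()) - set(levels)
        if bad:
            raise SwimkinError(f"unknown {factor} levels: {sorted(bad)}")
    if table[GROUPING].nunique() < 2:
        raise SwimkinError("at least 2 fish are required for a mixed fit")
    return table


def build_formula(
    response: str,
    covariate: str | None = COVARIATE,
    interactions: str = "two-way",
) -> str:
    """Fixed-effects formula: covariate + factors (+ two-way factor interactions)."""
    terms = []
    if covariate and covariate != response:
        terms.append(covariate)
    fac = [f"C({f})" for f in FACTORS]
    if interactions == "two-way":
        terms += fac + [f"{a}:{b}" for i, a in enumerate(fac) for b in fac[i + 1 :]]
    elif interactions == "none":
        terms += fac
    else:
        raise ValueError(f"unknown interaction structure {interactions!r}")
    return " + ".join(terms)


@dataclass
class MixedModelFit:
    """A fitted random-intercept linear mixed model (REML)."""

    response: str
    formula: str
    params: pd.Series
    cov_params: pd.DataFrame
    sigma_fish: float
    sigma_resid: dict  # variance-group level -> residual sd
    variance_groups: str | None
    df_resid: int
    n_obs: int
    loglik_reml: float
    converged: bool
    design_info: object
    data: pd.DataFrame
    fitted: np.ndarray
    resid_conditional: np.ndarray  # y - Xβ - b̂
    random_effects: dict  # fish -> b̂
    resid_group: np.ndarray  # per-row variance-group label
    singular: bool = False

    @property
    def resid_studentized(self) -> np.ndarray:
        sd = np.array([self.sigma_resid[g] for g in self.resid_group])
        sd = np.where(sd <= 0, np.nan, sd)
        return self.resid_conditional / sd

    def summary(self) -> str:
        lines = [
            f"Linear mixed model (REML): {self.response} ~ {self.formula}",
            f"  random intercept: {GROUPING} (sd = {self.sigma_fish:.4g})",
            f"  n = {self.n_obs}, residual df = {self.df_resid}, "
            f"REML loglik = {self.loglik_reml:.3f}",
        ]
        if self.variance_groups:
            lines.append(
                "  residual sd by "
                + self.variance_groups
                + ": "
                + ", ".join(f"{k}={v:.4g}" for k, v in self.sigma_resid.items())
            )
        else:
            lines.append(f"  residual sd = {next(iter(self.sigma_resid.values())):.4g}")
        if self.singular:
            lines.append("  [boundary fit: between-fish variance ≈ 0]")
        lines.append("  Fixed effects:")
        se = np.sqrt(np.diag(self.cov_params.values))
        for name, beta, s in zip(self.params.index, self.params.values, se):
            t = beta / s if s > 0 else np.nan
            p = 2 * sstats.t.sf(abs(t), self.df_resid)
            lines.append(f"    {name:38s} {beta:10.4f}  SE {s:8.4f}  t {t:7.2f}  p {p:.4g}")
        return "\n".join(lines)


def _reml_objective(log_params, y_g, X_g, D_idx_g, n_var):
    """-2 × REML log-likelihood for the random-intercept heteroscedastic model."""
    sb2 = math.exp(log_params[0])
    sg2 = np.exp(log_params[1 : 1 + n_var])
    XtViX = 0.0
    XtViy = 0.0
    logdet = 0.0
    quad_parts = []
    for y, X, didx in zip(y_g, X_g, D_idx_g):
        d = sg2[didx]
        di = 1.0 / d
        denom = 1.0 + sb2 * di.sum()
        # Sherman–Morrison: V^-1 z = D^-1 z − σb² (D^-1 1)(1' D^-1 z)/denom
        ViX = X * di[:, None] - (sb2 / denom) * np.outer(di, di @ X)
        Viy = y * di - (sb2 / denom) * di * (di @ y)
        XtViX = XtViX + X.T @ ViX
        XtViy = XtViy + X.T @ Viy
        logdet += np.log(d).sum() + math.log(denom)
        quad_parts.append((y, X, Viy, ViX))
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return 1e12, None, None
    quad = 0.0
    for y, X, Viy, ViX in quad_parts:
        r_vi = Viy - ViX @ beta
        quad += (y - X @ beta) @ r_vi
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12, None, None
    return logdet + logdet_XtViX + quad, beta, XtViX


def fit_variable_model(
    table: pd.DataFrame,
    response: str,
    variance_groups: str | None = None,
    covariate: str | None = COVARIATE,
    interactions: str = "two-way",
) -> MixedModelFit:
    """REML fit of ``response ~ covariate + factors (+ interactions)`` with a
    per-fish random intercept and, optionally, per-level residual variances.

    Rows with a missing response (e.g. unrecorded fin frequency) are dropped
    from this variable's fit only.  A boundary fit with zero between-fish
    variance is retained with a warning, mirroring a singular-fit report.
    """
    validate_trial_table(table)
    data = table.dropna(subset=[response]).reset_index(drop=True).copy()
    if len(data) < 10:
        raise SwimkinError(
            f"response {response!r} present for only {len(data)} rows (need ≥ 10)"
        )
    formula = build_formula(response, covariate, interactions)
    y_dm, X_dm = patsy.dmatrices(f"{response} ~ {formula}", data, return_type="dataframe")
    X = np.asarray(X_dm, float)
    y = np.asarray(y_dm, float).ravel()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SwimkinError(
            f"rank-deficient fixed-effects design for {response}: check for "
            "empty factor cells"
        )

    if variance_groups is None:
        group_labels = np.array(["all"] * len(data), dtype=object)
        var_levels = ["all"]
    else:
        group_labels = data[variance_groups].astype(str).to_numpy()
        var_levels = sorted(set(group_labels))
    didx = np.array([var_levels.index(g) for g in group_labels])

    fish = data[GROUPING].to_numpy()
    fish_levels = sorted(set(fish))
    y_g, X_g, D_idx_g, rows_g = [], [], [], []
    for fl in fish_levels:
        m = fish == fl
        y_g.append(y[m])
        X_g.append(X[m])
        D_idx_g.append(didx[m])
        rows_g.append(np.nonzero(m)[0])

    # start values from OLS residual variance
    beta0, res0, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2_0 = max(float(np.var(y - X @ beta0)), 1e-10)
    x0 = np.concatenate([[math.log(s2_0 / 2)], np.full(len(var_levels), math.log(s2_0))])

    def obj(lp):
        val, _, _ = _reml_objective(lp, y_g, X_g, D_idx_g, len(var_levels))
        return val

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        opt = optimize.minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=[(-25.0, 15.0)] * len(x0),
            options={"maxiter": 500},
        )
    if not opt.success and variance_groups is not None and not np.isfinite(opt.fun):
        raise SwimkinError(
            f"variance weights for {response} by {variance_groups} did not "
            "converge; retry without variance_groups (unweighted fallback)"
        )
    val, beta, XtViX = _reml_objective(opt.x, y_g, X_g, D_idx_g, len(var_levels))
    if beta is None:
        raise SwimkinError(f"mixed-model fit failed for {response}")
    sb2 = math.exp(opt.x[0])
    sg2 = np.exp(opt.x[1 : 1 + len(var_levels)])
    singular = sb2 < max(1e-10, 1e-8 * sg2.max())
    if singular:
        warnings.warn(
            f"singular fit for {response}: between-fish variance at the zero "
            "boundary; fit retained"
        )

    cov_beta = np.linalg.inv(XtViX)
    names = list(X_dm.columns)
    fitted = X @ beta

    # BLUP random intercepts and conditional residuals
    b_hat = {}
    resid = np.empty_like(y)
    for fl, yy, XX, dd, rows in zip(fish_levels, y_g, X_g, D_idx_g, rows_g):
        r = yy - XX @ beta
        di = 1.0 / sg2[dd]
        denom = 1.0 + sb2 * di.sum()
        b = sb2 * (di @ r) / denom
        b_hat[fl] = float(b)
        resid[rows] = r - b

    df_resid = len(y) - X.shape[1]
    return MixedModelFit(
        response=response,
        formula=formula,
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma_fish=math.sqrt(sb2),
        sigma_resid={lv: math.sqrt(v) for lv, v in zip(var_levels, sg2)},
        variance_groups=variance_groups,
        df_resid=df_resid,
        n_obs=len(y),
        loglik_reml=-0.5 * val,
        converged=bool(opt.success),
        design_info=X_dm.design_info,
        data=data,
        fitted=fitted,
        resid_conditional=resid,
        random_effects=b_hat,
        resid_group=group_labels,
        singular=singular,
    )


@dataclass
class ContrastResult:
    """One pairwise estimated-marginal-means contrast."""

    variable: str
    factor: str
    pair: tuple
    estimate: float
    std_error: float
    df: int
    t_value: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = self.p_adjusted < 0.05


def emmeans_contrasts(
    fit: MixedModelFit,
    factors: tuple = FACTORS,
    n_comparisons: int | None = None,
    alpha: float = 0.05,
) -> list:
    """Pairwise EMM contrasts per factor, Bonferroni-adjusted.

    Estimated marginal means are model predictions on the full factorial
    reference grid at the covariate mean, averaged with equal weights over
    the non-focal factors; differences use the fitted coefficient covariance
    and residual df.  ``n_comparisons`` defaults to the number of contrasts
    produced (the per-variable Bonferroni family).
    """
    from .synthetic import FACTOR_LEVELS

    from itertools import combinations, product

    grid_rows = []
    for combo in product(*(FACTOR_LEVELS[f] for f in FACTORS)):
        row = dict(zip(FACTORS, combo))
        if COVARIATE in fit.data.columns and COVARIATE != fit.response:
            row[COVARIATE] = float(fit.data[COVARIATE].mean())
        grid_rows.append(row)
    grid = pd.DataFrame(grid_rows)
    (Xg,) = patsy.build_design_matrices([fit.design_info], grid)
    Xg = np.asarray(Xg, float)

    contrasts = []
    specs = []
    for factor in factors:
        levels = FACTOR_LEVELS[factor]
        for a, b in combinations(levels, 2):
            La = Xg[grid[factor] == a].mean(axis=0)
            Lb = Xg[grid[factor] == b].mean(axis=0)
            specs.append((factor, (a, b), La - Lb))
    m = n_comparisons if n_comparisons is not None else len(specs)
    beta = fit.params.values
    C = fit.cov_params.values
    for factor, pair, L in specs:
        est = float(L @ beta)
        se = float(np.sqrt(L @ C @ L))
        t = est / se if se > 0 else np.nan
        p = float(2 * sstats.t.sf(abs(t), fit.df_resid))
        contrasts.append(
            ContrastResult(
                variable=fit.response,
                factor=factor,
                pair=pair,
                estimate=est,
                std_error=se,
                df=fit.df_resid,
                t_value=t,
                p_raw=p,
                p_adjusted=min(1.0, p * m),
                n_comparisons=m,
            )
        )
    return contrasts


def contrasts_frame(contrasts: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [c.variable for c in contrasts],
            "factor": [c.factor for c in contrasts],
            "level_a": [c.pair[0] for c in contrasts],
            "level_b": [c.pair[1] for c in contrasts],
            "estimate": [c.estimate for c in contrasts],
            "std_error": [c.std_error for c in contrasts],
            "df": [c.df for c in contrasts],
            "t_value": [c.t_value for c in contrasts],
            "p_raw": [c.p_raw for c in contrasts],
            "p_adjusted": [c.p_adjusted for c in contrasts],
            "n_comparisons": [c.n_comparisons for c in contrasts],
            "significant": [c.significant for c in contrasts],
        }
    )


def fisher_exact(table) -> float:
    """Two-sided exact test on a 2×K contingency table.

    Conditions on both margins and enumerates every table with the observed
    margins, summing the (multivariate) hypergeometric probabilities of
    tables no more probable than the observed one.  All arithmetic is exact
    (integer binomial weights), so ties are handled without floating-point
    tolerance.  A zero row or column margin makes the table degenerate:
    p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError(f"need a 2×K table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        tt = np.rint(t).astype(np.int64)
        if np.any(np.abs(tt - t) > 1e-9) or np.any(tt < 0):
            raise ValueError("table must hold non-negative integers")
        t = tt
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if n > 10_000:
        raise ValueError(f"exact enumeration limited to n ≤ 10000, got {n}")
    if np.any(row == 0) or np.any(col == 0):
        warnings.warn("degenerate margin (zero row or column sum): p = 1")
        return 1.0

    r1 = int(row[0])
    cols = [int(c) for c in col]
    w_obs = math.prod(math.comb(c, a) for c, a in zip(cols, t[0]))

    total = 0  # sum of weights ≤ w_obs
    K = len(cols)
    # suffix sums of column totals for pruning
    suffix = [0] * (K + 1)
    for j in range(K - 1, -1, -1):
        suffix[j] = suffix[j + 1] + cols[j]

    def rec(j, remaining, weight):
        nonlocal total
        if j == K:
            if remaining == 0 and weight <= w_obs:
                total += weight
            return
        lo = max(0, remaining - suffix[j + 1])
        hi = min(cols[j], remaining)
        for a in range(lo, hi + 1):
            rec(j + 1, remaining - a, weight * math.comb(cols[j], a))

    rec(0, r1, 1)
    return float(total / math.comb(n, r1))


def screen_outliers(
    table: pd.DataFrame,
    response: str,
    fit: MixedModelFit | None = None,
    threshold: float = 3.0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Flag candidate outlier trials; removal is the user's call, never silent.

    A trial is flagged when its absolute studentized conditional residual
    exceeds ``threshold`` AND removing it improves the Shapiro–Wilk
    normality statistic of the remaining residuals.  Returns the fitted
    table with ``studentized_resid`` and ``outlier_flag`` columns.
    """
    if fit is None:
        fit = fit_variable_model(table, response, **fit_kwargs)
    r = fit.resid_studentized
    flags = np.zeros(len(r), dtype=bool)
    candidates = np.nonzero(np.abs(r) > threshold)[0]
    if len(candidates) and len(r) >= 4:
        w_all = sstats.shapiro(fit.resid_conditional).statistic
        for i in candidates:
            keep = np.ones(len(r), dtype=bool)
            keep[i] = False
            w_wo = sstats.shapiro(fit.resid_conditional[keep]).statistic
            flags[i] = w_wo > w_all
    out = fit.data.copy()
    out["studentized_resid"] = r
    out["outlier_flag"] = flags
    return out
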