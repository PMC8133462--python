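"""Aggregated multinomial-logit share regressions and marginal effects.

With i.i.d. Gumbel heterogeneity, individual location choice aggregates to
log-odds that are linear in covariates and fixed effects:

    ln(n_l) - ln(n_h) = gamma_{j,y,l} + delta_{t,l} + X_{j,y,t} b_l + eta,
                                                          l in {m, p, o},

so three independent OLS fits on the city-day-hour panel recover the
individual-level coefficients. Counterfactual shares come from inverting the
logit at shifted covariates; marginal effects are averages of counterfactual
share differences (level switch) or the analytic logit derivative at sample
means (continuous AQI). Confidence intervals are percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import design
from .panel import log_odds_wide

NON_HOME = ["m", "p", "o"]
LOCATIONS = ["h", "m", "p", "o"]


@dataclass
class ModelSpec:
    """Covariate specification for the share (and distance) regressions."""

    measure: str = "levels"              # "levels" | "aqi"
    interactions: str = "none"           # "none" | "t2"
    extra: list[str] = field(default_factory=list)  # extra panel columns

    def air_columns(self, levels=None) -> list[str]:
        return design.air_columns(self.measure, self.interactions, levels)


@dataclass
class ChoiceFit:
    """Three per-location OLS fits sharing one design matrix."""

    spec: ModelSpec
    results: dict                        # location -> statsmodels results
    X: pd.DataFrame                      # full design (FE + air + extra)
    air_cols: list[str]                  # air columns present in the design
    panel: pd.DataFrame
    lo_wide: pd.DataFrame                # observed log-odds (NaN where dropped)

    def params(self, loc: str) -> pd.Series:
        return self.results[loc].params

    def air_beta(self, loc: str) -> pd.Series:
        return self.results[loc].params[self.air_cols]

    def base_logodds(self, residuals: bool = True) -> np.ndarray:
        """(n, 3) fitted or observed log-odds over m, p, o.

        With residuals included this is exactly the observed log-odds
        (prediction + residual identity of OLS); rows dropped by the zero
        policy fall back to -inf, i.e. an observed share of zero.
        """
        Xa = self.X.to_numpy(dtype=float)
        fitted = np.column_stack(
            [Xa @ self.results[l].params.to_numpy() for l in NON_HOME])
        if not residuals:
            return fitted
        obs = self.lo_wide[[f"logodds_{l}" for l in NON_HOME]].to_numpy()
        return np.where(np.isnan(obs), -np.inf, obs)


def fit_share_logit(panel: pd.DataFrame, spec: ModelSpec,
                    zero_policy: str = "error") -> ChoiceFit:
    """Least squares of each location's log-odds on the shared design."""
    X = design.full_design(panel, spec.air_columns())
    if spec.extra:
        X = pd.concat([X, panel[spec.extra].astype(float)], axis=1)
        design._check_rank(X)
    if len(panel) < X.shape[1]:
        raise ValueError(f"panel has {len(panel)} rows but the design has "
                         f"{X.shape[1]} parameters")
    air_cols = [c for c in spec.air_columns() if c in X.columns]
    lo = log_odds_wide(panel, zero_policy)
    results = {}
    for l in NON_HOME:
        y = lo[f"logodds_{l}"]
        mask = y.notna().to_numpy()
        results[l] = sm.OLS(y[mask], X[mask]).fit()
    return ChoiceFit(spec=spec, results=results, X=X, air_cols=air_cols,
                     panel=panel, lo_wide=lo)


def invert_logit(v: np.ndarray) -> np.ndarray:
    """Shares (n, 4) over h,m,p,o from non-home log-odds v (n, 3)."""
    ev = np.exp(v)
    s_h = 1.0 / (1.0 + ev.sum(axis=1))
    return np.column_stack([s_h, ev * s_h[:, None]])


def counterfactual_shares(fit: ChoiceFit, scenario, *,
                          residuals: bool = True) -> pd.DataFrame:
    """Predicted shares per panel row under a pollution scenario.

    ``scenario`` is ``{"level": name}``, ``{"aqi": value}`` or ``"observed"``.
    With residuals included (the default) the observed scenario reproduces
    the observed shares exactly. Rows always sum to one.
    """
    base = fit.base_logodds(residuals=residuals)
    if scenario == "observed":
        v = base
    else:
        X_obs = fit.X[fit.air_cols].to_numpy() if fit.air_cols else \
            np.zeros((len(fit.panel), 0))
        X_scen = design.scenario_air_design(
            fit.panel, fit.air_cols, scenario).to_numpy()
        B = np.column_stack([fit.air_beta(l).to_numpy() for l in NON_HOME])
        v = base + (X_scen - X_obs) @ B
    out = pd.DataFrame(invert_logit(v), index=fit.panel.index,
                       columns=[f"s_{l}" for l in LOCATIONS])
    return out


@dataclass
class EffectResult:
    """Marginal effects per location with optional bootstrap CIs.

    ``table`` holds, per location h/m/p/o: the share change in percentage
    points, the percent change relative to the baseline share, and the head
    count change per one million people (pp x 10,000).
    """

    table: pd.DataFrame
    scenario: tuple

    def __repr__(self):
        return f"EffectResult{self.scenario}:\n{self.table.round(4)}"


def _effect_table(diff_mean: np.ndarray, base_mean: np.ndarray,
                  scenario) -> EffectResult:
    tab = pd.DataFrame(index=LOCATIONS)
    tab["delta_pp"] = diff_mean * 100.0
    tab["pct_change"] = np.where(base_mean > 0, diff_mean / base_mean * 100.0,
                                 np.nan)
    tab["per_million"] = tab["delta_pp"] * 10_000.0
    return EffectResult(table=tab, scenario=scenario)


def effect_level_switch(fit: ChoiceFit, from_level: str = "Good",
                        to_level: str = "Heavily Polluted", *,
                        residuals: bool = True,
                        rows: np.ndarray | None = None) -> EffectResult:
    """Average counterfactual share change when air quality switches level.

    For each panel row both scenarios are evaluated with all other variables
    at their observed values; the effect is the across-row average of the
    difference. Percent change is the averaged difference over the averaged
    baseline share. Effects over the four locations sum to zero by
    construction (shares live on the simplex).
    """
    s_to = counterfactual_shares(fit, {"level": to_level}, residuals=residuals)
    s_from = counterfactual_shares(fit, {"level": from_level},
                                   residuals=residuals)
    if rows is not None:
        s_to, s_from = s_to.iloc[rows], s_from.iloc[rows]
    diff = s_to.to_numpy().mean(axis=0) - s_from.to_numpy().mean(axis=0)
    return _effect_table(diff, s_from.to_numpy().mean(axis=0),
                         (from_level, to_level))


def effect_continuous(fit: ChoiceFit, delta: float = 10.0, *,
                      at_hour: float | None = None,
                      shares: np.ndarray | None = None) -> EffectResult:
    """Analytic marginal effect of a ``delta``-point AQI increase.

    Evaluated at the sample-mean shares. The derivative of the inverted
    logit is s_l*b_l - s_l * sum_l' b_l' s_l' for l in {m,p,o} and
    -s_h * sum_l' b_l' s_l' for home, where b_l is the AQI coefficient of
    location l (at hour ``at_hour`` when the spec has t, t^2 interactions).
    The four derivatives sum to zero identically.
    """
    if fit.spec.measure != "aqi":
        raise ValueError("continuous-AQI effect requires a continuous-AQI fit")
    if shares is None:
        shares = fit.panel[[f"share_{l}" for l in LOCATIONS]].mean().to_numpy()
    b = np.empty(3)
    for i, l in enumerate(NON_HOME):
        p = fit.params(l)
        b[i] = p.get("aqi", 0.0)
        if fit.spec.interactions == "t2":
            if at_hour is None:
                raise ValueError("hour must be given for an interacted fit")
            b[i] += p.get("aqi:t", 0.0) * at_hour + p.get("aqi:t2", 0.0) * at_hour**2
    s_h, s_nh = shares[0], shares[1:]
    common = float(b @ s_nh)
    dds = np.concatenate([[-s_h * common], s_nh * b - s_nh * common]) * delta
    return _effect_table(dds, shares, ("aqi", f"+{delta}"))


def hourly_effects(fit: ChoiceFit, *, kind: str = "level_switch",
                   from_level: str = "Good", to_level: str = "Heavily Polluted",
                   delta: float = 10.0, residuals: bool = True) -> pd.DataFrame:
    """Per-hour marginal effects from a fit with t, t^2 interactions.

    Level-switch effects are stratum averages of the row-level counterfactual
    differences, so the size-weighted average over hours recomposes the
    pooled effect exactly. Continuous effects use stratum-mean shares and the
    hour-specific AQI coefficient.
    """
    frames = []
    hours = np.sort(fit.panel["hour"].unique())
    if kind == "level_switch":
        s_to = counterfactual_shares(fit, {"level": to_level},
                                     residuals=residuals).to_numpy()
        s_from = counterfactual_shares(fit, {"level": from_level},
                                       residuals=residuals).to_numpy()
        hour_col = fit.panel["hour"].to_numpy()
        for t in hours:
            m = hour_col == t
            eff = _effect_table(s_to[m].mean(axis=0) - s_from[m].mean(axis=0),
                                s_from[m].mean(axis=0), (from_level, to_level))
            frames.append(eff.table.assign(hour=t, n_rows=int(m.sum())))
    elif kind == "continuous":
        for t in hours:
            sub = fit.panel[fit.panel["hour"] == t]
            shares = sub[[f"share_{l}" for l in LOCATIONS]].mean().to_numpy()
            at = float(t) if fit.spec.interactions == "t2" else None
            eff = effect_continuous(fit, delta, at_hour=at, shares=shares)
            frames.append(eff.table.assign(hour=t, n_rows=len(sub)))
    else:
        raise ValueError(f"unknown effect kind {kind!r}")
    out = pd.concat(frames).reset_index(names="location")
    return out


def bootstrap_ci(panel: pd.DataFrame, estimator, *, B: int = 500,
                 unit: str = "city-day", rng=None, seed: int | None = None,
                 alpha: float = 0.05, max_failures: float = 0.10):
    """Percentile bootstrap CIs for any panel -> Series estimator.

    ``unit="row"`` resamples panel cells (city-day-hour rows, which carry the
    i.i.d. cell shocks); ``unit="city-day"`` resamples whole city-day blocks
    to respect within-day dependence. Failed replicates (e.g. a resample
    without pollution-level contrast) are dropped and counted; more than
    ``max_failures`` of B is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed) if rng is None else rng
    if unit == "city-day":
        blocks = panel.groupby(["city", "day"], sort=True).indices
        keys = list(blocks)
    elif unit == "row":
        keys = None
    else:
        raise ValueError(f"unknown bootstrap unit {unit!r}")

    reps, failures = [], 0
    for _ in range(B):
        if keys is None:
            idx = rng.integers(0, len(panel), len(panel))
        else:
            picked = rng.integers(0, len(keys), len(keys))
            idx = np.concatenate([blocks[keys[i]] for i in picked])
        sample = panel.iloc[idx].reset_index(drop=True)
        try:
            reps.append(pd.Series(estimator(sample)))
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failures * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    rep = pd.DataFrame(reps)
    lo = rep.quantile(alpha / 2)
    hi = rep.quantile(1 - alpha / 2)
    out = pd.DataFrame({"lo": lo, "hi": hi})
    out.attrs["n_failed"] = failures
    out.attrs["B"] = B
    return out


def level_switch_estimator(spec: ModelSpec, from_level: str = "Good",
                           to_level: str = "Heavily Polluted",
                           zero_policy: str = "error", residuals: bool = True):
    """Panel -> flat Series of level-switch effects, for the bootstrap."""
    def est(panel: pd.DataFrame) -> pd.Series:
        fit = fit_share_logit(panel, spec, zero_policy)
        eff = effect_level_switch(fit, from_level, to_level,
                                  residuals=residuals)
        return flatten_effect(eff)
    return est


def flatten_effect(eff: EffectResult) -> pd.Series:
    t = eff.table
    out = {}
    for loc in t.index:
        for col in t.columns:
            out[f"{col}_{loc}"] = t.loc[loc, col]
    return pd.Series(out)


def effect_with_ci(panel: pd.DataFrame, spec: ModelSpec, *,
                   from_level: str = "Good", to_level: str = "Heavily Polluted",
                   B: int = 500, unit: str = "city-day",
                   seed: int | None = None, zero_policy: str = "error",
                   residuals: bool = True) -> pd.DataFrame:
    """Level-switch effect table with percentile bootstrap CIs attached."""
    fit = fit_share_logit(panel, spec, zero_policy)
    eff = effect_level_switch(fit, from_level, to_level, residuals=residuals)
    ci = bootstrap_ci(panel, level_switch_estimator(spec, from_level, to_level,
                                                    zero_policy, residuals),
                      B=B, unit=unit, seed=seed)
    tab = eff.table.copy()
    for col in ("delta_pp", "pct_change", "per_million"):
        tab[f"{col}_lo"] = [ci.loc[f"{col}_{loc}", "lo"] for loc in tab.index]
        tab[f"{col}_hi"] = [ci.loc[f"{col}_{loc}", "hi"] for loc in tab.index]
    tab.attrs.update(ci.attrs)
    return tab
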