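"""Censored regression of hourly distance from home.

The latent intended distance is linear in covariates and fixed effects with
normal errors; the observed distance is censored below at 0 m and above at
50,000 m (every phone-hour at least 50 km out is pooled). The doubly-censored
normal log-likelihood is maximized by quasi-Newton iterations with an
analytic gradient, starting from OLS; sigma is parameterized on the log scale
so the optimization is unconstrained.

Interval midpoints are treated as exact values, matching the way the binned
distances enter the analysis; an interval likelihood is a non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import design
from .choice import ModelSpec


@dataclass
class TobitFit:
    params: pd.Series                    # named coefficients (latent scale)
    sigma: float
    se: pd.Series                        # asymptotic SEs incl. "log_sigma"
    loglike: float
    converged: bool
    n_obs: int
    n_lower: int
    n_upper: int
    lower: float
    upper: float
    trace: list = field(default_factory=list)
    X: pd.DataFrame | None = None
    frame: pd.DataFrame | None = None
    spec: ModelSpec | None = None
    air_cols: list[str] = field(default_factory=list)

    @property
    def se_sigma(self) -> float:
        # delta method from the log-scale parameterization
        return float(self.se["log_sigma"] * self.sigma)


def _loglike_and_grad(theta, X, y, lower, upper, interior, lo_mask, up_mask):
    beta, logsig = theta[:-1], theta[-1]
    sig = np.exp(logsig)
    mu = X @ beta
    ll = 0.0
    dmu = np.zeros(len(y))
    dls = 0.0
    if interior.any():
        r = (y[interior] - mu[interior]) / sig
        ll += float(np.sum(-0.5 * r**2 - 0.5 * np.log(2 * np.pi) - logsig))
        dmu[interior] = r / sig
        dls += float(np.sum(r**2 - 1.0))
    if lo_mask.any():
        a = (lower - mu[lo_mask]) / sig
        ll += float(np.sum(stats.norm.logcdf(a)))
        lam = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
        dmu[lo_mask] = -lam / sig
        dls += float(np.sum(-lam * a))
    if up_mask.any():
        b = (upper - mu[up_mask]) / sig
        ll += float(np.sum(stats.norm.logsf(b)))
        h = np.exp(stats.norm.logpdf(b) - stats.norm.logsf(b))
        dmu[up_mask] = h / sig
        dls += float(np.sum(h * b))
    grad = np.concatenate([X.T @ dmu, [dls]])
    return ll, grad


def tobit_mle(X: np.ndarray, y: np.ndarray, *, lower: float = 0.0,
              upper: float = 50_000.0, names=None,
              gtol_scale: float = 1e-6) -> TobitFit:
    """Maximize the doubly-censored normal likelihood.

    Observations at or below ``lower`` contribute the lower-tail probability,
    at or above ``upper`` the upper-tail probability, and interior ones the
    normal density. Raises when no interior observations identify the scale
    or when the optimizer fails to reach the gradient tolerance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lower >= upper:
        raise ValueError("lower limit must be below upper limit")
    lo_mask = y <= lower
    up_mask = y >= upper
    interior = ~(lo_mask | up_mask)
    if not interior.any():
        raise ValueError("all observations censored: model not identified")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("Tobit design matrix is rank deficient")

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sig0 = max(float(np.std(resid)), 1e-6)
    theta0 = np.concatenate([beta0, [np.log(sig0)]])

    trace = []

    def negll(theta):
        ll, g = _loglike_and_grad(theta, X, y, lower, upper,
                                  interior, lo_mask, up_mask)
        return -ll, -g

    def cb(theta):
        trace.append(-negll(theta)[0])

    res = optimize.minimize(negll, theta0, jac=True, method="BFGS",
                            callback=cb,
                            options={"gtol": 1e-10, "maxiter": 500})
    ll, grad = _loglike_and_grad(res.x, X, y, lower, upper,
                                 interior, lo_mask, up_mask)
    tol = gtol_scale * max(1.0, abs(ll))
    if np.max(np.abs(grad)) > tol:
        raise RuntimeError(
            f"Tobit optimizer did not converge: |grad|={np.max(np.abs(grad)):.3g} "
            f"> {tol:.3g} after {res.nit} iterations; trace={trace[-5:]}")

    H = _num_hessian(lambda th: _loglike_and_grad(
        th, X, y, lower, upper, interior, lo_mask, up_mask)[1], res.x)
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    p = X.shape[1]
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    return TobitFit(
        params=pd.Series(res.x[:p], index=names),
        sigma=float(np.exp(res.x[-1])),
        se=pd.Series(se, index=names + ["log_sigma"]),
        loglike=float(ll), converged=True, n_obs=len(y),
        n_lower=int(lo_mask.sum()), n_upper=int(up_mask.sum()),
        lower=lower, upper=upper, trace=trace)


def _num_hessian(grad_fn, theta, eps: float = 1e-5):
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        step = eps * max(1.0, abs(theta[i]))
        tp = theta.copy(); tp[i] += step
        tm = theta.copy(); tm[i] -= step
        H[:, i] = (grad_fn(tp) - grad_fn(tm)) / (2 * step)
    return (H + H.T) / 2


def fit_tobit(placements: pd.DataFrame, aqi: pd.DataFrame, spec: ModelSpec, *,
              lower: float = 0.0, upper: float = 50_000.0) -> TobitFit:
    """Tobit of binned distance from home on air quality and fixed effects.

    ``placements`` rows are phone-hours with ``distance_mid``; covariates are
    joined from the hourly AQI series by (city, day, hour). Lower censoring
    binds only for a recorded distance of 0 (with midpoint binning the
    smallest value is 50 m), upper censoring at the 50 km pool.
    """
    df = placements.merge(aqi[["city", "day", "hour", "aqi", "level"]],
                          on=["city", "day", "hour"], how="left")
    if df["aqi"].isna().any():
        missing = df[df["aqi"].isna()][["city", "day", "hour"]].iloc[0]
        raise ValueError(f"no AQI for cell {tuple(missing)}")
    X = design.full_design(df, spec.air_columns())
    y = df["distance_mid"].to_numpy(dtype=float)
    if "censored_upper" in df:
        y = np.where(df["censored_upper"].to_numpy(bool), upper, y)
    fit = tobit_mle(X.to_numpy(), y, lower=lower, upper=upper,
                    names=list(X.columns))
    fit.X = X
    fit.frame = df
    fit.spec = spec
    fit.air_cols = [c for c in spec.air_columns() if c in X.columns]
    return fit


def censored_mean(mu, sigma, lower, upper):
    """E[clip(N(mu, sigma), lower, upper)] for the doubly-censored normal."""
    mu = np.asarray(mu, dtype=float)
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    return lower * Fa + mu * (Fb - Fa) + sigma * (fa - fb) + upper * (1 - Fb)


def _scenario_mu(fit: TobitFit, scenario) -> np.ndarray:
    X_obs = fit.X[fit.air_cols].to_numpy() if fit.air_cols else \
        np.zeros((len(fit.frame), 0))
    X_scen = design.scenario_air_design(fit.frame, fit.air_cols,
                                        scenario).to_numpy()
    beta_air = fit.params[fit.air_cols].to_numpy()
    base = fit.X.to_numpy() @ fit.params.to_numpy()
    return base + (X_scen - X_obs) @ beta_air


def tobit_effect(fit: TobitFit, *, from_level: str = "Good",
                 to_level: str = "Heavily Polluted",
                 delta_aqi: float | None = None,
                 rows: np.ndarray | None = None) -> pd.Series:
    """Meters of change in distance from home under a pollution scenario.

    Reports both the latent effect (the coefficient contrast averaged over
    rows) and the expected-observed effect (average change of the censored
    mean E[d|x]); the two coincide when censoring never binds.
    """
    if delta_aqi is not None:
        if "aqi" not in {c.split(":")[0] for c in fit.air_cols}:
            raise ValueError("delta_aqi requires a continuous-AQI fit")
        obs_aqi = fit.frame["aqi"].to_numpy(dtype=float)
        X_obs = fit.X[fit.air_cols].to_numpy()
        base = fit.X.to_numpy() @ fit.params.to_numpy()
        shifted = fit.frame.assign(aqi=obs_aqi + delta_aqi)
        X_to = design.air_design(shifted, fit.air_cols).to_numpy()
        beta_air = fit.params[fit.air_cols].to_numpy()
        mu_from = base
        mu_to = base + (X_to - X_obs) @ beta_air
        label = ("aqi", f"+{delta_aqi}")
    else:
        mu_from = _scenario_mu(fit, {"level": from_level})
        mu_to = _scenario_mu(fit, {"level": to_level})
        label = (from_level, to_level)
    if rows is not None:
        mu_from, mu_to = mu_from[rows], mu_to[rows]
    latent = float(np.mean(mu_to - mu_from))
    e_to = censored_mean(mu_to, fit.sigma, fit.lower, fit.upper)
    e_from = censored_mean(mu_from, fit.sigma, fit.lower, fit.upper)
    expected = float(np.mean(e_to - e_from))
    return pd.Series({"latent_m": latent, "expected_observed_m": expected},
                     name=str(label))


def tobit_hourly(fit: TobitFit, *, from_level: str = "Good",
                 to_level: str = "Heavily Polluted",
                 delta_aqi: float | None = None) -> pd.DataFrame:
    """Per-hour scenario contrasts from a fit with t, t^2 interactions."""
    hours = np.sort(fit.frame["hour"].unique())
    hour_col = fit.frame["hour"].to_numpy()
    rows_list = []
    for t in hours:
        m = np.where(hour_col == t)[0]
        eff = tobit_effect(fit, from_level=from_level, to_level=to_level,
                           delta_aqi=delta_aqi, rows=m)
        rows_list.append({"hour": int(t), "n_rows": len(m), **eff.to_dict()})
    return pd.DataFrame(rows_list)


def summarize_distance(placements: pd.DataFrame) -> pd.DataFrame:
    """Median binned distance from home per (city, hour), pooled over days."""
    out = (placements.groupby(["city", "hour"])["distance_mid"]
           .median().reset_index(name="median_distance"))
    return out
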