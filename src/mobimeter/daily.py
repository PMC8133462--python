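"""Daily aggregates and the intra-day substitution comparison.

If individuals only reschedule activities within the day, daily average
shares are insensitive to daily pollution even though hourly shares respond
to hourly pollution. Regressing daily mean hourly shares (x1000) and daily
mean distance on daily AQI summaries with city and day fixed effects, and
comparing the coefficients to the hourly marginal effects, separates
cancellation from rescheduling: a daily/hourly ratio near 1 means no
substitution, near 0 perfect substitution, in between partial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

LOCATIONS = ["h", "m", "p", "o"]

AQI_MEASURES = ("max", "mean", "median", "official")


def build_daily(panel: pd.DataFrame,
                placements: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per (city, day): mean hourly shares x1000, AQI summaries.

    Every city-day must contain the full set of analysed hours. The
    "official" daily AQI has no public construction rule; the daily mean is
    used as a clearly-labelled stand-in (pluggable by replacing the column).
    When ``placements`` are given, the daily mean of per-hour mean distances
    is added.
    """
    hours = np.sort(panel["hour"].unique())
    miss = (panel.groupby(["city", "day"])["hour"]
            .apply(lambda h: len(set(hours) - set(h))))
    if (miss > 0).any():
        c, y = miss[miss > 0].index[0]
        raise ValueError(f"city {c} day {y} is missing {miss[(c, y)]} hours")

    g = panel.groupby(["city", "day"])
    out = pd.DataFrame({
        **{f"share_{l}_x1000": g[f"share_{l}"].mean() * 1000.0
           for l in LOCATIONS},
        "aqi_max": g["aqi"].max(),
        "aqi_mean": g["aqi"].mean(),
        "aqi_median": g["aqi"].median(),
    })
    out["aqi_official"] = out["aqi_mean"]      # stand-in; see docstring
    out = out.reset_index()

    if placements is not None:
        hourly_mean = (placements.groupby(["city", "day", "hour"])
                       ["distance_mid"].mean().reset_index())
        daily = (hourly_mean.groupby(["city", "day"])["distance_mid"]
                 .mean().rename("mean_distance"))
        out = out.merge(daily.reset_index(), on=["city", "day"], how="left")
    return out


def fit_daily(rows: pd.DataFrame, measure: str = "mean",
              outcome: str = "share_h_x1000"):
    """OLS of a daily outcome on one daily AQI summary + city & day FE.

    Small-sample normal-theory inference, as appropriate for a handful of
    city-days. Returns the statsmodels results object; the AQI coefficient
    is ``res.params["aqi"]``.
    """
    if measure not in AQI_MEASURES:
        raise ValueError(f"measure must be one of {AQI_MEASURES}")
    col = f"aqi_{measure}"
    X = pd.concat([
        pd.Series(1.0, index=rows.index, name="const"),
        pd.get_dummies(rows["city"].astype(str), prefix="city",
                       dtype=float, drop_first=True),
        pd.get_dummies(rows["day"].astype(str), prefix="day",
                       dtype=float, drop_first=True),
        rows[col].rename("aqi"),
    ], axis=1)
    df_resid = len(rows) - X.shape[1]
    if df_resid < 1:
        raise ValueError(
            f"insufficient degrees of freedom ({len(rows)} rows, "
            f"{X.shape[1]} parameters)")
    return sm.OLS(rows[outcome].astype(float), X).fit()


def compare_scales(hourly_pp_per_delta: pd.Series,
                   daily_results: dict, *, delta: float = 10.0,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Daily-vs-hourly effect ratio per location with CIs.

    ``hourly_pp_per_delta`` maps location -> hourly marginal effect in
    percentage points per ``delta`` AQI points. ``daily_results`` maps
    location -> fitted daily regression (share x1000 outcome). A daily
    coefficient of c (share x1000 per AQI point) equals c percentage points
    per 10 AQI points, so with the default delta the ratio is
    c / hourly_pp. Ratios strictly inside (0, 1) are flagged as partial
    substitution.
    """
    rows = []
    for loc, res in daily_results.items():
        c = res.params["aqi"]
        lo, hi = res.conf_int(alpha).loc["aqi"]
        scale = delta * 100.0 / 1000.0       # share x1000/AQI pt -> pp/delta
        daily_pp = c * scale
        h = float(hourly_pp_per_delta[loc])
        ratio = daily_pp / h if h != 0 else np.inf
        r_lo, r_hi = sorted((lo * scale / h, hi * scale / h)) if h != 0 \
            else (np.nan, np.nan)
        rows.append({
            "location": loc, "hourly_pp": h, "daily_pp": daily_pp,
            "ratio": ratio, "ratio_lo": r_lo, "ratio_hi": r_hi,
            "daily_p_value": float(res.pvalues["aqi"]),
            "partial_substitution": bool(0.0 < ratio < 1.0)})
    return pd.DataFrame(rows).set_index("location")
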