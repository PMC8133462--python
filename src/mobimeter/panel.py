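"""Aggregate labelled phone-hours into the city-day-hour panel.

The panel has one row per (city, day, hour) with the counts of phones at
home/park/mall/other, their shares, the hourly AQI and its official level.
All regressions downstream consume this frame (or the per-phone placements,
for the distance model). The log-odds ln(n_l) - ln(n_h) relative to home are
the dependent variables of the share regressions and are invariant to
rescaling all counts - the property that makes multi-phone ownership
harmless for the choice analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LOCATIONS = ["h", "m", "p", "o"]


def build_panel(labeled: pd.DataFrame, aqi: pd.DataFrame,
                covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per (city, day, hour) cell of the AQI grid.

    Every cell of the grid (restricted to analysed hours present in ``aqi``)
    must contain at least one labelled phone-hour; an empty cell is an error
    naming the cell. Optional ``covariates`` (indexed or keyed by city, day,
    hour) are left-joined; missing values stay null and are counted in
    ``attrs["missing_covariates"]``.
    """
    if not set(labeled["label"]) <= set(LOCATIONS):
        bad = set(labeled["label"]) - set(LOCATIONS)
        raise ValueError(f"unknown labels: {sorted(bad)}")
    counts = (labeled.groupby(["city", "day", "hour", "label"])
              .size().unstack("label", fill_value=0))
    for l in LOCATIONS:
        if l not in counts:
            counts[l] = 0
    counts = counts[LOCATIONS].add_prefix("n_")

    panel = aqi.merge(counts, left_on=["city", "day", "hour"],
                      right_index=True, how="left")
    empty = panel[panel[[f"n_{l}" for l in LOCATIONS]].isna().any(axis=1)
                  | (panel[[f"n_{l}" for l in LOCATIONS]].sum(axis=1) == 0)]
    if len(empty):
        cell = empty.iloc[0]
        raise ValueError(
            f"panel cell with no phones: city={cell['city']} day={cell['day']} "
            f"hour={cell['hour']}")
    for l in LOCATIONS:
        panel[f"n_{l}"] = panel[f"n_{l}"].astype(int)
    panel["n_total"] = sum(panel[f"n_{l}"] for l in LOCATIONS)
    for l in LOCATIONS:
        panel[f"share_{l}"] = panel[f"n_{l}"] / panel["n_total"]

    if covariates is not None:
        panel = panel.merge(covariates, on=["city", "day", "hour"], how="left")
        extra = [c for c in covariates.columns if c not in ("city", "day", "hour")]
        panel.attrs["missing_covariates"] = int(panel[extra].isna().sum().sum())
    return panel.reset_index(drop=True)


def log_odds(panel: pd.DataFrame, zero_policy: str = "error") -> pd.DataFrame:
    """Long frame of ln(n_l) - ln(n_h) for l in {m, p, o} per cell.

    Zero counts are handled per policy: ``error`` (default), ``add_half``
    (add 0.5 to all four counts of affected rows, a continuity correction for
    small panels), or ``drop`` (remove the affected log-odds rows). The number
    of affected rows is recorded in ``attrs["zero_count_rows"]``.
    """
    wide = log_odds_wide(panel, zero_policy)
    out = wide.melt(id_vars=["city", "day", "hour"], var_name="loc",
                    value_name="value")
    out["loc"] = out["loc"].str.replace("logodds_", "", regex=False)
    out = out.dropna(subset=["value"]).reset_index(drop=True)
    out.attrs.update(wide.attrs)
    return out


def log_odds_wide(panel: pd.DataFrame, zero_policy: str = "error") -> pd.DataFrame:
    counts = panel[["n_h", "n_m", "n_p", "n_o"]].to_numpy(dtype=float)
    zero_rows = (counts == 0).any(axis=1)
    n_zero = int(zero_rows.sum())
    if n_zero and zero_policy == "error":
        i = int(np.where(zero_rows)[0][0])
        raise ValueError(
            f"zero count in panel row {i} "
            f"(city={panel.iloc[i]['city']} day={panel.iloc[i]['day']} "
            f"hour={panel.iloc[i]['hour']}); choose a zero_policy or enlarge the panel")
    if zero_policy == "add_half":
        counts = counts + np.where(zero_rows[:, None], 0.5, 0.0)
    elif zero_policy not in ("error", "drop"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    out = panel[["city", "day", "hour"]].copy()
    with np.errstate(divide="ignore"):
        for i, l in enumerate(["m", "p", "o"], start=1):
            # ln(n_l) - ln(n_h) computed as ln(n_l/n_h): the count ratio is
            # what identifies the model, and the ratio form is exactly
            # invariant to rescaling every count by a common factor
            v = np.log(counts[:, i] / counts[:, 0])
            if zero_policy == "drop":
                v = np.where(np.isfinite(v), v, np.nan)
            out[f"logodds_{l}"] = v
    out.attrs["zero_count_rows"] = n_zero
    return out


def thin_users(placements: pd.DataFrame, k: float,
               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Keep each phone independently with probability 1/k.

    Emulates reducing a multi-phone sample (k phones per user on average) to
    one phone per user by dropping (k-1)/k of the phones; k = 1 is the
    identity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return placements.copy()
    rng = np.random.default_rng(0) if rng is None else rng
    phones = placements["phone_id"].unique()
    keep = phones[rng.random(len(phones)) < 1.0 / k]
    return placements[placements["phone_id"].isin(keep)].reset_index(drop=True)
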