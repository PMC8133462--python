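"""Regression design matrices shared by the generator and the estimators.

Both the location-choice (log-odds) and distance (Tobit) stages regress on the
same kind of design: air-quality covariates -- either official level dummies
with "Good" as the omitted base, or the AQI as a continuous variable,
optionally interacted with the hour t and t^2 -- plus city-day and hour fixed
effects. Column naming is the contract: interaction columns are
"<base>:t" and "<base>:t2".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aqi as aqi_mod

INTERACTION_SUFFIXES = (":t", ":t2")


def air_columns(measure: str, interactions: str = "none",
                levels: list[str] | None = None) -> list[str]:
    """Names of the air-quality covariate columns for a model spec."""
    if measure == "aqi":
        base = ["aqi"]
    elif measure == "levels":
        base = list(levels) if levels is not None else list(aqi_mod.DUMMY_LEVELS)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    if interactions == "none":
        return base
    if interactions == "t2":
        out = list(base)
        for c in base:
            out += [f"{c}:t", f"{c}:t2"]
        return out
    raise ValueError(f"unknown interactions {interactions!r}")


def air_design(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Evaluate named air-quality covariates on rows with aqi/level/hour.

    ``df`` needs columns ``aqi`` and ``hour`` (and ``level`` when level
    dummies are requested). Values for a level dummy are 1.0 where the row's
    level equals the dummy's level.
    """
    t = df["hour"].to_numpy(dtype=float)
    out = {}
    for col in columns:
        base, power = _split(col)
        if base == "aqi":
            v = df["aqi"].to_numpy(dtype=float)
        else:
            if base not in aqi_mod.LEVELS:
                raise ValueError(f"unknown air covariate {base!r}")
            level = df["level"] if "level" in df else aqi_mod.categorize(df["aqi"])
            v = (np.asarray(level, dtype=object) == base).astype(float)
        out[col] = v * t**power
    return pd.DataFrame(out, index=df.index)


def scenario_air_design(df: pd.DataFrame, columns: list[str],
                        scenario: dict) -> pd.DataFrame:
    """Air covariates with pollution pinned to a counterfactual scenario.

    ``scenario`` is ``{"level": name}`` (that level's dummy set to 1, all
    others 0; "Good" means all dummies 0) or ``{"aqi": value}``. Hour-dependent
    interaction terms still use each row's own hour.
    """
    if set(scenario) == {"level"}:
        name = scenario["level"]
        if name not in aqi_mod.LEVELS:
            raise ValueError(f"unknown air quality level {name!r}")
        known = {_split(c)[0] for c in columns if _split(c)[0] != "aqi"}
        if name != "Good" and name not in known:
            raise ValueError(
                f"level {name!r} has no dummy in this model (available: {sorted(known)})")
        mod = df.assign(level=name)
    elif set(scenario) == {"aqi"}:
        if "aqi" not in {_split(c)[0] for c in columns}:
            raise ValueError("scenario sets an AQI value but the model uses level dummies")
        mod = df.assign(aqi=float(scenario["aqi"]))
    else:
        raise ValueError("scenario must be {'level': name} or {'aqi': value}")
    return air_design(mod, columns)


def fixed_effects(df: pd.DataFrame) -> pd.DataFrame:
    """City-day and hour fixed-effect dummies, first category of each omitted.

    The reference coding is arbitrary; all reported effects are invariant to
    it. Returns an intercept column plus drop-first dummies.
    """
    cd = df["city"].astype(str) + "/" + df["day"].astype(str)
    hr = df["hour"].astype(int).astype(str)
    d_cd = pd.get_dummies(pd.Categorical(cd), prefix="cd", dtype=float, drop_first=True)
    d_hr = pd.get_dummies(pd.Categorical(hr, categories=sorted(hr.unique(), key=int)),
                          prefix="t", dtype=float, drop_first=True)
    out = pd.concat([pd.Series(1.0, index=df.index, name="const"),
                     d_cd.set_axis(df.index), d_hr.set_axis(df.index)], axis=1)
    return out


def full_design(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Fixed effects plus air covariates; drops all-zero air columns.

    A dummy for a level never observed in the data carries no information and
    would make the design singular, so such columns are removed (the list of
    kept columns is what the caller should treat as estimable).
    """
    X_air = air_design(df, columns)
    keep = [c for c in X_air.columns if np.any(X_air[c].to_numpy() != 0.0)]
    X = pd.concat([fixed_effects(df), X_air[keep]], axis=1)
    _check_rank(X)
    return X


def _split(col: str) -> tuple[str, int]:
    if col.endswith(":t2"):
        return col[:-3], 2
    if col.endswith(":t"):
        return col[:-2], 1
    return col, 0


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns by greedy QR elimination
        _, R = np.linalg.qr(arr)
        diag = np.abs(np.diag(R))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * max(diag.max(), 1.0))[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"suspect columns: {bad}")
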