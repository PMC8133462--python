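"""Synthetic tower-log world with known ground truth.

Emulates the statistical structure the downstream pipeline assumes: cities on
planar meter coordinates with towers on a jittered grid, square park/mall
polygons, homes drawn uniformly, an AQI wave in the 25-225 range spreading
across cities with lags, hourly location choices governed by a multinomial
logit with Gumbel heterogeneity (home utility normalized to zero), an
Eq-style latent distance model for non-home hours, and noisy connection logs
that split each hour among the k nearest towers with distance-decaying
weights. Night hours (0:00-6:00) are generated at the true home so that home
inference is identifiable by construction.

Everything is deterministic given the config seed. The ``WorldTruth`` object
stores every parameter the estimators later try to recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box

from . import aqi as aqi_mod
from . import design

LOCATIONS = ["h", "m", "p", "o"]       # home, mall, park, other
NON_HOME = ["m", "p", "o"]

SECONDS_PER_HOUR = 3600
SECONDS_PER_DAY = 86400


# --------------------------------------------------------------------------
# configuration and truth containers

@dataclass
class WorldConfig:
    """Study-design knobs for the synthetic world.

    Defaults mirror the observed study layout: 6 cities, 4 days, 16 analysed
    hours per day (7:00-22:00). User and tower counts are desk-scale.
    """

    n_cities: int = 6
    n_days: int = 4
    hours_per_day: int = 16
    first_hour: int = 7
    n_users_per_city: int = 1000
    towers_per_city: int = 49
    city_extent: float = 10_000.0       # square side, meters
    n_parks: int = 2
    n_malls: int = 2
    facility_size: float = 2_000.0      # square side, meters
    tower_jitter: float = 0.12          # fraction of grid spacing
    aqi_range: tuple[float, float] = (25.0, 225.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cities", "n_days", "hours_per_day", "n_users_per_city",
                     "towers_per_city"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_parks < 0 or self.n_malls < 0:
            raise ValueError("facility counts must be >= 0")
        if self.city_extent <= 0:
            raise ValueError("city_extent must be positive")
        if not (0 <= self.first_hour and self.first_hour + self.hours_per_day <= 24):
            raise ValueError("analysed hours must lie within 0..24")
        if (self.n_parks or self.n_malls) and self.facility_size >= self.city_extent:
            raise ValueError("city_extent too small for the requested facilities")

    @property
    def hours(self) -> list[int]:
        """Analysed hours t (hour t covers the interval (t-1, t])."""
        return list(range(self.first_hour, self.first_hour + self.hours_per_day))

    @property
    def grid_side(self) -> int:
        return max(1, int(np.floor(np.sqrt(self.towers_per_city))))

    @property
    def tower_spacing(self) -> float:
        return self.city_extent / self.grid_side

    def city_origin(self, city: int) -> np.ndarray:
        # cities laid out on a shared plane, separated by one extent of slack
        return np.array([city * 2.0 * self.city_extent, 0.0])


@dataclass
class WorldTruth:
    """Ground-truth parameters of the generating model.

    Choice model (log-odds scale relative to home, whose utility components
    are identically zero):
      v[j,y,t,l] = gamma[j,y,l] + delta[t,l] + X[j,y,t] @ beta[l] + eta[j,y,t,l]
    Distance model (latent meters for non-home hours):
      d* = loc_mean[l] + gamma_d[j,y] + delta_d[t] + X @ beta_d + N(0, sigma_d)
    """

    measure: str                         # "aqi" | "levels"
    interactions: str                    # "none" | "t2"
    beta: dict[str, dict[str, float]]    # location -> covariate -> coefficient
    gamma: np.ndarray                    # (n_cities, n_days, 3) over NON_HOME
    delta: np.ndarray                    # (n_hours, 3)
    eta: np.ndarray                      # (n_cities, n_days, n_hours, 3)
    beta_d: dict[str, float]
    gamma_d: np.ndarray                  # (n_cities, n_days)
    delta_d: np.ndarray                  # (n_hours,)
    sigma_d: float
    loc_mean: dict[str, float]           # intended-distance base per non-home type
    substitution: float = 0.0            # 1 = perfect intra-day rescheduling

    def __post_init__(self):
        if self.sigma_d <= 0:
            raise ValueError("sigma_d must be positive")
        if not 0.0 <= self.substitution <= 1.0:
            raise ValueError("substitution must be in [0, 1]")

    @property
    def air_cols(self) -> list[str]:
        return sorted({c for b in self.beta.values() for c in b}, key=str)

    def beta_matrix(self, cols: list[str]) -> np.ndarray:
        """(n_cols, 3) coefficient matrix over NON_HOME locations."""
        return np.array([[self.beta[l].get(c, 0.0) for l in NON_HOME] for c in cols])

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("gamma", "delta", "eta", "gamma_d", "delta_d"):
            d[k] = np.asarray(d[k]).tolist()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "WorldTruth":
        d = json.loads(text)
        for k in ("gamma", "delta", "eta", "gamma_d", "delta_d"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class LogNoise:
    """Tower-assignment noise for the connection-log generator.

    Each phone-hour is split among the ``k`` nearest towers with weights
    proportional to exp(-distance/decay); ``concentration`` > 0 perturbs the
    weights with a Dirichlet draw (smaller = noisier), 0 disables the
    perturbation entirely.
    """

    k: int = 3
    decay: float | None = None           # meters; default: half the tower spacing
    concentration: float = 0.0
    service_rate: float = 0.0            # expected service events per hour

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.concentration < 0 or self.service_rate < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class World:
    config: WorldConfig
    towers: pd.DataFrame                 # tower_id, city, x, y
    parks: pd.DataFrame                  # facility_id, city, kind, geometry
    malls: pd.DataFrame
    homes: pd.DataFrame                  # phone_id, city, x, y
    truth: WorldTruth

    @property
    def facilities(self) -> pd.DataFrame:
        return pd.concat([self.parks, self.malls], ignore_index=True)


# --------------------------------------------------------------------------
# default truth parameters: the study conditions

def default_truth(config: WorldConfig, rng: np.random.Generator, *,
                  measure: str = "aqi", interactions: str = "none",
                  substitution: float = 0.0,
                  eta_sd: float = 0.05, gamma_sd: float = 0.10,
                  aqi_response: dict[str, float] | None = None) -> WorldTruth:
    """Truth with realistic baseline shares and a home-ward pollution response.

    Baseline (clean-air, midday) shares are set near home 40%, other 55%,
    park 2.5%, mall 1.5% -- the observed orders of magnitude (park/mall are
    single-digit percent shares). Pollution responses are negative for all
    away-from-home options, strongest for parks, so a Good-to-Heavily swing
    (~+150 AQI) moves several percentage points of the population home.
    """
    n_h = config.hours_per_day
    hours = np.asarray(config.hours, dtype=float)
    base = {"m": np.log(0.015 / 0.40), "p": np.log(0.025 / 0.40),
            "o": np.log(0.55 / 0.40)}
    if aqi_response is None:
        aqi_response = {"m": -0.0012, "p": -0.0020, "o": -0.0010}

    beta: dict[str, dict[str, float]] = {}
    for l in NON_HOME:
        if measure == "aqi":
            b = {"aqi": aqi_response[l]}
            if interactions == "t2":
                # mild U-shape in t: response weakest in mid-afternoon
                tm = hours.mean()
                b["aqi:t"] = aqi_response[l] * 0.12 * tm * 2 / (tm**2)
                b["aqi:t2"] = -aqi_response[l] * 0.12 / (tm**2)
                b["aqi"] = aqi_response[l] * (1 - 0.12)
            beta[l] = b
        elif measure == "levels":
            per_level = {"Excellent": -0.4, "Slightly Polluted": 0.4,
                         "Moderately Polluted": 0.8, "Heavily Polluted": 1.2}
            b = {lev: s * aqi_response[l] * 125.0 for lev, s in per_level.items()}
            if interactions == "t2":
                raise NotImplementedError("level-dummy truth with interactions")
            beta[l] = b
        else:
            raise ValueError(f"unknown measure {measure!r}")

    gamma = np.empty((config.n_cities, config.n_days, 3))
    for i, l in enumerate(NON_HOME):
        gamma[:, :, i] = base[l] + gamma_sd * rng.standard_normal(
            (config.n_cities, config.n_days))
    # hour profile: away-from-home activity peaks early afternoon
    tm = hours.mean()
    hump = -((hours - tm) / (hours[-1] - hours[0])) ** 2 * 4 + 1  # 1 at midday, <=1
    delta = np.column_stack([0.3 * hump, 0.5 * hump, 0.4 * hump])
    eta = eta_sd * rng.standard_normal((config.n_cities, config.n_days, n_h, 3))

    return WorldTruth(
        measure=measure, interactions=interactions, beta=beta,
        gamma=gamma, delta=delta, eta=eta,
        beta_d={"aqi": -5.0} if measure == "aqi" else
               {lev: v for lev, v in zip(
                   ["Excellent", "Slightly Polluted", "Moderately Polluted",
                    "Heavily Polluted"], [200.0, -200.0, -400.0, -650.0])},
        gamma_d=100.0 * rng.standard_normal((config.n_cities, config.n_days)),
        delta_d=500.0 * hump,
        sigma_d=1200.0,
        loc_mean={"m": 2500.0, "p": 2000.0, "o": 1800.0},
        substitution=substitution,
    )


# --------------------------------------------------------------------------
# world geometry

def gen_world(config: WorldConfig, *, truth: WorldTruth | None = None,
              **truth_kwargs) -> World:
    """Lay out towers, facilities and homes, and draw the ground truth."""
    root = np.random.default_rng(config.seed)
    r_geom, r_truth = root.spawn(2)

    towers = _gen_towers(config, r_geom)
    parks = _gen_facilities(config, r_geom, "park", config.n_parks)
    malls = _gen_facilities(config, r_geom, "mall", config.n_malls)
    homes = _gen_homes(config, r_geom)
    if truth is None:
        truth = default_truth(config, r_truth, **truth_kwargs)
    return World(config=config, towers=towers, parks=parks, malls=malls,
                 homes=homes, truth=truth)


def _gen_towers(config: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.grid_side
    s = config.tower_spacing
    rows = []
    for city in range(config.n_cities):
        ox, oy = config.city_origin(city)
        gx, gy = np.meshgrid(np.arange(m), np.arange(m))
        x = ox + (gx.ravel() + 0.5) * s
        y = oy + (gy.ravel() + 0.5) * s
        jit = rng.uniform(-config.tower_jitter * s, config.tower_jitter * s,
                          size=(m * m, 2))
        x = x + jit[:, 0]
        y = y + jit[:, 1]
        extra = config.towers_per_city - m * m
        if extra > 0:
            ex = ox + rng.uniform(0, config.city_extent, extra)
            ey = oy + rng.uniform(0, config.city_extent, extra)
            x = np.concatenate([x, ex])
            y = np.concatenate([y, ey])
        for i in range(config.towers_per_city):
            rows.append((f"c{city}t{i}", city, x[i], y[i]))
    return pd.DataFrame(rows, columns=["tower_id", "city", "x", "y"])


def _gen_facilities(config: WorldConfig, rng: np.random.Generator,
                    kind: str, count: int) -> pd.DataFrame:
    size = config.facility_size
    rows = []
    for city in range(config.n_cities):
        ox, oy = config.city_origin(city)
        for i in range(count):
            x0 = ox + rng.uniform(0, config.city_extent - size)
            y0 = oy + rng.uniform(0, config.city_extent - size)
            poly = box(x0, y0, x0 + size, y0 + size)
            rows.append((f"c{city}{kind[0]}{i}", city, kind, poly))
    return pd.DataFrame(rows, columns=["facility_id", "city", "kind", "geometry"])


def _gen_homes(config: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    pid = 0
    for city in range(config.n_cities):
        ox, oy = config.city_origin(city)
        x = ox + rng.uniform(0, config.city_extent, config.n_users_per_city)
        y = oy + rng.uniform(0, config.city_extent, config.n_users_per_city)
        for i in range(config.n_users_per_city):
            rows.append((pid, city, x[i], y[i]))
            pid += 1
    return pd.DataFrame(rows, columns=["phone_id", "city", "x", "y"])


def city_region(config: WorldConfig, city: int) -> Polygon:
    """Bounding region for one city (used to clip Voronoi cells)."""
    ox, oy = config.city_origin(city)
    return box(ox, oy, ox + config.city_extent, oy + config.city_extent)


# --------------------------------------------------------------------------
# AQI series

def gen_aqi(config: WorldConfig, pattern: str = "wave", *,
            flat_value: float = 75.0, lag_hours: float | None = None,
            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Hourly city AQI over the analysed hours, with official levels.

    ``wave`` produces a single pollution peak sweeping across cities with
    city-specific lags (the north-to-south spread); ``flat`` is a constant;
    ``iid`` draws independently within the configured range.
    """
    lo, hi = config.aqi_range
    if not (0 <= lo <= hi <= 500):
        raise ValueError("aqi_range must lie within [0, 500]")
    rng = np.random.default_rng(config.seed + 101) if rng is None else rng

    idx = pd.MultiIndex.from_product(
        [range(config.n_cities), range(config.n_days), config.hours],
        names=["city", "day", "hour"])
    df = idx.to_frame(index=False)
    tau = df["day"] * 24.0 + df["hour"]          # absolute hour in the period
    total = config.n_days * 24.0

    if pattern == "flat":
        vals = np.full(len(df), float(flat_value))
    elif pattern == "iid":
        vals = rng.uniform(lo, hi, len(df))
    elif pattern == "wave":
        if lag_hours is None:
            lag_hours = 36.0 / max(config.n_cities - 1, 1)
        peak0 = 0.70 * total
        width = 0.22 * total
        lag = df["city"].to_numpy() * lag_hours - lag_hours * (config.n_cities - 1) / 2
        bump = np.exp(-0.5 * ((tau.to_numpy() - (peak0 + lag)) / width) ** 2)
        vals = lo + (hi - lo) * bump
    else:
        raise ValueError(f"unknown AQI pattern {pattern!r}")

    vals = np.clip(vals, lo, hi)
    df["aqi"] = vals
    df["level"] = aqi_mod.categorize(df["aqi"])
    return df


# --------------------------------------------------------------------------
# choices

def cell_probabilities(truth: WorldTruth, aqi: pd.DataFrame,
                       closed: dict[str, np.ndarray] | None = None
                       ) -> pd.DataFrame:
    """Closed-form logit probabilities per (city, day, hour) cell.

    Returns the aqi frame with added columns p_h, p_m, p_p, p_o. ``closed``
    optionally maps a location to a boolean mask over rows where that option
    is unavailable (probability forced to zero, e.g. a city with no parks).
    """
    df = aqi.sort_values(["city", "day", "hour"]).reset_index(drop=True)
    cols = truth.air_cols
    X = _truth_air_design(df, cols, truth.substitution).to_numpy()
    B = truth.beta_matrix(cols)                          # (n_cols, 3)
    city = df["city"].to_numpy()
    day = df["day"].to_numpy()
    t_idx = df["hour"].to_numpy() - df["hour"].min()
    v = (truth.gamma[city, day, :] + truth.delta[t_idx, :]
         + X @ B + truth.eta[city, day, t_idx, :])       # (n, 3) over NON_HOME
    ev = np.exp(v)
    if closed:
        for loc, mask in closed.items():
            ev[np.asarray(mask, bool), NON_HOME.index(loc)] = 0.0
    denom = 1.0 + ev.sum(axis=1)
    df["p_h"] = 1.0 / denom
    for i, l in enumerate(NON_HOME):
        df[f"p_{l}"] = ev[:, i] / denom
    return df


def _truth_air_design(df: pd.DataFrame, cols: list[str],
                      substitution: float) -> pd.DataFrame:
    """Air covariates as the generating utility sees them.

    Under intra-day substitution s, the behavioural response keys on the AQI
    relative to its city-day mean: effective AQI = aqi - s * daily mean. With
    s = 1 a uniform daily shift in pollution leaves every hour's utility (and
    hence the daily average share) unchanged -- perfect rescheduling.
    """
    if substitution > 0:
        daily_mean = df.groupby(["city", "day"])["aqi"].transform("mean")
        df = df.assign(aqi=df["aqi"] - substitution * daily_mean)
    return design.air_design(df, cols)


def gen_choices(truth: WorldTruth, aqi: pd.DataFrame, homes: pd.DataFrame, *,
                mode: str = "multinomial", rng: np.random.Generator | None = None,
                no_parks: bool = False, no_malls: bool = False) -> pd.DataFrame:
    """Draw each user's true hourly location and intended distance.

    ``mode="multinomial"`` draws cell counts from the closed-form logit
    probabilities and deals locations to users; ``mode="gumbel"`` draws
    per-user type-I extreme-value utilities and takes the argmax. The two are
    distributionally identical.

    Returns one row per (phone_id, day, hour) with columns ``loc`` and
    ``intended_distance`` (NaN at home).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    closed = {}
    if no_parks:
        closed["p"] = np.ones(len(aqi), bool)
    if no_malls:
        closed["m"] = np.ones(len(aqi), bool)
    cells = cell_probabilities(truth, aqi, closed=closed or None)

    by_city = {c: g["phone_id"].to_numpy() for c, g in homes.groupby("city")}
    probs = cells[["p_h", "p_m", "p_p", "p_o"]].to_numpy()
    loc_arr = np.array(LOCATIONS, dtype=object)

    frames = []
    for r, row in enumerate(cells.itertuples(index=False)):
        users = by_city.get(row.city)
        if users is None:
            continue
        n = len(users)
        if mode == "multinomial":
            counts = rng.multinomial(n, probs[r])
            locs = np.repeat(loc_arr, counts)
            locs = locs[rng.permutation(n)]
        elif mode == "gumbel":
            # utilities: v_h = 0; others ln(p_l / p_h)
            with np.errstate(divide="ignore"):
                v = np.log(probs[r] / probs[r, 0])
            u = v[None, :] + rng.gumbel(size=(n, 4))
            locs = loc_arr[np.argmax(u, axis=1)]
        else:
            raise ValueError(f"unknown choice mode {mode!r}")
        frames.append(pd.DataFrame({
            "phone_id": users, "city": row.city, "day": row.day,
            "hour": row.hour, "loc": locs}))
    out = pd.concat(frames, ignore_index=True)

    # intended distance for non-home hours (latent normal, censored below at 0)
    out["intended_distance"] = np.nan
    away = out["loc"] != "h"
    if away.any():
        sub = out.loc[away]
        merged = sub.merge(cells[["city", "day", "hour", "aqi", "level"]],
                           on=["city", "day", "hour"], how="left")
        cols_d = sorted(truth.beta_d)
        Xd = _truth_air_design(merged, cols_d, truth.substitution).to_numpy()
        bd = np.array([truth.beta_d[c] for c in cols_d])
        t_idx = (merged["hour"] - cells["hour"].min()).to_numpy()
        mu = (np.array([truth.loc_mean[l] for l in merged["loc"]])
              + truth.gamma_d[merged["city"].to_numpy(), merged["day"].to_numpy()]
              + truth.delta_d[t_idx] + Xd @ bd)
        d = mu + truth.sigma_d * rng.standard_normal(len(mu))
        out.loc[away, "intended_distance"] = np.maximum(d, 0.0)
    return out


# --------------------------------------------------------------------------
# true positions and connection logs

def true_positions(world: World, choices: pd.DataFrame,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach a true (x, y) to every chosen phone-hour.

    Home hours sit at the home; park/mall hours at a uniform point inside a
    random same-city facility of that kind (the geometric distance then
    supersedes the drawn intended distance); "other" hours at the intended
    distance from home along a uniform bearing, clipped into the city extent.
    """
    rng = np.random.default_rng(1) if rng is None else rng
    cfg = world.config
    df = choices.merge(world.homes.rename(columns={"x": "home_x", "y": "home_y"}),
                       on=["phone_id", "city"], how="left")
    n = len(df)
    x = df["home_x"].to_numpy().copy()
    y = df["home_y"].to_numpy().copy()
    loc = df["loc"].to_numpy()

    for kind, tag in (("park", "p"), ("mall", "m")):
        fac = world.parks if kind == "park" else world.malls
        mask = loc == tag
        if not mask.any():
            continue
        if fac.empty:
            raise ValueError(f"choices include {kind} visits but the world has no {kind}s")
        for city, grp in df.loc[mask].groupby("city"):
            cand = fac[fac["city"] == city]
            if cand.empty:
                raise ValueError(f"city {city} has no {kind}")
            pick = rng.integers(0, len(cand), len(grp))
            minx, miny, maxx, maxy = np.array(
                [cand.iloc[i]["geometry"].bounds for i in pick]).T
            x[grp.index] = rng.uniform(minx, maxx)
            y[grp.index] = rng.uniform(miny, maxy)

    mask = loc == "o"
    if mask.any():
        theta = rng.uniform(0, 2 * np.pi, int(mask.sum()))
        d = df.loc[mask, "intended_distance"].to_numpy()
        x[mask] = x[mask] + d * np.cos(theta)
        y[mask] = y[mask] + d * np.sin(theta)
        # keep positions inside the tower-covered extent
        city = df.loc[mask, "city"].to_numpy()
        ox = np.array([cfg.city_origin(c)[0] for c in city])
        oy = np.array([cfg.city_origin(c)[1] for c in city])
        x[mask] = np.clip(x[mask], ox, ox + cfg.city_extent)
        y[mask] = np.clip(y[mask], oy, oy + cfg.city_extent)

    out = df[["phone_id", "city", "day", "hour", "loc"]].copy()
    out["x"] = x
    out["y"] = y
    return out


def gen_logs(world: World, positions: pd.DataFrame,
             noise: LogNoise | None = None, *,
             night_window: tuple[int, int] = (0, 6),
             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit the connection-record stream for true phone-hour positions.

    Day hours come from ``positions``; night hours in ``night_window`` are
    generated at each phone's home for every day plus one trailing morning,
    so the raw first-to-last span exceeds the analysed days (mirroring a raw
    capture period with partial lead-out) and the home-inference window is
    populated. Records are time-ordered per phone: a connect to a new tower
    implicitly ends the previous connection; each hour ends with a disconnect.
    """
    noise = LogNoise() if noise is None else noise
    rng = np.random.default_rng(2) if rng is None else rng
    cfg = world.config

    frames = [positions[["phone_id", "city", "day", "hour", "x", "y"]].copy()]
    # night phone-hours at home, days 0..n_days inclusive
    nights = []
    h0, h1 = night_window
    homes = world.homes
    for day in range(cfg.n_days + 1):
        for hour in range(h0 + 1, h1 + 1):   # hour t covers (t-1, t]
            nights.append(homes.assign(day=day, hour=hour))
    frames.append(pd.concat(nights, ignore_index=True)[
        ["phone_id", "city", "day", "hour", "x", "y"]])
    ph = pd.concat(frames, ignore_index=True)

    recs = []
    for city, grp in ph.groupby("city"):
        tw = world.towers[world.towers["city"] == city].reset_index(drop=True)
        k = min(noise.k, len(tw))
        tree = cKDTree(tw[["x", "y"]].to_numpy())
        dist, idx = tree.query(grp[["x", "y"]].to_numpy(), k=k)
        if k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        decay = noise.decay if noise.decay is not None else cfg.tower_spacing / 2
        w = np.exp(-(dist - dist.min(axis=1, keepdims=True)) / decay)
        w = w / w.sum(axis=1, keepdims=True)
        if noise.concentration > 0:
            alpha = np.maximum(noise.concentration * w, 1e-6)
            w = rng.gamma(alpha)
            w = w / w.sum(axis=1, keepdims=True)

        n = len(grp)
        start = (grp["day"].to_numpy() * SECONDS_PER_DAY
                 + (grp["hour"].to_numpy() - 1) * SECONDS_PER_HOUR).astype(float)
        # connect events at cumulative offsets, then a final disconnect
        cum = np.concatenate([np.zeros((n, 1)), np.cumsum(w, axis=1)], axis=1)
        ts_connect = start[:, None] + cum[:, :k] * SECONDS_PER_HOUR
        phone = np.repeat(grp["phone_id"].to_numpy(), k)
        recs.append(pd.DataFrame({
            "phone_id": phone,
            "tower_id": tw["tower_id"].to_numpy()[idx].ravel(),
            "timestamp": ts_connect.ravel(),
            "event": "connect"}))
        recs.append(pd.DataFrame({
            "phone_id": grp["phone_id"].to_numpy(),
            "tower_id": tw["tower_id"].to_numpy()[idx[:, k - 1]],
            "timestamp": start + SECONDS_PER_HOUR,
            "event": "disconnect"}))
        if noise.service_rate > 0:
            n_serv = rng.poisson(noise.service_rate, n)
            rep = np.repeat(np.arange(n), n_serv)
            if len(rep):
                offs = rng.uniform(0, 1, len(rep))
                slot = np.minimum((offs[:, None] >= cum[rep, 1:k + 1]).sum(axis=1),
                                  k - 1) if k > 1 else np.zeros(len(rep), int)
                recs.append(pd.DataFrame({
                    "phone_id": grp["phone_id"].to_numpy()[rep],
                    "tower_id": tw["tower_id"].to_numpy()[idx[rep, slot]],
                    "timestamp": start[rep] + offs * SECONDS_PER_HOUR,
                    "event": "service"}))

    out = pd.concat(recs, ignore_index=True)
    # at equal timestamps a disconnect must precede the next hour's connect,
    # otherwise the opening interval of that hour would be attributed to a gap
    rank = out["event"].map({"disconnect": 0, "service": 1, "connect": 2})
    out = (out.assign(_rank=rank)
           .sort_values(["phone_id", "timestamp", "_rank"], kind="stable")
           .drop(columns="_rank").reset_index(drop=True))
    return out


# --------------------------------------------------------------------------
# direct simulators for the estimation stages

def gen_panel_counts(truth: WorldTruth, aqi: pd.DataFrame, n_users: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """City-day-hour counts drawn straight from the individual logit.

    Equivalent to simulating ``n_users`` independent logit choices per cell
    and tallying them -- the fast path for estimator recovery studies that do
    not need tower logs.
    """
    cells = cell_probabilities(truth, aqi)
    probs = cells[["p_h", "p_m", "p_p", "p_o"]].to_numpy()
    counts = np.vstack([rng.multinomial(n_users, p) for p in probs])
    out = cells[["city", "day", "hour", "aqi", "level"]].copy()
    for i, l in enumerate(LOCATIONS):
        out[f"n_{l}"] = counts[:, i]
    out["n_total"] = counts.sum(axis=1)
    for l in LOCATIONS:
        out[f"share_{l}"] = out[f"n_{l}"] / out["n_total"]
    return out


def gen_tobit_sample(n: int, beta: np.ndarray, sigma: float, *,
                     lower: float = 0.0, upper: float = 50_000.0,
                     rng: np.random.Generator,
                     x_sd: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Doubly-censored normal data with an intercept-first design."""
    p = len(beta)
    X = np.column_stack([np.ones(n)] + [rng.normal(0, x_sd, n)
                                        for _ in range(p - 1)])
    latent = X @ beta + sigma * rng.standard_normal(n)
    y = np.clip(latent, lower, upper)
    return X, y
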