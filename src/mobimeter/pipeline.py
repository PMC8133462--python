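"""End-to-end orchestration: simulate -> geolocate -> classify -> panel ->
choice fit -> distance fit -> daily, with seeded substreams, a manifest and
CSV/JSON artifacts per stage.

One global seed deterministically spawns per-stage random substreams, so a
rerun with the same config is byte-identical and individual stages can be
rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import daily as daily_mod
from . import facilities as fac_mod
from . import io as io_mod
from . import panel as panel_mod
from . import synthetic as syn
from . import tobit as tobit_mod
from .geolocate import SelectionRules
from .geolocate import geolocate as _geolocate
from .choice import ModelSpec, effect_with_ci, fit_share_logit

STAGES = ["simulate", "geolocate", "classify", "build-panel", "fit-choice",
          "fit-distance", "daily"]


@dataclass
class RunConfig:
    outdir: str = "mobimeter-run"
    seed: int = 0
    world: dict = field(default_factory=dict)      # WorldConfig overrides
    aqi_pattern: str = "wave"
    noise: dict = field(default_factory=dict)      # LogNoise overrides
    measure: str = "levels"
    interactions: str = "none"
    bootstrap_B: int = 200
    bootstrap_unit: str = "city-day"
    zero_policy: str = "add_half"
    home_radius: float = 500.0
    facility_min_seconds: float = 2400.0
    overlap_threshold: float = 0.05
    min_records: int = 20
    min_span_hours: float = 96.0
    censor_limit: float = 50_000.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_rngs(seed: int, n: int = 8):
    return np.random.default_rng(seed).spawn(n)


def run_pipeline(config: RunConfig, *, stages=None, log=print) -> Path:
    """Run the requested stages (default: all) into the artifact directory."""
    stages = STAGES if stages is None else stages
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "python": sys.version.split()[0],
                "config_hash": hashlib.sha256(
                    json.dumps(config.to_dict(), sort_keys=True).encode()
                ).hexdigest()[:16],
                "stages": {}}
    r_world, r_aqi, r_choice, r_pos, r_logs, r_boot, *_ = _stage_rngs(config.seed)

    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            counts = _run_stage(stage, config, state, out,
                                dict(world=r_world, aqi=r_aqi, choice=r_choice,
                                     pos=r_pos, logs=r_logs, boot=r_boot))
        except Exception:
            log(f"stage {stage!r} failed")
            for f in out.glob("*.tmp"):
                f.rename(f.with_suffix(".partial"))
            raise
        manifest["stages"][stage] = counts
        log(f"stage {stage}: {counts}")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _run_stage(stage, cfg: RunConfig, state, out: Path, rngs) -> dict:
    if stage == "simulate":
        wc = syn.WorldConfig(seed=cfg.seed, **cfg.world)
        world = syn.gen_world(wc, measure=cfg.measure,
                              interactions=cfg.interactions)
        aqi = syn.gen_aqi(wc, cfg.aqi_pattern, rng=rngs["aqi"])
        choices = syn.gen_choices(world.truth, aqi, world.homes,
                                  rng=rngs["choice"],
                                  no_parks=world.parks.empty,
                                  no_malls=world.malls.empty)
        positions = syn.true_positions(world, choices, rng=rngs["pos"])
        records = syn.gen_logs(world, positions,
                               syn.LogNoise(**cfg.noise), rng=rngs["logs"])
        world.towers.to_csv(out / "towers.csv", index=False)
        world.homes.to_csv(out / "true_homes.csv", index=False)
        aqi.to_csv(out / "aqi.csv", index=False)
        records.to_csv(out / "records.csv", index=False)
        io_mod.write_facilities(out / "facilities.geojson", world.facilities)
        (out / "truth.json").write_text(world.truth.to_json())
        state.update(world=world, aqi=aqi, records=records, choices=choices)
        return {"towers": len(world.towers), "records": len(records),
                "phones": int(world.homes["phone_id"].nunique())}

    if stage == "geolocate":
        records = state.get("records")
        if records is None:
            records = pd.read_csv(out / "records.csv")
        towers = state["world"].towers if "world" in state else \
            pd.read_csv(out / "towers.csv")
        res = _geolocate(
            records, towers,
            rules=SelectionRules(cfg.min_records, cfg.min_span_hours))
        res["placements"].to_csv(out / "placements.csv", index=False)
        res["homes"].to_csv(out / "homes.csv", index=False)
        state.update(**res, towers=towers)
        return {**res["log"], "placements": len(res["placements"])}

    if stage == "classify":
        facilities = state["world"].facilities if "world" in state else \
            io_mod.read_facilities(out / "facilities.geojson")
        rules = fac_mod.LabelRules(home_radius=cfg.home_radius,
                                   facility_min_seconds=cfg.facility_min_seconds,
                                   overlap_threshold=cfg.overlap_threshold)
        res = fac_mod.classify(state["towers"], facilities,
                               state["placements"], state["dwell"], rules=rules)
        res["tags"].to_csv(out / "tower_tags.csv", index=False)
        res["labeled"].to_csv(out / "labeled_placements.csv", index=False)
        state.update(labeled=res["labeled"], tags=res["tags"])
        return {"park_towers": int(res["tags"]["is_park_tower"].sum()),
                "mall_towers": int(res["tags"]["is_mall_tower"].sum()),
                "label_conflicts": res["labeled"].attrs["label_conflicts"]}

    if stage == "build-panel":
        aqi = state.get("aqi")
        if aqi is None:
            aqi = pd.read_csv(out / "aqi.csv")
        pnl = panel_mod.build_panel(state["labeled"], aqi)
        pnl.to_csv(out / "panel.csv", index=False)
        state.update(panel=pnl)
        return {"rows": len(pnl)}

    if stage == "fit-choice":
        spec = ModelSpec(measure=cfg.measure, interactions=cfg.interactions)
        pnl = state["panel"]
        tab = effect_with_ci(pnl, spec, B=cfg.bootstrap_B,
                             unit=cfg.bootstrap_unit,
                             seed=int(rngs["boot"].integers(2**31)),
                             zero_policy=cfg.zero_policy)
        payload = {"spec": dataclasses.asdict(spec),
                   "effects": json.loads(tab.to_json(orient="index"))}
        (out / "effects.json").write_text(json.dumps(payload, indent=1))
        state.update(choice_effects=tab)
        return {"locations": len(tab)}

    if stage == "fit-distance":
        spec = ModelSpec(measure=cfg.measure, interactions=cfg.interactions)
        fit = tobit_mod.fit_tobit(state["labeled"], state["panel"], spec,
                                  upper=cfg.censor_limit)
        eff = tobit_mod.tobit_effect(fit)
        payload = {"sigma_m": fit.sigma, "loglike": fit.loglike,
                   "n_obs": fit.n_obs, "n_upper_censored": fit.n_upper,
                   "effect": eff.to_dict()}
        (out / "distance_effects.json").write_text(json.dumps(payload, indent=1))
        state.update(tobit=fit, tobit_effect=eff)
        return {"n_obs": fit.n_obs, "n_upper": fit.n_upper}

    if stage == "daily":
        rows = daily_mod.build_daily(state["panel"], state["labeled"])
        rows.to_csv(out / "daily.csv", index=False)
        fits = {loc: daily_mod.fit_daily(rows, "mean", f"share_{loc}_x1000")
                for loc in daily_mod.LOCATIONS}
        payload = {loc: {"coef": float(f.params["aqi"]),
                         "p": float(f.pvalues["aqi"])}
                   for loc, f in fits.items()}
        (out / "daily_effects.json").write_text(json.dumps(payload, indent=1))
        state.update(daily=rows, daily_fits=fits)
        return {"city_days": len(rows)}

    raise AssertionError(stage)
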