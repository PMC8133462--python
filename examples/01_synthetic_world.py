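"""Build a synthetic six-city world and inspect its ground truth.

The generator lays towers on a jittered grid, drops square park/mall
polygons, draws homes uniformly, and produces an AQI wave (25-225) that
peaks later in higher-numbered cities. Every parameter the estimators later
try to recover is stored in the WorldTruth object.
"""

import mobimeter as mm

cfg = mm.WorldConfig(n_users_per_city=500, seed=1)
world = mm.gen_world(cfg)
aqi = mm.gen_aqi(cfg, "wave")

print(f"towers: {len(world.towers)}  homes: {len(world.homes)} "
      f"facilities: {len(world.facilities)}")
print("\nAQI range per city (index points):")
print(aqi.groupby("city")["aqi"].agg(["min", "max"]).round(1))
print("\nhours at each official level:")
print(aqi["level"].value_counts())
print("\ntrue AQI response (log-odds per index point, negative = "
      "option loses appeal as pollution rises):")
for loc, b in world.truth.beta.items():
    print(f"  {loc}: {b}")
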