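"""Aggregated logit: how a Good -> Heavily Polluted swing moves people.

Draws a city-day-hour panel straight from the individual logit (5,000 users
per city), fits the log-odds share regressions with level dummies ("Good"
omitted), and inverts the logit to get counterfactual marginal effects with
percentile-bootstrap CIs. delta_pp is the share change in percentage
points; per_million is the head count per one million people.
"""

import numpy as np

import mobimeter as mm
from mobimeter.choice import ModelSpec

cfg = mm.WorldConfig(seed=3)
rng = np.random.default_rng(3)
truth = mm.default_truth(cfg, rng, measure="levels")
aqi = mm.gen_aqi(cfg, "wave")
panel = mm.gen_panel_counts(truth, aqi, 5000, rng)

tab = mm.effect_with_ci(panel, ModelSpec(measure="levels"),
                        B=200, unit="row", seed=3)
cols = ["delta_pp", "delta_pp_lo", "delta_pp_hi", "per_million",
        "pct_change"]
print("effect of air quality worsening from 'Good' to 'Heavily Polluted':")
print(tab[cols].round(2))
print("\nsimplex check - effects sum to "
      f"{tab['delta_pp'].sum():.2e} pp (exactly conserved)")
print("positive home row: people relocate home as pollution rises; the "
      "away-from-home options absorb the mirror-image loss.")
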