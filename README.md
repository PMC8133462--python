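# mobimeter

Measures how air pollution shifts hourly human location choice and distance
from home, starting from raw mobile-tower connection logs. The package is
aimed at researchers working with call-detail-record-style mobility data who
want to estimate exposure-avoidance behaviour: when the Air Quality Index
(AQI) worsens, how many people move home, give up park or shopping-mall
visits, and how many meters of travel they forgo.

Because operator tower logs are proprietary, the package ships a first-class
synthetic-world generator with stored ground truth. Every estimator is
validated by parameter recovery against that truth.

## What it computes

**Measurement.** Phones are geolocated from timestamped connect/disconnect/
service records: a phone-hour's position is the dwell-time-weighted average
of its towers' coordinates; its home is the same average over the 0:00-6:00
night window pooled across days. Phones with fewer than 20 records or an
active span under 96 hours are dropped. Each tower's service area is its
Voronoi cell; a tower whose cell overlaps parks (malls) by at least 5% is a
park (mall) tower. A phone-hour is labelled home (`h`) if its raw distance
from home is below 500 m, else park (`p`) or mall (`m`) if it spent more
than 40 minutes of the hour on such towers, else other (`o`). Distance from
home is binned into 501 intervals of 100 m, censored at 50 km.

**Location choice.** With i.i.d. Gumbel (type-I extreme value) taste shocks,
individual choice aggregates so that for each away-from-home option
l ∈ {m, p, o} the cell log-odds are linear:

    ln n_{jytl} − ln n_{jyth} = γ_{jyl} + δ_{tl} + X_{jyt} β_l + η_{jytl}

with city-day (γ) and hour (δ) fixed effects, covariates X (level dummies
with "Good" omitted, or continuous AQI, optionally interacted with t and
t²), and a cell shock η that also absorbs measurement error. Three OLS fits
on the city-day-hour panel identify β. Counterfactual shares come from
inverting the logit (s_h = 1/(1+Σ e^v), s_l = e^{v_l} s_h); marginal effects
are averages of counterfactual share differences (level switch) or the
analytic derivative ∂s_l/∂AQI = s_l β_l − s_l Σ_{l′} β_{l′} s_{l′} at sample
means. CIs are percentile bootstrap (rows or city-day blocks).

**Distance.** Latent intended distance d* = γ^D + δ^D + Xβ^D + ε with
normal ε, observed clipped to [0 m, 50,000 m]: a doubly-censored Tobit
maximized by BFGS with analytic gradients (σ on the log scale).

**Daily substitution.** Daily mean hourly shares (×1000) regressed on daily
AQI summaries with city and day fixed effects; the daily/hourly effect
ratio separates cancelled activities (ratio ≈ 1) from intra-day
rescheduling (ratio ≈ 0).

## Worked example

```bash
python examples/03_location_choice_effects.py
```

prints (panel drawn from a known individual logit, 5,000 users/city,
6 cities × 4 days × 16 hours):

```
effect of air quality worsening from 'Good' to 'Heavily Polluted':
   delta_pp  delta_pp_lo  delta_pp_hi  per_million  pct_change
h      3.00         2.01         4.07     29992.63        8.43
m     -0.18        -0.33        -0.06     -1823.56      -11.36
p     -0.72        -0.90        -0.53     -7205.96      -23.17
o     -2.10        -3.12        -1.06    -20963.10       -3.51

simplex check - effects sum to 4.88e-14 pp (exactly conserved)
```

`delta_pp` is the change in each location's population share in percentage
points when air quality switches from "Good" to "Heavily Polluted" with all
other covariates at observed values; `per_million` is the same change as a
head count per one million people (pp × 10,000); the `_lo`/`_hi` columns are
percentile-bootstrap 95% bounds. The positive home row and negative
away-from-home rows show the exposure-avoidance pattern: under heavy
pollution people relocate home, and the four effects conserve the share
simplex exactly.

The other examples cover the generator (`01`), the raw-log measurement chain
(`02`), the censored distance model (`04`), and the daily substitution
contrast (`05`). The end-to-end pipeline is also available as a CLI:

```bash
mobimeter run-all --config run.yaml --seed 1 --outdir artifacts/
```

writing `towers.csv`, `records.csv`, `aqi.csv`, `facilities.geojson`,
`placements.csv` (phone_id, city, day, hour, x, y, distance_mid,
censored_upper, ...), `panel.csv` (counts `n_h,n_m,n_p,n_o`, shares
`share_*`, `aqi`, `level` per city-day-hour), `effects.json`,
`distance_effects.json`, `daily_effects.json` and a `manifest.json` with
the config hash and per-stage row counts.

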