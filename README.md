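# metanets

Delineate **metacommunities** — sets of local species communities linked by
dispersal — from time series of habitat maps, and test which delineation
best matches observed biodiversity patterns.

In landscapes that have lost most of their habitat over the last century
(the motivating case: wetlands and their dragonfly/damselfly communities),
present-day species composition can still reflect *historical* habitat
connectivity: formerly connected patches keep sharing species long after the
connections are gone (an extinction debt). `metanets` operationalises this
idea. It builds, for every time step t and dispersal threshold θ, a habitat
network whose nodes are patches and whose edges link patches with
edge-to-edge distance d ≤ θ; the connected components of that network are
candidate metacommunities, including patches joined only through
stepping-stone chains. Each candidate delineation is then scored on current
species data:

- **Beta diversity.** For all pairs of current patches (i, j) within 15 km,
  the Jaccard dissimilarity β_ij = 1 − |S_i∩S_j| / |S_i∪S_j| is binarized at
  its median into low/high; pairs are labelled *within* or *between*
  metacommunities by the delineation; the agreement between the two
  labellings is summarised by accuracy, precision and Cohen's
  κ = (p_o − p_e)/(1 − p_e), plus a two-sided Welch t-test on the within vs
  between β distributions. The delineation with the highest κ (given mean
  within-β < mean between-β) is flagged best.
- **Gamma diversity.** Per metacommunity, regional richness γ (union of
  member species sets) is correlated (Pearson, on log-transformed
  predictors) against metacommunity size: total habitat area, patch count,
  and mean shortest-path distance ("network diameter").

Because the habitat record is loss-only, layers are first *harmonized*:
habitat present at time t is backward-propagated to all earlier layers, so
every current patch is nested in some historical patch.

A fully seeded synthetic generator (clustered disc landscapes, stepwise
habitat loss, communities drawn from per-metacommunity species pools under
either an extinction-debt or a no-debt regime) provides ground-truthed data
for every stage, so the whole pipeline is testable without licensed survey
data.

## Worked example

Simulate an extinction-debt study (three time steps of habitat loss,
communities seeded from the *earliest* step's components) and score one
delineation per time step at θ = 500 m:

```python
from metanets.experiments import score_study
from metanets.synthetic_data import simulate_study

study = simulate_study(11, regime="historical")
results = score_study(study)
print(results[["source", "n_within", "n_between", "accuracy", "kappa",
               "t_stat", "direction_ok", "best"]].round(3).to_string(index=False))
```

```
               source  n_within  n_between  accuracy  kappa  t_stat  direction_ok  best
network:t=0:theta=500       625        924     0.680  0.358 -17.617          True  True
network:t=1:theta=500       597        952     0.673  0.344 -16.674          True False
network:t=2:theta=500       509       1040     0.649  0.294 -14.821          True False
```

The landscape shrinks from 104 to 81 patches over the three steps. Every
delineation separates the β distributions in the right direction (within
lower than between, strongly negative t), but κ is highest for the earliest
time step — the evaluation recovers the fact that these communities were
shaped by the historical, not the current, network. With
`regime="current"` the same pipeline flags the final time step instead.

The same workflow runs from the shell on raster + CSV inputs:

```sh
metanets fixtures --out fx          # small synthetic dataset + config
metanets run --config fx/run.ini --out results/
```

which writes `evaluation.csv` (one row per time step × θ × source,
including an abiotic watershed delineation), `gamma_records.csv`,
`gamma_correlations.csv`, `timeseries_summary.csv`, per-pair diagnostics,
membership tables, extent GeoJSONs and a run manifest. Reruns are
byte-identical.

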