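# fireconn

Spatiotemporal fire-connectivity analysis for insect surveys.

Pyrophilic (fire-favoured) insects track a resource — recently burned forest —
that is scattered in space and short-lived in time. Given a regional
fire-history register and per-site catch tables from a trapping survey,
`fireconn` quantifies each sampling site's *spatiotemporal connectivity* to
surrounding fires, relates the catch composition to it, and estimates the
spatial and temporal scales over which fire history matters. It is written for
fire ecologists and conservation planners deciding, for example, how far apart
and how often conservation burns should be placed.

## The model

Connectivity of trap *i* to the fire register is

```
ST_i = Σ_j  exp(−d_ij · α_s) · FA_j · exp(−T_j · α_t)
```

where `d_ij` is the planar distance (km) to fire *j*, `FA_j = ln(area_j)` the
log burned area (m²), `T_j` the whole years since the fire, and only fires
within 20 km (inclusive) contribute. The decay scales `α_s` (per km) and `α_t`
(per year) are *not* assumed: for each response they are chosen on a grid over
[0, 4] × [0, 4] by minimizing the deviance (residual sum of squares) of a
normal-family GLM

```
ln(k_i / (n_i − k_i)) = β₀ + β · z_i + ε_i
```

of the per-site ln-odds that a random caught individual (or species) belongs
to a focal group (pyrophilic, with non-pyrophilic and obligate-saproxylic
controls), on connectivity standardized to mean 0, sd 1 (`z_i`), so `β` is a
standardized estimate. Zero count cells get a Haldane continuity constant
(0.5 on both cells). Because the same data pick the scales and test the slope,
the reported p-value at the optimum is anti-conservative; the package
documents and demonstrates this rather than hiding it.

A synthetic-data module generates fire landscapes and binomial-logit catches
with known ground truth (`α_s*`, `α_t*`, `β*`), so the entire chain is
validated by parameter recovery without any downloads.

## Worked example

```
$ fireconn simulate --seed 5 --n-sites 12 --outdir demo
$ fireconn fit --fires demo/fires.csv --catches demo/catches.csv \
      --grid-step 0.5 --outdir demo
$ head -3 demo/report.csv
# fireconn 0.1.0 config_hash=1576c32d5feb seed=none
group,level,status,alpha_s,alpha_t,intercept,se_i,p_i,slope,se_s,p_s,deviance,n_obs
pyrophilic,individuals,ok,1.0,1.0,-3.499,0.2050,1.00e-08,2.014,0.2141,2.77e-06,5.041,12
```

(values shown rounded). Read: for the individual-level pyrophilic response
the best-fitting kernel decays at 1.0 km⁻¹ in space and 1.0 yr⁻¹ in time —
exactly the generator's ground truth — the mean ln-odds is −3.50 (odds ≈
e^−3.50 ≈ 0.03), and one standard deviation of connectivity raises the
ln-odds by 2.01 (the generative effect was β* = 2; p is unadjusted for the
scale search). `profile.csv` holds the full deviance surfaces and
`weights.csv` the decay curves at the selected scales.

Descriptive statistics, including the pooled survey composition and the
fraction of forest burned:

```
$ fireconn describe --catches demo/catches.csv --burned-km2 20.54 --forested-km2 14394
...
burned_forest_percent: 0.14
```

`fireconn recover` runs the simulate → analyse → score loop against ground
truth (`--scenario recovery` or `--scenario null`).

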