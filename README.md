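# lingvar

Personalised network analysis of daily language-feature time series:
per-person regularised graphical VAR (lag-1) networks, strength
centralities, within/outside-episode contrasts with permutation and
bootstrap controls, and a random-network generalisation experiment —
exercised end-to-end on synthetic cohorts with known latent dynamics.

## What it does

- **`lingvar.simulate`** — synthetic cohorts: latent lag-1 VAR feature
  dynamics whose innovation precision gains connectivity during simulated
  depressive episodes, episode schedules, missing days, severity scores tied
  to connectivity, and optional raw token streams.
- **`lingvar.text`** — document cleaning (URLs/mentions/emoji removed, `.!?`
  kept as tokens), a `%`-delimited word/stem category dictionary, daily
  aggregation into per-user feature-percentage matrices (12-month window,
  days without documents absent).
- **`lingvar.episodes`** — recoding of self-reported episode intervals
  (merge gaps < 2 weeks, drop residuals < 2 weeks), day labelling, and the
  30-day / 15+15-day eligibility filters.
- **`lingvar.gvar`** — sparse graphical VAR per person: L1-penalised temporal
  matrix, graphical-lasso innovation precision, contemporaneous
  partial-correlation network, EBIC model selection over a 10×10 λ grid
  (γ = 0 → BIC).
- **`lingvar.centrality`** — node/global strength, 3-SD group outlier masks,
  mean networks with closeness/betweenness, and case-dropping bootstrap
  stability (CS coefficient).
- **`lingvar.group`** — severity-scale pooling, feature–severity
  associations, severity–connectivity regressions, split-half edge
  reliability, relevant/irrelevant feature pools.
- **`lingvar.episode_effects`** — paired within/outside networks, episode
  effect with per-user intercepts and day-count controls, Wilcoxon check,
  80% subsample bootstrap, and a day-label permutation null that re-estimates
  networks under preserved day counts (exposing the day-count bias).
- **`lingvar.generalize`** — sampled 9-feature networks from each pool,
  per-set episode effects, pool comparison, top-network report.

## CLI

```sh
lingvar simulate --config cfg.json --out data/ --seed 7
lingvar features --docs data/documents.jsonl --dict toy.dic \
    --survey-dates surveys.csv --out feats.csv
lingvar episodes --in data/episodes.csv --features data/features.csv --out coded/
lingvar fit --features data/features.csv --out nets/
lingvar centrality --features data/features.csv --out centrality.csv
lingvar stability --features data/features.csv --n-boot 200 --out stability.json
lingvar severity-analysis --features data/features.csv \
    --severity data/severity.csv --out sev/
lingvar pools --features data/features.csv --severity data/severity.csv \
    --out pools.csv
lingvar episode-effect --features data/features.csv \
    --episodes data/episodes.csv --out effect.json
lingvar permute --features ... --episodes ... --n-perm 200 --seed 1 --out perm.json
lingvar bootstrap --features ... --episodes ... --n-boot 200 --out boot.json
lingvar generalize --features ... --episodes ... --pools pools.csv \
    --n-sets 50 --seed 1 --out gen/    # --full for 1000+1000 sets
```

All inputs/outputs are plain text (CSV/JSONL/JSON). Fit settings can be
overridden with a JSON `--config` mirroring `FitConfig` (e.g.
`{"n_lambda": 10, "gamma": 0}` or fixed grids via `lambda_kappa_values`).

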