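# scenoset

Objective selection of a representative subset of climate-change scenarios by
Ward-seeded k-means clustering, and the downstream double-weighted ensemble
machinery for projecting species range change: change-field climate
projection, split-sample SDM calibration with AUC weighting, consensus
probability maps, maxSSS thresholding, gain/loss statistics, and a
combinatorial sensitivity analysis of arbitrary climate-model selection.

## What it does

1. **Scenario subsetting** — a table of per-scenario regional climate deltas
   (one row per AOGCM × forcing combination) is standardized, clustered with
   Ward's minimum-variance criterion to seed a restarted k-means, and scored
   by the Rsq statistic (between-group SS / total SS). The operating cluster
   count is chosen by a linear cost–benefit rule on the Rsq profile, and each
   cluster contributes its nearest-to-centroid member as a representative
   scenario, weighted by cluster size. On the packaged 27-scenario table this
   yields 6 clusters capturing 83% of the variance.
2. **Projection** — scenario deltas are applied to a baseline climatology with
   the change-field method (additive temperature, relative precipitation,
   clipped relative precipitation ratio), and per-cell ensemble percentile
   fields compare the reduced ensemble against the full one.
3. **SDM ensemble** — repeated 70/30 split-sample calibration of a
   ridge-stabilized logistic occurrence model (pluggable "algorithm slots";
   externally fitted probability stacks are accepted too), rank-based AUC
   evaluation, and projection of every model under every scenario.
4. **Consensus & range change** — AUC-weighted consensus for the reference
   period and full future ensemble; double-weighted (AUC × cluster size)
   consensus for the representative subset; maxSSS binarization with
   reference-period thresholds; gain/loss percentages and 4-way difference
   maps.
5. **Sensitivity** — all q-of-m AOGCM combinations (capped with seeded
   subsampling at scale) are scored to quantify how much projections depend
   on an arbitrary model choice.

A synthetic-fixture module generates every input with known ground truth
(smooth multi-gradient climate landscape, virtual species with a known
logistic response), so the whole pipeline runs with no external data.

## CLI

```sh
scenoset cluster --restarts 999 --seed 1 --out solution.json   # packaged table
scenoset cluster --table deltas.csv --k auto --out solution.json
scenoset summarize --out summary.json
scenoset fixtures --what species --n-cells 900 --seed 1 --out data/
scenoset project --baseline data/baseline.csv --scenario "CM4:A2" --out future.csv
scenoset fit --occurrences data/occurrences.csv --repeats 20 --slots 7 --out models.json
scenoset consensus --stack stack.csv --mode eq1 --representatives solution.json \
    --threshold-from threshold.json --out consensus.csv
scenoset sensitivity --stack stack.csv --reference ref.csv \
    --threshold-from threshold.json --q 1..9 --out sensitivity.json
scenoset run --config config.ini     # full pipeline; all-fixture demo by default
```

`scenoset run` executes cluster → project → fit → consensus (full and
double-weighted) → compare (→ sensitivity, if enabled) and writes a manifest
with per-file checksums plus a resolved copy of its configuration. Exit
codes: 0 success, 2 validation error, 1 computation error.

Scenario tables are CSV/TSV with columns `center, model, sres` plus one
column per delta variable (`dTavg` °C additive, `dPrec` and `dPrat` in %).
Cell tables are keyed by a `cell_id` column. Probability stacks travel as
long-format CSV (`cell_id, model_id, auc, aogcm, sres, p`).

## Layout

- `src/scenoset/scenario_io.py` — delimited-text tables, validation
- `src/scenoset/clustering.py` — standardize, Ward tree, k-means, Rsq,
  representatives
- `src/scenoset/projection.py` — change-field method, percentile fields
- `src/scenoset/sdm.py` — splits, reference learner, AUC, probability stacks
- `src/scenoset/consensus.py` — weighted consensus, maxSSS, range change
- `src/scenoset/sensitivity.py` — q-of-m combination analysis
- `src/scenoset/fixtures.py` — packaged scenario table, synthetic landscape,
  virtual species
- `src/scenoset/pipeline.py`, `cli.py` — orchestration and the `scenoset`
  command

Tests mirror the modules; `tests/oracles.py` holds the independent
brute-force oracles (exhaustive partition enumeration, recompute-SS
agglomeration, pair-count AUC, threshold sweep, direct weighted summation)
and `tests/test_acceptance.py` pins the headline numbers.
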