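# cogebm

Event-based modelling (EBM) of cognitive decline from cross-sectional cohort
data, built around a 16-outcome cognitive/informant test battery for adults
with Down syndrome.

The pipeline:

1. **Synthetic cohorts** (`cogebm.synthetic`) — generates participant tables
   with a known ground-truth event ordering, per-participant latent stages,
   pre/post-event score distributions with floor/ceiling effects,
   intellectual-disability (ID) level offsets, task non-engagement, and
   missingness, so every downstream stage is testable without external data.
2. **Preprocessing** (`cogebm.preprocessing`) — imputation rules
   (zero score for attempted-but-not-understood tasks, worst recorded
   latency for reaction time, nearest-integer mean imputation for up to 15%
   of questionnaire items) and residualization of every score on ID level
   using regressions fitted on the young-adult (YA, 16–35) rows only.
3. **KDE mixtures** (`cogebm.mixture`) — per-biomarker semisupervised
   two-component kernel density mixtures giving P(x|event) and P(x|no
   event), initialized from the YA/OA group split; YA controls stay anchored
   in the normal component while OA rows are re-weighted.
4. **Event ordering** (`cogebm.ordering`) — maximum-likelihood event
   sequence via greedy pairwise-swap ascent plus Metropolis MCMC over
   permutations; sampling and bootstrap uncertainty are summarized as
   positional variance diagrams.
5. **Staging** (`cogebm.staging`) — per-participant maximum-likelihood stage
   (0..16) along the fitted sequence.
6. **Group comparison** (`cogebm.comparison`) — Mann–Whitney U contrasts of
   stage distributions: YA vs OA, dementia vs none within OA, and APOE4 vs
   APOE2/APOE3 within age groups (APOE 2:4 carriers omitted).

## Command line

```bash
# simulate a cohort, fit, stage, compare, bootstrap — everything:
cogebm run-all --seed 1 --n-boot 25 --out-dir out/

# or stage by stage:
cogebm simulate --seed 1 --out-dir out/
cogebm preprocess out/cohort.csv --out-dir out/
cogebm fit out/cohort.csv --seed 1 --out-dir out/
cogebm bootstrap out/cohort.csv --seed 1 --n-boot 100 --out-dir out/
cogebm compare out/stages.csv out/cohort.csv --out-dir out/
```

Outputs are plain text (CSV/JSON/TSV) plus PNG figures: the fitted sequence,
per-biomarker mixture fits, positional variance diagrams, stage assignments,
stage histograms by grouping, the contrast table, and a run manifest
(config hash, seed, versions).

Configuration is YAML with two optional sections, `cohort:` (generator
parameters — group sizes, separation, missingness rates, stage
distributions) and `pipeline:` (mixture refinement, MCMC iterations,
bootstrap settings). Every field has a sensible default; see
`cogebm.synthetic.CohortConfig` and `cogebm.pipeline.PipelineConfig`.

### Cohort table schema

One row per participant: `participant_id`, `age`, `age_group` (YA/OA),
`sex`, `id_level` (mild/moderate/severe), `dementia` (none/diagnosed),
`apoe_group` (APOE2/APOE3/APOE4/APOE24/unknown), then for each of the 16
biomarkers a score column (`NA` when missing) and a `<name>__engagement`
column (`completed` / `attempted_not_understood` / `not_attempted`).

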