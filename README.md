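# pairsurv

Quartile-stratified gene-pair survival screening for expression cohorts.

Given a gene-expression matrix (genes × samples, RSEM-like non-negative
values), a per-patient clinical table (follow-up days, vital status) and an
optional tumor/normal sample labeling, `pairsurv`:

1. **Screens single genes** — tumor-vs-normal differential expression
   (Mann–Whitney, p < 0.001), survival association under median and extreme
   quartile cutoffs (log-rank, p < 0.05) with an O/E hazard ratio outside the
   (0.8, 1.2) indifference band, plus a force-include list.
2. **Screens every gene pair** — for each ordering, five-year Kaplan–Meier
   survival is computed per factor-gene quartile within the second gene's
   high (Q1) and low (Q4) strata; pairs are kept when a strict four-point
   survival trend implies the same survival direction in *both* orderings
   (bidirectional concordance) and the strata-conditional Q1-vs-Q4 hazard
   ratios differ by ≥ 10%.  Each kept pair gets a scenario label (i–iv)
   describing which expression combination drives reduced or increased
   survival.
3. **Characterizes selected pairs** — genes correlated with both members
   (|r| > 0.3), hypergeometric gene-set enrichment with BH FDR against a
   user-supplied GMT, and shared up/down gene subsets across combinations of
   three or more pairs.
4. **Simulates cohorts** — a seeded generator with log-normal expression,
   block latent correlation, tumor/normal shifts, and survival times whose
   log-hazard carries planted marginal and pairwise-interaction effects;
   every planted effect is recorded for recovery testing.

All screening statistics (product-limit estimator, log-rank, O/E hazard
ratio, Mann–Whitney, Pearson, hypergeometric tail, BH FDR, quartile binning)
are implemented in `pairsurv.survstats`; external survival libraries appear
only as independent oracles in the test suite.

## CLI

```bash
pairsurv simulate      --config sim.yaml --out data/ --seed 7
pairsurv screen-genes  --expr data/expression.tsv --clinical data/clinical.tsv \
                       --classes data/classes.tsv --out genes.tsv
pairsurv screen-pairs  --expr data/expression.tsv --clinical data/clinical.tsv \
                       --genes passed.txt --horizon-days 1825 --hr-diff 0.10 \
                       --out pairs.tsv
pairsurv correlate     --pairs pairs.tsv --expr data/expression.tsv \
                       --clinical data/clinical.tsv --out sets/
pairsurv enrich        --set sets/GA|GB.tsv --gmt annotation.gmt --out enr.tsv
pairsurv overlap       --sets sets/ --min-pairs 3 --out overlap.tsv
pairsurv run           --config pipeline.yaml     # full workflow
```

`pipeline.yaml` accepts the fields of `pairsurv.config.PipelineConfig`
(paths plus every threshold; unknown keys are rejected).  File formats are
plain text: TSV with a header row and `.` for undefined values, standard
GMT, clinical status encoded 0 = censored/alive, 1 = dead.

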