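# mplexcog

Structure–function multiplex brain-network analysis: from per-subject
connectivity matrices to binarized maximum-spanning-tree layers, a
two-layer multiplex with unit interlayer links, multilayer eigenvector
centrality and eccentricity, frontoparietal-network summaries, and the
hierarchical-regression / leave-site-out cross-validation statistics —
plus a synthetic multi-site cohort generator with a planted cognition
effect so the whole pipeline is testable without any imaging data.

## What it does

1. **I/O + transforms** (`mplexcog.connectome_io`): TSV readers/writers
   for square connectivity matrices, parcellation tables (the seven
   canonical resting-state networks + subcortex) and cohort manifests.
   Functional correlations are Fisher z-transformed and absolutized;
   structural streamline-weight sums are `log10(1 + w)`-transformed
   (strictly increasing, so spanning trees are unaffected; zeros stay
   absent links).
2. **Graph layers** (`mplexcog.graph_layers`): maximum spanning tree per
   modality via descending-rank Kruskal with deterministic tie-breaking
   (N − 1 binary links, connected, acyclic), stacked into a multiplex
   whose supra-adjacency matrix has layer adjacencies on the diagonal
   blocks and identity off-diagonal blocks.
3. **Metrics** (`mplexcog.network_metrics`): eigenvector centrality
   (leading eigenvector, positive, unit norm) on layers and on the
   supra-adjacency (replica entries averaged per region and
   renormalized), BFS eccentricity with means, and subnetwork averages
   (e.g. mean frontoparietal EC).
4. **Statistics** (`mplexcog.stats_models`): hierarchical block OLS with
   ΔR²/ΔF increment tests, raw and standardized coefficients, VIF
   collinearity diagnostics, a quadratic age model, leave-site-out
   cross-validation with out-of-sample R² and Levene's test on pooled
   residuals, and the impairment-rate summary (z < −1.5).
5. **Synthetic cohorts** (`mplexcog.synthetic_cohort`): multi-site
   cohorts (13 scan-site labels by default) of sparse log-normal
   structural weights and latent-factor functional time series, with
   additive per-site effects and a cognition score built from the
   pipeline's own multiplex frontoparietal centrality — so coefficient
   recovery is a closed-loop test of the entire stack.
6. **Pipeline + CLI** (`mplexcog.pipeline`, `mplexcog.cli`).

Two parcellation label tables are packaged: `schaefer114`
(100 cortical + 14 subcortical regions) and `bna224` (210 + 14).

## CLI

```sh
# simulate a cohort, compute everything, write the report bundle
mplexcog all --out results/run --seed 7

# or stage by stage
mplexcog simulate --out results/cohort --n-subjects 50 --seed 7
mplexcog metrics  --cohort-dir results/cohort --out results/m
mplexcog regress  --metrics results/m/metrics.tsv --out results/reg
mplexcog cv       --metrics results/m/metrics.tsv --out results/cv
```

`mplexcog all` also accepts `--config run.toml` (keys mirror
`PipelineConfig`, with an optional `[cohort]` table), `--parcellation`
(packaged name or TSV path), `--fd-threshold` for motion exclusion, and
`--fd-covariate`. Outputs are TSV/JSON: per-subject metric table,
three-block regression reports (FPN, DAN, eccentricity), quadratic-age
report, leave-site-out CV tables with Levene statistics, and a
`run_summary.json` with seed, config hash and impairment rate.

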