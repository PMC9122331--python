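# turnover-aging

Pulse-labeling (pulse-SILAC) protein lifetime estimation and aged-vs-young
proteome turnover comparison, with a synthetic cohort generator so the whole
pipeline can be exercised and validated without external data.

## What it does

* **Labeling kinetics** (`turnover_aging.kinetics`) — the forward model: a
  double-exponential heavy-lysine precursor pool
  `F(t) = 1 − a·e^(−bt) − (1−a)·e^(−t/r)` (shipped parameters
  a=0.034277, b=0.444865, r=11.836573) and the closed-form protein heavy
  fraction solving `dh/dt = k(F(t) − h)`, so fitted lifetimes are
  intrinsically corrected for lysine reuse. An independent adaptive-ODE
  oracle is included for testing.
* **Lifetime estimation** (`turnover_aging.estimation`) — parses MaxQuant
  proteinGroups-dialect TSVs (dropping reverse/contaminant/
  only-identified-by-site rows), summarizes peptide H/L ratios (median,
  > 3 peptides), fits one half-life per (protein, cohort, dataset) by
  bounded least squares on heavy fractions over t½ ∈ [0.1, 1000] days,
  derives 95% profile-likelihood CIs, and applies QC rules
  (single-time-point and decreasing-labeling exclusion, wide-CI flags).
  LFQ abundances are H+L summed, median-normalized, and averaged.
* **Aging comparison** (`turnover_aging.comparison`) — median rescaling of
  aged onto young lifetimes, per-dataset log2FC, the ≥3-of-4
  direction-consistency rule, rLL/rSL extremes, percentile bands
  (<25th / 37.5–67.5th / >75th), z-score matrices, the lifetime-compression
  correlation with its raw-ratio bidirectionality control, abundance
  quadrants, and cell-type specificity (log2 margin > 1).
* **Sequence features** (`turnover_aging.features`) — length, average MW,
  isoelectric point (bisection on the net-charge function), GRAVY
  (Kyte–Doolittle), 20 composition fractions, average biosynthetic cost per
  residue (avECPA), and expensive (>60) / affordable (<20) residue classes.
  The pKa, hydropathy, and cost tables are editable TSVs under
  `src/turnover_aging/data/`.
* **Statistics** (`turnover_aging.statistics`) — feature/log2FC Pearson
  correlations, Wilcoxon matched-pairs signed-rank test,
  Welch/Brown–Forsythe ANOVA with Dunnett (group n < 50) or Games–Howell
  (n > 50) posthoc, Anderson–Darling log-normality check.
* **Synthetic cohorts** (`turnover_aging.synthetic`) — log-normal ground
  truth for 2 cohorts × 4 datasets (cortex/cerebellum homogenate +
  synaptic), global aging factor, targeted rLL/rSL effects, lifetime
  compression, multiplicative ratio noise, missingness, decoy rows, FASTA
  sequences, and annotation tables. Fully deterministic given (config, seed).

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` runs the acceptance criteria (oracle
equivalence, estimator recovery/coverage, factor recovery, rule-engine
enumeration, compression discrimination, feature oracles, statistical
calibration, end-to-end determinism); the full suite takes a few minutes on
one CPU.

## CLI

```bash
# generate a synthetic cohort
turnover-aging simulate --config cohort.yaml --outdir sim/

# fit lifetimes from a proteinGroups-dialect table
turnover-aging fit --input sim/proteinGroups_young_cortex_hom.tsv \
    --sample-map sim/sample_map.tsv --pool 0.034277,0.444865,11.836573 \
    --out lifetimes.tsv

# aged-vs-young comparison from two lifetimes tables
turnover-aging compare --aged aged.tsv --young young.tsv --out cmp/

# sequence feature table
turnover-aging features --fasta seqs.fasta --annotations ann.tsv --out features.tsv

# full pipeline (simulate -> fit -> QC -> compare -> features -> report)
turnover-aging all --config run.yaml --outdir out/
```

`run.yaml` mirrors `turnover_aging.pipeline.RunConfig` (see
`out/run_config.yaml` from any run for a template). Exit codes: 0 ok,
2 validation, 3 data/format, 4 numerical.

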