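# rtepi

Predicting enhancer–promoter interactions (EPIs) from DNA replication-timing
(RT) profiles alone.

`rtepi` builds labelled EPI datasets from chromatin loops (Hi-C-style BEDPE)
and enhancer/promoter annotations (BED), encodes each pair as a 482-dimensional
multi-scale RT feature vector from a bedGraph/wiggle RT track, trains a random
forest, and evaluates it with 5-fold cross-validation, repeated resampling,
cross-sample matrices and pooled ("general") models. On top of the classifier
it provides:

- **dataset construction** — merging of adjacent same-class elements
  (gap ≤ 500 bp), positive calling from loop anchors, candidate enumeration,
  and distance-matched negative sampling at a 1:20 positive:negative ratio;
- **interpretation** — impurity/permutation feature importances with
  promoter/enhancer and per-scale groupings, incremental top-k feature
  selection, feature-subset evaluation, and a distance-only control that
  verifies the negatives are genuinely distance-matched;
- **cross-platform application** — scoring of independent loop catalogues
  (ChIA-PET / Hi-TrAC / 5C style), loop-recovery fractions, and union
  combination of several models;
- **disease cohorts** — top-N candidate selection, per-sample re-encoding into
  a samples × EPIs probability matrix, two-group specific/common EPI calling,
  and clustering quality metrics (adjusted Rand index, Calinski–Harabasz);
- **a synthetic generator** — RT tracks with early/late domain structure,
  element annotations, RT-coupled loop sets and two-group sample cohorts with
  planted group-specific EPIs, so the entire pipeline is testable without any
  external data.

In-house implementations are used for AUPRC (average-precision summation with
tied scores collapsed to one threshold), AUROC (Mann–Whitney rank statistic),
ARI and the Calinski–Harabasz index; all four are verified against brute-force
oracles in the test suite.

## CLI

Every command writes its outputs plus a `run_log.json` (inputs, effective
config, config hash, seed, version) into `--out`; randomised commands require
an explicit `--seed`. A full synthetic round trip:

```bash
rtepi simulate --seed 1 --out out/sim
rtepi build-dataset --loops out/sim/loops.bedpe \
    --enhancers out/sim/enhancers.bed --promoters out/sim/promoters.bed \
    --seed 1 --out out/dataset
rtepi encode --pairs out/dataset/pairs.tsv --rt out/sim/rt.bedgraph \
    --out out/encoded
rtepi train --features out/encoded/features.tsv --scheme out/encoded/scheme.cfg \
    --seed 1 --out out/model
rtepi evaluate --features out/encoded/features.tsv \
    --scheme out/encoded/scheme.cfg --seed 1 --out out/eval
```

Further commands: `cross-sample` (train-on-row/test-on-column AUPRC matrix),
`interpret` (importances, incremental selection, distance-only control),
`recover-loops` (independent catalogue recovery), `combine` (union of model
calls), and `cancer-diff` (two-group cohort pipeline with `--sample
GROUP=track.bedgraph` per sample). Generator and dataset parameters are set
with `--config file` and/or repeated `--set key=value` overrides.

## Feature scheme

The default encoder emits, per anchor (enhancer and promoter): the anchor-region
mean plus, for each window scale in {500, 1000, 2000, 5000, 10000, 50000} bp,
20 upstream and 20 downstream flanking windows summarised by their
length-weighted mean RT — 2 × (1 + 6 × 40) = 482 features. Windows covered
below a configurable fraction (default 0.5) are treated as missing and imputed
with the chromosome-wide mean. Scales, bin counts, anchor means, imputation
and coverage threshold are all configurable (`FeatureScheme`, serialisable to
a plain-text config). Genomic distance is carried as metadata, not as a model
feature; `rtepi interpret --distance-control` trains on distance alone to
check that a dataset's negatives are properly matched.

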