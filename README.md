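# refstab

Reference-gene stability analysis for RT-qPCR experiments.

Choosing a normalization (housekeeping) gene is experiment-specific: a gene
that is stable across cultivars may drift under stress treatments.  `refstab`
implements the standard selection workflow end to end:

- **Candidate screening** from two-library expression tables: RPKM, signed
  log2 expression ratio, significance filter (|log2 ratio| >= 1) and
  per-family selection of the least differential member.
- **Primer / standard-curve QC**: ordinary least squares of Ct against
  log10(relative template amount), amplification efficiency
  `E = 10^(-1/k) - 1`, configurable acceptance band (default 90-110 %,
  R² >= 0.99).
- **Three stability algorithms**:
  - *geNorm*: relative quantities `Q = base^(Ctmin - Ct)`, pairwise
    variation, M values, stepwise exclusion ranking, normalization factors
    and the V(n/n+1) series (0.15 threshold) for the optimal number of
    reference genes.
  - *NormFinder*: model-based intra-/inter-group variance decomposition on
    sample-centered log2 expression, with shrinkage of the group
    differences; grouped and ungrouped modes; best two-gene combination.
  - *BestKeeper*: per-gene SD/CV of raw Ct, geometric-mean index and
    Pearson correlation of each gene with it; SD < 1 stability rule.
- **Consensus ranking** by the geometric mean of the three methods' ranks,
  and **2^-ddCt validation** of chosen references, including a sensitivity
  report that flags when an unstable reference flips the apparent direction
  of regulation.
- **Synthetic data** with known ground truth (gene noise SDs, group
  regulation effects, shared sample-loading shifts) for every stage.

## CLI

```sh
# write a seeded study-scale fixture bundle (5 sample sets, 10 genes)
refstab simulate --seed 1 --outdir simulated/

# screen candidates from a two-library FPKM (or read-count) table
refstab screen simulated/screening.tsv --out screening_report.tsv

# standard-curve QC from a gene/dilution/ct table
refstab qc simulated/dilution.tsv --out curves.tsv

# run all three stability methods per sample set + consensus tables
refstab stability simulated/stress_leaf_ct.tsv \
    --sample-sheet simulated/stress_leaf_samples.tsv --outdir stability/

# merge standalone per-method rank tables (columns: gene, rank)
refstab consensus genorm.tsv normfinder.tsv bestkeeper.tsv --out com.tsv

# 2^-ddCt validation of a target against chosen references
refstab validate ct.tsv --sample-sheet sheet.tsv --target T1 \
    --references PPX,SANDX --calibrator control --group-mean \
    --compare-refs PPX,ACTX
```

Ct tables are plain TSV/CSV, wide (first column gene, then one column per
sample) or long (`gene`, `sample`, `ct`).  The sample sheet has
`sample_id` plus any of `set`, `group`, `tissue`, `time`, `replicate`;
biological replicates are averaged before stability analysis by default.

## Python API

```python
from refstab import (read_ct_table, collapse_replicates, genorm,
                     normfinder_stability, bestkeeper, consensus_rank, ddct)

m = read_ct_table("ct.tsv", sample_sheet="samples.tsv")
m = collapse_replicates(m)
gn = genorm(m)                       # M values, V series, best pair
nf = normfinder_stability(m)         # stability values S
bk = bestkeeper(m)                   # SD/CV/r table
cons = consensus_rank({"genorm": gn.ranking(), "normfinder": nf.ranking(),
                       "bestkeeper": bk.ranking()})
```

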