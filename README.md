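# statewise-burden

Rare and low-frequency variant association testing for whole-genome
case-control studies that mix internally and externally sequenced
controls — annotation-state and repeat-class weighted burden tests,
sequencing-metadata-PC batch correction with genomic-control (λ_GC)
diagnostics, singleton-PTV gene and gene-set burden tests, sliding-window
burden scans with permutation-calibrated significance, and analytic
case-control power.

## Who this is for

Statistical-genetics analysts combining a deeply phenotyped case-control
cohort with external, psychiatrically (or otherwise) unscreened controls
sequenced elsewhere. Joint calling does not remove depth-driven
differences in variant calling, and tests that aggregate thousands of rare
variants — chromatin/conservation-state burdens in particular — are
exquisitely sensitive to them. The package provides both the association
machinery and the diagnostics that tell you when it is lying to you.

## The model

For annotation category *c* (one of 200 chromatin/conservation states, 22
repeat classes, a gene, or a window) the per-sample predictor is the
weighted non-reference allele count

    B_sc = Σ_{v∈c} w(MAF_v) · g_sv,      w(f) = Beta(f; 1, 25) = 25 (1−f)^24

over bi-allelic SNVs with MAF < 0.05 outside excluded regions. Logistic
regression of case/control (or cohort) status on `B_sc` adjusts for 10
genetic PCs, sex, sequencing batch (internal-only comparisons), the total
weighted burden, and optionally the first 4 sequencing-metadata PCs.
Family calibration is summarised by

    λ_GC = median( Q_χ²₁(1 − p) ) / 0.45494 .

Samples pass hard QC filters (contamination ≤ 5%, ≥ 98% of sites at ≥ 10×,
sex concordance), are pruned to an unrelated set with KING-robust kinship
(φ > 0.0409 removed, duplicates resolved internal-first), and PCs come
from LD-pruned (500 kb / r² 0.2 / MAF > 5%) genotypes. Sliding windows of
5–50 kb step by half their size; the scan threshold is 0.05/n̂ with the
effective test count n̂ fit by maximum likelihood from the permutation
distribution of the scan minimum p (min-p ~ Beta(1, n)). Analytic power
uses the 1-df trend-test non-centrality under a multiplicative disease
model with population-based controls.

A fully synthetic cohort generator (`statewise_burden.synthetic_cohort`)
reproduces the data structure all of this assumes — two control cohorts at
26.8 ± 5.5× vs 36.8 ± 4.7× depth with depth-dependent differential calling
concentrated in repeat classes, 200 annotation states with state-specific
repeat composition, admixture-driven allele-frequency gradients, singleton
PTVs in genes, duplicate and parent-offspring pairs — with every latent
parameter recorded for recovery testing. See `docs/methods.md`.

## Worked example

Detectable odds ratio at 80% power for a bipolar-disorder-sized case group
against 11,000 population controls, risk-allele frequency 1%, prevalence
1%, genome-wide α = 5×10⁻⁹:

```bash
$ statewise-burden power --raf 0.01 --prevalence 0.01 \
      --ncase 1500 --nctrl 11000 --alpha 5e-9 --solve-or
OR for 80% power: 2.4343
```

so variants of OR ≥ 2.43 at MAF 0.01 are detectable — anything reported
as detectable at OR 3.2 under these inputs has power well above 80%
(`power_cc` returns 1.000 there).

The batch-effect diagnostic on a synthetic two-cohort control set:

```python
import numpy as np
from statewise_burden import CohortConfig, generate_cohort
from statewise_burden.io_formats import compute_maf_mac
from statewise_burden.weights_annotation import select_analysis_variants, build_burden_matrix
from statewise_burden.burden_tests import build_covariates, run_category_scan
from statewise_burden.metadata_pcs import compute_metadata_pcs, metric_matrix
from statewise_burden.sample_qc import compute_genetic_pcs

cohort = generate_cohort(CohortConfig(seed=2, n_bd=0, n_sz=0))
y = np.array([s.cohort == "internal_control" for s in cohort.samples], float)
maf, _, _ = compute_maf_mac(cohort.genotypes.data)
idx = select_analysis_variants(cohort.variants, "state", maf=maf)
bm = build_burden_matrix(cohort.genotypes, cohort.variants, idx, "state", maf=maf)
sex = np.array([s.sex == "XX" for s in cohort.samples], float)
pcs, _ = compute_genetic_pcs(cohort.genotypes, np.flatnonzero(maf > 0.05)[:4000], k=10)
meta, _ = compute_metadata_pcs(metric_matrix(cohort.samples), k=4)
base = build_covariates(genetic_pcs=pcs, sex=sex, total_burden=bm.totals)
adj  = build_covariates(genetic_pcs=pcs, sex=sex, total_burden=bm.totals, metadata_pcs=meta)
_, lam_base, _ = run_category_scan(bm, y, base, method="score")
_, lam_adj, _  = run_category_scan(bm, y, adj,  method="score")
print(f"state-scan lambda_GC: base {lam_base:.2f} -> +metaPCs {lam_adj:.2f}")
```

prints (seed 2):

```
state-scan lambda_GC: base 1.56 -> +metaPCs 0.75
```

the signature of depth-driven differential calling absorbed by
sequencing-metadata PCs: the 200-state family is inflated under the base
covariates and drops to near-null after adjustment (single-run λ estimates
carry sampling noise of roughly ±0.16; averaged over seeds the pattern is
≈1.6 → ≈0.95, while the single-variant GWAS on the same cohorts stays at
λ ≈ 1.01 throughout).

A full seven-comparison battery (six case-control + control-control, each
family and covariate model, with a λ_GC summary matrix) runs from a YAML
config:

```bash
statewise-burden run --config cfg.yaml --seed 1 --out results/
```

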