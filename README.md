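# tmescape

Tumor-microenvironment (TME) subtyping and multi-omic characterization of
bulk tumor cohorts, built as a tested, reusable Python library with a thin
command-line layer.

## The problem

The immune and stromal composition of a tumor — its microenvironment —
stratifies patients beyond histology: cohorts with the same diagnosis split
into TME subtypes with different survival, expression programs, methylation
landscapes and copy-number behavior. `tmescape` implements that analysis
end-to-end for bulk multi-omics:

1. **Immune-cell deconvolution.** Per-sample fractions of 22 reference
   immune cell types are estimated from bulk expression by linear
   ν-support-vector regression of the z-scored mixture on the z-scored
   signature matrix (ν ∈ {0.25, 0.5, 0.75}, lowest RMSE wins; negative
   coefficients clipped and renormalized to the simplex).
2. **Consensus clustering.** Samples are subsampled (proportion *p* = 0.8,
   default 100 repetitions) and clustered (K-means or PAM) for each
   candidate *k*; the consensus matrix entry M(i, j) is the proportion of
   co-sampled iterations in which i and j co-cluster. The number of
   subtypes is chosen from the consensus CDF: the smallest *k* for which
   one extra cluster raises the area under the CDF by < 10%.
3. **Subtype characterization** per group pair:
   - moderated differential tests (linear model + empirical-Bayes variance
     shrinkage; DEGs at raw p < 0.01 **and** BH-adjusted p < 0.05), with
     all-region Venn intersection across contrasts;
   - pathway impact scores P_NDE (hypergeometric over-representation),
     P_PERT (signed-graph perturbation with bootstrap), combined as
     P_G = c(1 − ln c), c = P_NDE · P_PERT; crosstalk between significant
     pathways as the distance correlation Rm of their member-gene
     expression per group, and the differential crosstalk R_d = Rm₁ − Rm₂;
   - methylation: hyper- (FC > 1.25, FDR < 0.01) and hypomethylated
     (FC < 0.8) probes, mean β per genomic region class (TSS1500, TSS200,
     5'UTR, 1st exon, body, 3'UTR), Welch t contrasts, Fisher/χ² region
     enrichment;
   - copy number: copynum = 2^(x+1) from the segment mean x, five
     categories (−2…+2), gene assignment by full segment containment,
     χ² group tests and amplification:deletion ratios;
   - ceRNA networks: lncRNA–miRNA–mRNA triplets where all three members
     are differential, the lncRNA–miRNA pair is in the interaction table
     and the miRNA–gene pair is supported by all three target databases;
   - survival: Kaplan–Meier curves with Greenwood variance, k-group
     log-rank tests, and median-split KM for single RNAs.

A synthetic-cohort generator (`tmescape.simulate`) produces multi-omic
cohorts with known ground truth — mixing fractions, monotone DEG sets,
region-specific methylation shifts, group-specific amp:del odds, planted
ceRNA triplets and group hazards — so every stage is testable without any
external download.

## Worked example

```python
import numpy as np
from tmescape import estimate_fractions, make_signature, simulate_mixtures

signature = make_signature(n_genes=220, n_cell_types=22,
                           markers_per_type=10, fold=5.0, seed=1)
expr, truth = simulate_mixtures(signature, n_samples=20, noise_sd=0.1, seed=2)
est = estimate_fractions(expr, signature, seed=0).fractions
print(f"MAE: {np.abs(est.to_numpy() - truth.to_numpy()).mean():.4f}")
```

prints `MAE: 0.0034` — the estimated immune fractions are within half a
percentage point per entry of the true mixing proportions despite 10%
log-normal expression noise. The `examples/` directory holds one short
script per capability; `python examples/02_consensus_subtypes.py` prints

```
planted separation: 8.6 sigma
chosen k: 3
area under consensus CDF per k: {2: 0.459, 3: 0.674, 4: 0.724, 5: 0.776, 6: 0.813}
adjusted Rand index vs planted groups: 1.000
```

— the consensus-CDF area gain collapses after k = 3 and the recovered
subtypes match the planted groups exactly.

The same functionality is scriptable from the shell:

```bash
tmescape simulate-cohort --out cohort/ --seed 1
tmescape run --config pipeline.yaml     # eight stages, file-to-file
```

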