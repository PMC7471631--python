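# Methods

This note records the models implemented in `tmescape`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Deconvolution

Bulk expression is modeled as a non-negative linear mixture of reference
cell-type profiles. For each sample the z-scored mixture vector is
regressed on the z-scored signature matrix with linear ν-SVR over
ν ∈ {0.25, 0.5, 0.75}; the fit with the lowest RMSE wins, negative
coefficients are clipped to zero and the rest renormalized to sum to 1
(relative fractions). Rationale for the grid and selection rule: they are
the established convention for signature-based SVR deconvolution. Two
deliberate divergences from the original tool: no quantile normalization
(inputs are assumed TPM-comparable) and no permutation filtering by
default (`n_permutations=0`); a permutation p-value per sample is
available on request. Genes absent from the mixture are dropped, not
imputed, and fewer than 50% of signature genes present is a hard error —
silent degradation is worse than failure. Units: FPKM-like inputs are
converted per sample by TPM normalization (xᵢ / Σx × 10⁶); differential
analysis uses log2(TPM + 1).

Because the regression runs on z-scores, output is invariant to positive
rescaling of a sample up to SVR optimizer tolerance (~1e-4 absolute on
fractions).

## Consensus clustering and choice of k

For each k and repetition, ⌈p_item · n⌉ samples are drawn without
replacement (default p_item = 0.8, 100 repetitions) and clustered —
K-means (k-means++ with 10 restarts) or a built-in PAM (greedy BUILD then
first-improvement SWAP on Euclidean distances; ties break toward lower
total cost). The consensus entry is co-clustered/co-sampled counts, the
diagonal is fixed at 1, and never-co-sampled pairs are set to 0 with a
warning. Every repetition's sample indices and labels are retained in
`resample_log`, so any entry can be re-tallied from first principles —
this is tested exactly.

The CDF of off-diagonal consensus values is evaluated at 101 grid points.
We define `delta_area(k)` = (A(k+1) − A(k)) / A(k), the relative gain in
area under the CDF from permitting one more cluster beyond k, and choose
the smallest k whose gain falls below 0.10: past the true cluster number,
extra clusters stop sharpening the consensus. If the gain never drops
below threshold, the maximum k is returned with a warning, and `force_k`
bypasses selection entirely. Final labels always come from
average-linkage hierarchical clustering of 1 − consensus at the chosen k.
With p_item = 1 and `deterministic_init=True` (base-clusterer seeds taken
from the repetition index) the whole procedure is seed-independent.

## Moderated differential testing

Per feature, a two-group mean model gives the pooled residual variance
s² with d = n₁ + n₂ − 2 degrees of freedom. A scaled inverse-χ² prior
(d₀, s₀²) is moment-matched on log variances — d₀ solves
trigamma(d₀/2) = Var(log s²) − trigamma(d/2) (inverted by bracketed root
finding), s₀² from the matching mean with digamma corrections; when the
observed spread is at or below the sampling floor, d₀ = ∞ and all
variances shrink to s₀². The moderated t uses the posterior variance
(d₀s₀² + ds²)/(d₀ + d) with d₀ + d degrees of freedom. Forcing d₀ = 0
recovers the classic pooled t exactly (tested to 1e-8); on data with a
genuine inverse-χ² variance prior the statistic matches the reference R
implementation (limma) to ~1e-9 relative, which the suite checks through
`Rscript` when available.

Thresholds: DEGs require raw p < 0.01 AND BH-adjusted p < 0.05.
Methylation is tested on raw β values and classified on the ratio scale:
hyper iff FC > 1.25 and FDR < 0.01, hypo iff FC < 0.8 and FDR < 0.01,
strict inequalities, where FC is the ratio of group-mean βs — the
fold-change thresholds only make sense on a ratio scale, and β (not
M-value) is the scale on which the thresholds are stated. Zero-variance
features get p = 1 and are logged. Contrasts are all unordered group
pairs in alphabetical order; no omnibus F-test. A Kruskal–Wallis utility
covers rank comparisons of cell-type fractions across the three groups.

## Pathway impact and crosstalk

P_NDE is the exact hypergeometric upper tail for the overlap of
differential genes with pathway members. P_PERT propagates log2 fold
changes through the pathway's signed adjacency: PF = ΔE + B·PF with
B[g,u] = sign(u→g)/N_downstream(u), so the total net accumulation is
t_A = w·ΔE with w = colsums((I−B)⁻¹ − I); a singular system skips the
pathway (P_PERT = 1, warned). The null redistributes the observed ΔE
values over random member positions (default 2000 bootstraps); the
p-value is the two-sided tail of t_A around the bootstrap median with a
**mid-p tie correction** (ties get half weight). Without mid-p, pathway
positions with zero downstream weight put t_A exactly at the null median
and pile probability at p = 1; with it the discrete null is approximately
uniform, which the acceptance suite verifies by KS test. Pathways with no
differential members score P_PERT = 1 by definition. The combination is
P_G = c(1 − ln c), c = P_NDE·P_PERT (P_G = 0 at c = 0), significant below
0.05.

Crosstalk: the statistic Rm for a pathway pair in group m is the distance
correlation between the two pathways' member-gene expression submatrices
restricted to that group's samples — the only reading that yields one Rm
per group per pair; this was a genuinely open design point and is the
package's choice. Genes shared by both pathways stay in both submatrices
(shared genes inflate dCor; `drop_shared=True` removes them). The
differential crosstalk R_d = Rm₁ − Rm₂ lies in [−1, 1], is antisymmetric
under swapping the groups, and is ranked by |R_d| — no p-value is
attached to it. dCor itself uses double-centered Euclidean distance
matrices; dCov² is clamped at 0 against round-off, degenerate (constant)
inputs return 0 by convention, and at least 4 samples are required.

## Methylation regions and CNV

Probes carry one of six region classes (TSS1500, TSS200, 5'UTR, 1stExon,
Body, 3'UTR). Region summaries average β over all probe-sample values per
region × group; group pairs are compared by Welch t ("two-sample t-test"
alone leaves the variance assumption open; unequal variances is the
safer default). Region enrichment builds the 2×2 table {in region vs out} ×
{in class vs not} per (region, hyper/hypo) and uses Fisher's exact test
when any expected cell is < 5, χ² otherwise; an empty class reports an NA
odds ratio with p = 1.

CNV: copynum = 2^(x+1); categories +2 above 3.5, +1 on (2.5, 3.5], 0 on
(1.5, 2.5], −1 on [0.5, 1.5], −2 below 0.5 — upper-inclusive bins, fixed
by the worked boundary x = −2 → copynum 0.5 → −1. A gene inherits a
segment's category only under full containment of the gene interval
(1-based inclusive, same chromosome and sample); genes in no segment are
neutral. When several segments of one sample contain a gene, the most
extreme call wins (largest |copynum − 2|, amplification on exact ties) —
the source analysis is silent here and "most extreme" is the
biologically conservative reading for calling events. Group comparison is
a 5-category × group χ² plus per-group amp:del = #{+1,+2}/#{−1,−2}.

## ceRNA and survival

A triplet (lncRNA, miRNA with 3p/5p arm, mRNA) for a contrast requires
all three members differential under the same dual threshold as genes,
the (lncRNA, miRNA) pair in the lncRNA–miRNA table, and (miRNA, gene) in
at least `min_db_support` target tables — default 3 (intersection of all
three databases), the conservative choice where union vs intersection was
unstated. Raising support can only shrink the network (tested). The
differential miRNA–lncRNA correlation is Pearson r per group with
diff = r₁ − r₂.

Kaplan–Meier estimation, Greenwood variances and log-rank tests are
backed by lifelines; events precede censorings at tied times. Median
splits send samples at the median to the low-expression stratum; a
constant expression vector is an error, not a silent single-stratum fit.

## Synthetic cohorts: what they emulate, and what not

`simulate_cohort` generates three groups (A, B, C; default 100 samples
each) with: immune fractions from group-specific Dirichlet distributions
(three boosted cell types per group, boost 4, concentration 300 — tight,
well-separated compositions); expression as signature mixtures with
multiplicative log-normal noise (sd 0.1, a bulk-RNA-seq-like dispersion)
plus extra genes carrying monotone effects ("Down": C > A > B, "Up":
B > A > C, 2 log2 units per step, 40 genes each); methylation β from
Beta(μc, (1−μ)c) with c = 60, a global group-B shift of −0.4 on the logit
scale (B lowest overall) and a planted −0.2 mean-β shift in TSS1500 of
group B; Poisson(12) copy-number events per sample with amp:del odds
A 1.1, B 1.8, C 1.0 and occasional high-level events; small-RNA tables
with one planted ceRNA triplet differential in B vs C, embedded in all
interaction tables among random decoy pairs; and exponential survival
with hazards B 1.5/1000 > A 1.0/1000 > C 0.5/1000 per day under uniform
censoring to day 3000. `CohortConfig.null()` zeroes every effect for
calibration runs. All parameters and the planted truth are recorded in
the bundle and serialized with the cohort.

Not emulated: cross-platform batch structure (the analysis this package
implements removes it by TPM conversion, so the generator assumes none),
count-level sampling noise (expression is continuous), correlated probe
blocks in methylation, subclonal/fractional copy numbers, and non-
proportional hazards. Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted effects under clean
assumptions, not robustness to real-data artifacts.

## Problem sizes and numerics

The test and acceptance runs use desk-scale sizes chosen to make every
statistical check sharp at negligible cost: 60 mixtures for
deconvolution recovery; 150 samples for subtype recovery (per-component
separation ≥ 3σ, verified at run time, with the area-gain threshold at
its 0.10 default); 300 pathways × 2000 bootstraps for null calibration;
20 seeded repetitions for type-I and region-ranking rates; n = 5000 for
the KM median against ln2/λ; 200 repetitions for log-rank size/power
(HR 3, 50 per group); and a 300-sample cohort for the end-to-end
byte-identity run (50 consensus repetitions, 100 bootstraps). Seeds flow
from a single `numpy.random.default_rng`; all TSV output is written with
`%.10g` floats and LF endings, which is what makes same-seed runs
byte-identical.

Known limitations: PAM is O(n²k) per repetition and intended for the
cohort sizes above, not thousands of samples; the SVR step is the runtime
bottleneck of the pipeline (~3 fits per sample); P_PERT's linear solve
assumes the normalized adjacency spectral radius stays below 1 — cyclic
pathways violating this are skipped rather than mis-scored; and the
automatic k selection inherits the usual fragility of elbow criteria on
weakly separated data (hence `force_k`).
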