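"""Estimate immune-cell fractions from bulk expression by SVR deconvolution.

Builds a 22-type marker signature, mixes it into 20 noisy bulk samples
with known fractions, and recovers the fractions. The printed MAE is
the mean absolute error per (sample, cell type) entry; the worst
per-type correlation shows how faithfully each cell type is tracked
across samples.
"""

import numpy as np

from tmescape import estimate_fractions, make_signature, simulate_mixtures

signature = make_signature(n_genes=220, n_cell_types=22, markers_per_type=10, fold=5.0, seed=1)
expr, truth = simulate_mixtures(signature, n_samples=20, noise_sd=0.1, seed=2)

result = estimate_fractions(expr, signature, seed=0)
est = result.fractions

mae = np.abs(est.to_numpy() - truth.to_numpy()).mean()
worst_r = min(np.corrcoef(est.iloc[:, j], truth.iloc[:, j])[0, 1] for j in range(22))
print(f"mean absolute error of recovered fractions: {mae:.4f}")
print(f"worst per-cell-type correlation with truth: {worst_r:.3f}")
print(f"median fit RMSE (z-score scale): {result.fit_stats['rmse'].median():.3f}")
# MAE well below 0.01 and correlations near 1 mean the relative immune
# composition of each bulk sample is essentially recovered.
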