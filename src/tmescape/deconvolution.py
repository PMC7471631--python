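"""Immune-cell deconvolution of bulk expression by nu-support-vector regression.

Per-sample relative fractions of reference cell types are estimated by
regressing the z-scored mixture profile on the z-scored signature matrix
(22 immune cell types by default, LM22-style layout), selecting the
``nu`` with lowest RMSE, clipping negative coefficients and
renormalizing to the probability simplex — the CIBERSORT approach.
Quantile normalization of the original tool is omitted: inputs are
assumed TPM-comparable already.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from tmescape.io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class CellFractions:
    """Samples x cell-types fractions on the probability simplex.

    ``fractions`` is indexed by sample id with cell-type columns; every
    row sums to 1 and entries are non-negative. ``fit_stats`` carries
    per-sample RMSE, the Pearson correlation between the fitted and
    observed mixture and, when permutations were requested, an empirical
    p-value for that correlation.
    """

    fractions: pd.DataFrame
    fit_stats: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.fractions.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("NaN fractions")
        if (arr < -1e-12).any():
            raise ValueError("negative fractions")
        if arr.size and not np.allclose(arr.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("fraction rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.fractions.columns)


def fpkm_to_tpm(values: np.ndarray, sample_id: str = "") -> np.ndarray:
    """Rescale one sample's FPKM vector to TPM: x_i / sum(x) * 1e6."""
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"cannot convert all-zero/invalid column to TPM (sample {sample_id!r})")
    return values / total * 1e6


def to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert an FPKM (or arbitrary-scale) matrix to TPM column-wise."""
    if matrix.unit == "TPM":
        return matrix
    if matrix.unit == "LOG2TPM":
        raise ValueError("cannot convert log-scale matrix to TPM")
    out = matrix.values.apply(lambda col: fpkm_to_tpm(col.to_numpy(), col.name), axis=0)
    return ExpressionMatrix(values=out, unit="TPM")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def estimate_fractions(
    expr: ExpressionMatrix,
    signature: pd.DataFrame,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    n_permutations: int = 0,
    seed: int = 0,
) -> CellFractions:
    """Estimate relative cell-type fractions for every sample.

    Parameters
    ----------
    expr
        Bulk expression, genes x samples, linear scale.
    signature
        Reference profiles, genes x cell types (LM22-style).
    nu_grid
        Candidate ``nu`` values for the linear NuSVR; the fit with
        lowest RMSE (on z-scores) wins.
    n_permutations
        If > 0, a per-sample permutation p-value is computed as the
        fraction of gene-shuffled mixtures whose fit correlation reaches
        the observed one.

    Requires >= 50% of signature genes present in the mixture; the
    intersection is used and missing genes are dropped, not imputed.
    """
    shared = [g for g in signature.index if g in set(expr.gene_ids)]
    if len(shared) < 0.5 * signature.shape[0]:
        raise ValueError(
            f"only {len(shared)}/{signature.shape[0]} signature genes found in "
            "the mixture (need >= 50%)"
        )
    S = signature.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        logger.warning("signature matrix is rank-deficient; fractions may be unstable")
    S_z = (S - S.mean()) / S.std()

    rng = np.random.default_rng(seed)
    X = expr.values.loc[shared].to_numpy(dtype=float)
    frac_rows, stat_rows = [], []
    for j, sample in enumerate(expr.sample_ids):
        w, rmse, corr = _fit_sample(S_z, X[:, j], nu_grid)
        pval = np.nan
        if n_permutations > 0:
            y = X[:, j].copy()
            hits = 0
            for _ in range(n_permutations):
                rng.shuffle(y)
                _, _, c_perm = _fit_sample(S_z, y, nu_grid)
                hits += c_perm >= corr
            pval = hits / n_permutations
        frac_rows.append(w)
        stat_rows.append((rmse, corr, pval))

    fractions = pd.DataFrame(frac_rows, index=expr.sample_ids, columns=signature.columns)
    stats = pd.DataFrame(
        stat_rows, index=expr.sample_ids, columns=["rmse", "correlation", "perm_p"]
    )
    return CellFractions(fractions=fractions, fit_stats=stats)


def _fit_sample(
    S_z: np.ndarray, y: np.ndarray, nu_grid: tuple[float, ...]
) -> tuple[np.ndarray, float, float]:
    """Fit one mixture against the z-scored signature over the nu grid."""
    y_z = _zscore(np.asarray(y, dtype=float))
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=1.0, tol=1e-5)
        model.fit(S_z, y_z)
        coef = model.coef_.ravel()
        fitted = S_z @ coef + model.intercept_
        rmse = float(np.sqrt(np.mean((fitted - y_z) ** 2)))
        if best is None or rmse < best[1]:
            corr = _safe_corr(fitted, y_z)
            best = (coef, rmse, corr)
    coef, rmse, corr = best
    w = np.clip(coef, 0.0, None)
    total = w.sum()
    if total <= 0:  # pathological fit: fall back to uniform
        w = np.full_like(w, 1.0 / len(w))
    else:
        w = w / total
    return w, rmse, corr


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
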