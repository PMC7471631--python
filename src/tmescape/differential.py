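"""Moderated differential testing between TME groups.

A per-feature two-group linear model with empirical-Bayes variance
shrinkage: residual variances are pooled toward a prior (d0, s0^2)
estimated by moment-matching a scaled inverse-chi-square distribution
to the observed variances on the log scale, and the moderated t gains
d0 extra degrees of freedom. This is the standard moderated t-statistic
used throughout microarray/RNA-seq differential analysis.

Expression is tested on log2(TPM + 1); methylation on raw beta values,
where the hyper/hypo thresholds are ratios of group-mean betas
(fold-change on the ratio scale).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: dual DEG threshold: raw p < 0.01 AND BH-adjusted p < 0.05
DEG_RAW_P = 0.01
DEG_ADJ_P = 0.05
#: methylation class thresholds: FC > 1.25 (hyper) / FC < 0.8 (hypo), FDR < 0.01
METH_FC_HYPER = 1.25
METH_FC_HYPO = 0.8
METH_FDR = 0.01


def _fit_inv_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of a scaled inverse-chi-square prior.

    Works on z = log(s^2): under the model z - log(s0^2) follows a
    log-F whose mean/variance involve digamma/trigamma terms; d0 solves
    trigamma(d0/2) = var(z) - trigamma(df/2), inverted numerically.
    Returns d0 = inf when the observed spread is at or below the
    sampling floor (complete shrinkage to s0^2).
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return 0.0, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e_z = z.mean()
    v_z = z.var(ddof=1)
    target = v_z - special.polygamma(1, df / 2)
    if target <= 1e-8:
        s0_sq = float(np.exp(e_z - special.digamma(df / 2) + np.log(df / 2)))
        return np.inf, s0_sq
    f = lambda d0: special.polygamma(1, d0 / 2) - target
    # trigamma is decreasing: bracket the root
    lo, hi = 1e-6, 1e6
    d0 = brentq(f, lo, hi)
    s0_sq = float(
        np.exp(e_z - special.digamma(df / 2) + np.log(df / 2) + special.digamma(d0 / 2) - np.log(d0 / 2))
    )
    return float(d0), s0_sq


def moderated_ttest(
    matrix: pd.DataFrame,
    group_labels: pd.Series | dict,
    contrast: tuple[str, str],
    mode: str = "expression",
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test for every feature (row) of ``matrix``.

    Parameters
    ----------
    matrix
        Features x samples. Expression should be log2(TPM + 1);
        methylation raw betas in [0, 1].
    group_labels
        Sample id -> group label.
    contrast
        ``(group1, group2)``; effects are group1 minus group2 (log
        scale) or group1 / group2 (ratio scale for methylation).
    mode
        ``expression``: log2FC is the difference of group means.
        ``methylation``: FC is the ratio of group-mean betas.
    d0_override
        Force the prior degrees of freedom (0 recovers the classic
        pooled two-sample t exactly).

    Returns a tidy table with log2_fold_change, fold_change, raw_p,
    adjusted_p (Benjamini-Hochberg) and a direction call.
    """
    labels = pd.Series(group_labels)
    g1, g2 = contrast
    s1 = [s for s in matrix.columns if labels.get(s) == g1]
    s2 = [s for s in matrix.columns if labels.get(s) == g2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError(f"need >= 2 samples per group; got {len(s1)} vs {len(s2)}")
    X1 = matrix[s1].to_numpy(dtype=float)
    X2 = matrix[s2].to_numpy(dtype=float)
    n1, n2 = X1.shape[1], X2.shape[1]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    # pooled residual variance from the two-group-mean linear model
    rss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    df_res = n1 + n2 - 2
    s2_g = rss / df_res

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = 0.0 if d0 == 0 else float(np.median(s2_g[s2_g > 0])) if (s2_g > 0).any() else 1.0
    else:
        d0, s0_sq = _fit_inv_chisq_prior(s2_g, df_res)

    if np.isinf(d0):
        s2_post = np.full_like(s2_g, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_res * s2_g) / (d0 + df_res)
        df_total = d0 + df_res

    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    delta = m1 - m2
    zero_var = s2_post <= 0
    if zero_var.any():
        logger.info("%d features with zero variance in both groups -> p = 1", int(zero_var.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / (np.sqrt(s2_post) * se_factor)
    t = np.where(zero_var, 0.0, t)
    if np.isinf(df_total):
        raw_p = 2 * stats.norm.sf(np.abs(t))
    else:
        raw_p = 2 * stats.t.sf(np.abs(t), df=df_total)
    raw_p = np.where(zero_var, 1.0, raw_p)
    adj_p = bh_adjust(raw_p)

    if mode == "expression":
        log2fc = delta
        fc = 2.0 ** log2fc
    elif mode == "methylation":
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(m2 > 0, m1 / np.maximum(m2, 1e-300), np.inf)
            log2fc = np.log2(np.maximum(fc, 1e-300))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "group_contrast": f"{g1}_vs_{g2}",
            "mean_1": m1,
            "mean_2": m2,
            "log2_fold_change": log2fc,
            "fold_change": fc,
            "t": t,
            "raw_p": raw_p,
            "adjusted_p": adj_p,
        }
    ).set_index("feature_id")
    sig = (out["raw_p"] < DEG_RAW_P) & (out["adjusted_p"] < DEG_ADJ_P)
    out["direction"] = np.where(
        ~sig, "ns", np.where(out["log2_fold_change"] > 0, "up", "down")
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def call_degs(diff_table: pd.DataFrame) -> dict[str, set[str]]:
    """Apply the dual threshold (raw p < 0.01 AND adjusted p < 0.05)."""
    sig = (diff_table["raw_p"] < DEG_RAW_P) & (diff_table["adjusted_p"] < DEG_ADJ_P)
    up = set(diff_table.index[sig & (diff_table["log2_fold_change"] > 0)])
    down = set(diff_table.index[sig & (diff_table["log2_fold_change"] < 0)])
    return {"up": up, "down": down, "all": up | down}


def classify_methylation(diff_table: pd.DataFrame) -> pd.DataFrame:
    """Label probes hyper / hypo / ns by fold-change and FDR.

    hyper: FC > 1.25 and FDR < 0.01 (strict inequalities);
    hypo:  FC < 0.8  and FDR < 0.01; everything else ns.
    """
    out = diff_table.copy()
    fdr_ok = out["adjusted_p"] < METH_FDR
    out["class"] = np.where(
        fdr_ok & (out["fold_change"] > METH_FC_HYPER),
        "hyper",
        np.where(fdr_ok & (out["fold_change"] < METH_FC_HYPO), "hypo", "ns"),
    )
    return out


def intersect_sets(named_sets: dict[str, set]) -> dict[frozenset, int]:
    """Counts for every membership pattern across the named sets (Venn regions).

    Keys are frozensets of set names; the value counts elements that
    belong to exactly those sets. Region counts sum to |union|.
    """
    names = list(named_sets)
    universe = set().union(*named_sets.values()) if named_sets else set()
    counts: dict[frozenset, int] = {}
    for elem in universe:
        pattern = frozenset(n for n in names if elem in named_sets[n])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def kruskal_by_column(values: pd.DataFrame, group_labels: pd.Series | dict) -> pd.DataFrame:
    """Kruskal-Wallis rank test of each column across >= 2 groups.

    Used to compare per-cell-type infiltration fractions between TME
    subtypes (samples are rows, cell types columns).
    """
    labels = pd.Series(group_labels).reindex(values.index)
    groups = sorted(labels.dropna().unique())
    rows = []
    for col in values.columns:
        parts = [values.loc[labels == g, col].to_numpy() for g in groups]
        if any(len(p) < 2 for p in parts):
            raise ValueError("need >= 2 samples per group for Kruskal-Wallis")
        try:
            stat, p = stats.kruskal(*parts)
        except ValueError:  # all values identical
            stat, p = 0.0, 1.0
        rows.append((col, stat, p))
    return pd.DataFrame(rows, columns=["feature", "statistic", "p"]).set_index("feature")


def pairwise_contrasts(groups) -> list[tuple[str, str]]:
    """All unordered group pairs, alphabetical: (earlier, later)."""
    return [tuple(pair) for pair in combinations(sorted(set(groups)), 2)]
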