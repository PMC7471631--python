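"""Pathway impact scores and distance-correlation crosstalk.

A pathway's significance combines two probabilities: P_NDE, the
hypergeometric over-representation of differential genes among its
members, and P_PERT, a topology-aware perturbation probability obtained
by propagating log-fold-changes through the pathway's signed gene-gene
graph and bootstrapping the total net accumulation. The global score is
the Fisher-product combination

    P_G = c (1 - ln c),   c = P_NDE * P_PERT,

with P_G < 0.05 calling a pathway significant.

Crosstalk between two significant pathways is the distance correlation
(dCor) between their member-gene expression submatrices within one
sample group, Rm; the differential crosstalk across a two-group
contrast is Rd = Rm1 - Rm2 in [-1, 1], ranked by |Rd|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_G_SIGNIFICANT = 0.05


def p_nde(n_universe: int, n_pathway: int, n_de: int, n_de_in_pathway: int) -> float:
    """Hypergeometric upper-tail P(X >= observed) for pathway over-representation."""
    if not (0 <= n_de_in_pathway <= min(n_pathway, n_de) <= n_universe):
        raise ValueError(
            f"inconsistent counts: universe={n_universe}, pathway={n_pathway}, "
            f"de={n_de}, overlap={n_de_in_pathway}"
        )
    if n_pathway > n_universe or n_de > n_universe:
        raise ValueError("pathway/DE set larger than universe")
    return float(stats.hypergeom.sf(n_de_in_pathway - 1, n_universe, n_pathway, n_de))


def _perturbation_weights(genes: list[str], edges: list[tuple[str, str, int]]) -> np.ndarray | None:
    """Column sums of (I - B)^-1 - I for the normalized signed adjacency.

    B[g, u] = sign(u -> g) / N_downstream(u). The perturbation factor
    solves PF = dE + B @ PF, so the total net accumulation is
    t_A = sum(PF - dE) = w . dE with w = colsums((I - B)^-1 - I).
    Returns None when (I - B) is singular.
    """
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    B = np.zeros((n, n))
    n_ds = np.zeros(n)
    for src, dst, sign in edges:
        if src in idx and dst in idx:
            n_ds[idx[src]] += 1
    for src, dst, sign in edges:
        if src in idx and dst in idx:
            B[idx[dst], idx[src]] += sign / n_ds[idx[src]]
    A = np.eye(n) - B
    if abs(np.linalg.det(A)) < 1e-12:
        return None
    M = np.linalg.inv(A) - np.eye(n)
    return M.sum(axis=0)


def p_pert(
    pathway_genes: list[str],
    edges: list[tuple[str, str, int]],
    de_log_fold_changes: dict[str, float],
    all_de_pool: list[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap perturbation probability and total net accumulation.

    dE is the log2 fold change for differential member genes and 0
    otherwise. The null redistributes ``n_de`` values drawn from the
    global DE pool over random member positions; P_PERT is the
    two-sided tail of the total accumulation t_A around the bootstrap
    median. A pathway with no differential members (t_A = 0) or a
    singular propagation system scores P_PERT = 1.
    """
    w = _perturbation_weights(pathway_genes, edges)
    if w is None:
        logger.warning("singular pathway system; P_PERT set to 1")
        return 1.0, 0.0
    de = np.array([de_log_fold_changes.get(g, 0.0) for g in pathway_genes])
    t_a = float(w @ de)
    n_de = int(np.count_nonzero(de))
    if n_de == 0 or not all_de_pool:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    pool = np.asarray(all_de_pool, dtype=float)
    n = len(pathway_genes)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        de_b = np.zeros(n)
        pos = rng.choice(n, size=min(n_de, n), replace=False)
        de_b[pos] = rng.choice(pool, size=len(pos), replace=True)
        boots[b] = w @ de_b
    med = np.median(boots)
    dev = np.abs(boots - med)
    obs = abs(t_a - med)
    # mid-p: half-weight ties so the discrete null stays ~uniform
    p = (np.sum(dev > obs) + 0.5 * np.sum(dev == obs) + 0.5) / (n_boot + 1.0)
    return float(min(p, 1.0)), t_a


def combine_global(p_nde_value: float, p_pert_value: float) -> float:
    """Fisher-product combination: P_G = c(1 - ln c), c = P_NDE * P_PERT."""
    if not (0 <= p_nde_value <= 1 and 0 <= p_pert_value <= 1):
        raise ValueError("input probabilities must lie in [0, 1]")
    c = p_nde_value * p_pert_value
    if c == 0:
        return 0.0
    return float(c * (1.0 - np.log(c)))


def score_pathways(
    gene_sets: dict[str, set[str]],
    edges: dict[str, list[tuple[str, str, int]]],
    diff_table: pd.DataFrame,
    universe: list[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every pathway: P_NDE, P_PERT, total accumulation and P_G.

    ``diff_table`` is a moderated-test result; differential genes are
    those passing the dual DEG threshold, with their log2 fold changes
    as the perturbation input.
    """
    from tmescape.differential import call_degs

    de_genes = call_degs(diff_table)["all"]
    universe_set = set(universe)
    de_in_universe = de_genes & universe_set
    lfc = diff_table.loc[list(de_in_universe), "log2_fold_change"].to_dict()
    pool = list(lfc.values())
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        members_u = sorted(members & universe_set)
        overlap = len(set(members_u) & de_in_universe)
        pn = p_nde(len(universe_set), len(members_u), len(de_in_universe), overlap)
        pp, t_a = p_pert(
            members_u,
            edges.get(name, []),
            lfc,
            pool,
            n_boot=n_boot,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append((name, pn, pp, combine_global(pn, pp), t_a))
    return pd.DataFrame(
        rows, columns=["pathway_id", "p_nde", "p_pert", "p_g", "total_net_accumulation"]
    ).set_index("pathway_id")


def distance_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Distance correlation between two multivariate samples in [0, 1].

    Rows are samples (>= 4 required); columns are variables. Computed
    from double-centered Euclidean distance matrices:
    dCov^2 = mean(A * B), dCor = dCov / sqrt(dVarX dVarY); returns 0
    when either marginal distance variance is degenerate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    if n != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples (rows)")
    if n < 4:
        raise ValueError("distance correlation needs >= 4 samples")
    A = _double_center(_pdist(X))
    B = _double_center(_pdist(Y))
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def _pdist(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def _double_center(D: np.ndarray) -> np.ndarray:
    return D - D.mean(axis=0, keepdims=True) - D.mean(axis=1, keepdims=True) + D.mean()


@dataclass
class CrosstalkMatrix:
    """Per-group pathway-pair crosstalk Rm and the differential Rd."""

    contrast: tuple[str, str]
    rm: dict[str, pd.DataFrame]  # group -> symmetric pathway x pathway dCor
    rd: pd.DataFrame  # rm[group1] - rm[group2]


def crosstalk(
    expr: pd.DataFrame,
    group_labels: pd.Series | dict,
    pathway_members: dict[str, set[str]],
    contrast: tuple[str, str],
    drop_shared: bool = False,
) -> CrosstalkMatrix:
    """Distance-correlation crosstalk between pathways, per group.

    For each pair of pathways and each group of the contrast, Rm is the
    dCor between the pathways' member-gene expression submatrices over
    that group's samples; Rd = Rm1 - Rm2 (group order as given, so
    swapping the contrast negates Rd). Genes shared by both pathways
    are kept in both submatrices unless ``drop_shared``.
    """
    labels = pd.Series(group_labels)
    names = sorted(pathway_members)
    gene_index = set(expr.index)
    members = {}
    for p in names:
        present = sorted(pathway_members[p] & gene_index)
        if len(present) < 2:
            raise ValueError(f"pathway {p} has < 2 member genes in the expression matrix")
        members[p] = present
    rm: dict[str, pd.DataFrame] = {}
    for g in contrast:
        samples = [s for s in expr.columns if labels.get(s) == g]
        M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for i, p in enumerate(names):
            for q in names[i + 1 :]:
                gp, gq = members[p], members[q]
                if drop_shared:
                    shared = set(gp) & set(gq)
                    gp = [x for x in gp if x not in shared]
                    gq = [x for x in gq if x not in shared]
                    if len(gp) < 1 or len(gq) < 1:
                        M.loc[p, q] = M.loc[q, p] = np.nan
                        continue
                X = expr.loc[gp, samples].to_numpy().T
                Y = expr.loc[gq, samples].to_numpy().T
                val = distance_correlation(X, Y)
                M.loc[p, q] = M.loc[q, p] = val
        rm[g] = M
    rd = rm[contrast[0]] - rm[contrast[1]]
    return CrosstalkMatrix(contrast=contrast, rm=rm, rd=rd)
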