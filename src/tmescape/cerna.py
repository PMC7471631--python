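"""Competing-endogenous-RNA (ceRNA) network assembly and correlation analysis.

A ceRNA triplet (lncRNA, miRNA, mRNA) for a group contrast requires all
three members to be differentially expressed in that contrast, the
lncRNA-miRNA pair to appear in the lncRNA-miRNA interaction table
(miRcode-style), and the miRNA-gene pair to appear in at least
``min_db_support`` of the miRNA-target tables (miRDB / miRTarBase /
TargetScan-style; default: all three — the conservative intersection).
miRNA identifiers carry their 3p/5p arm label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from tmescape.io import InteractionTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    gene_id: str
    contrast: str
    supporting_dbs: frozenset[str]


def build_cerna(
    deg_lnc: set[str],
    deg_mi: set[str],
    deg_gene: set[str],
    lnc_mi_table: InteractionTable,
    target_tables: list[InteractionTable],
    min_db_support: int = 3,
    contrast: str = "",
) -> list[CeRNATriplet]:
    """Assemble the ceRNA triplet set for one contrast.

    Raising ``min_db_support`` can only shrink the result (monotone).
    Empty interaction tables yield an empty network with a warning.
    """
    if not lnc_mi_table.pairs or all(not t.pairs for t in target_tables):
        logger.warning("empty interaction table(s); ceRNA network is empty")
        return []
    lnc_mi = {(l, m) for (l, m) in lnc_mi_table.pairs if l in deg_lnc and m in deg_mi}
    support: dict[tuple[str, str], set[str]] = {}
    for table in target_tables:
        for (m, g) in table.pairs:
            if m in deg_mi and g in deg_gene:
                support.setdefault((m, g), set()).add(table.source_db)
    triplets = []
    for (l, m) in sorted(lnc_mi):
        for (m2, g), dbs in sorted(support.items()):
            if m2 == m and len(dbs) >= min_db_support:
                triplets.append(
                    CeRNATriplet(
                        lncrna_id=l,
                        mirna_id=m,
                        gene_id=g,
                        contrast=contrast,
                        supporting_dbs=frozenset(dbs),
                    )
                )
    return triplets


def diff_correlation(
    mirna_expr: pd.DataFrame,
    lncrna_expr: pd.DataFrame,
    group_labels: pd.Series | dict,
    contrast: tuple[str, str],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-pair differential miRNA-lncRNA Pearson correlation.

    For each (miRNA, lncRNA) pair, Pearson r is computed within each
    group of the contrast over that group's samples; ``diff`` is
    r(group1) - r(group2) (so swapping the contrast negates it).
    """
    labels = pd.Series(group_labels)
    g1, g2 = contrast
    s1 = [s for s in mirna_expr.columns if labels.get(s) == g1]
    s2 = [s for s in mirna_expr.columns if labels.get(s) == g2]
    if pairs is None:
        pairs = [(m, l) for m in mirna_expr.index for l in lncrna_expr.index]
    rows = []
    for m, l in pairs:
        r1, p1 = _corr(mirna_expr.loc[m, s1], lncrna_expr.loc[l, s1])
        r2, p2 = _corr(mirna_expr.loc[m, s2], lncrna_expr.loc[l, s2])
        rows.append((m, l, r1, p1, r2, p2, r1 - r2))
    return pd.DataFrame(
        rows,
        columns=["mirna", "lncrna", f"r_{g1}", f"p_{g1}", f"r_{g2}", f"p_{g2}", "diff"],
    )


def _corr(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def km_by_median(
    expr_vector: pd.Series, survival_table: pd.DataFrame
) -> tuple[float, KaplanMeierFitter, KaplanMeierFitter]:
    """Median-split Kaplan-Meier comparison for one RNA's expression.

    Samples at or below the median go to the low-expression stratum.
    Returns the log-rank p-value and the fitted high/low KM curves.
    A constant expression vector admits no split and is an error.
    """
    surv = survival_table.set_index("sample")
    common = [s for s in expr_vector.index if s in surv.index]
    x = expr_vector.loc[common].astype(float)
    if x.nunique() <= 1:
        raise ValueError("constant expression vector: no median split possible")
    med = x.median()
    high = x.index[x > med]
    low = x.index[x <= med]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("degenerate median split (all samples on one side)")
    res = logrank_test(
        surv.loc[high, "time"],
        surv.loc[low, "time"],
        event_observed_A=surv.loc[high, "event"],
        event_observed_B=surv.loc[low, "event"],
    )
    kmf_high = KaplanMeierFitter().fit(
        surv.loc[high, "time"], surv.loc[high, "event"], label="high"
    )
    kmf_low = KaplanMeierFitter().fit(
        surv.loc[low, "time"], surv.loc[low, "event"], label="low"
    )
    return float(res.p_value), kmf_high, kmf_low
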