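"""Methylation region analysis and copy-number discretization/group tests.

Copy-number segments carry a log2 ratio x; the estimated copy number is
copynum = 2^(x + 1), discretized into five categories (two-copy loss to
two-or-more-copy gain). A gene inherits a segment's category only when
the segment interval fully contains the gene interval (1-based
inclusive); a gene covered by no segment is copy-neutral.

Methylation betas are summarized per genomic region class (TSS1500,
TSS200, 5'UTR, 1st exon, gene body, 3'UTR) and group, compared by
Welch two-sample t-tests, and hyper-/hypomethylated probe classes are
tested for region enrichment with Fisher's exact test (any expected
cell < 5) or the chi-square test otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tmescape.io import REGION_CLASSES, ProbeAnnotation, Segment

logger = logging.getLogger(__name__)

CNV_CATEGORIES = (-2, -1, 0, 1, 2)


def discretize_cnv(segment_mean: float) -> tuple[float, int]:
    """Map a segment's log2 ratio x to (copynum, category).

    copynum = 2^(x + 1); category +2 above copynum 3.5, +1 on
    (2.5, 3.5], 0 on (1.5, 2.5], -1 on [0.5, 1.5], -2 below 0.5.
    """
    copynum = float(2.0 ** (segment_mean + 1.0))
    if copynum > 3.5:
        cat = 2
    elif copynum > 2.5:
        cat = 1
    elif copynum > 1.5:
        cat = 0
    elif copynum >= 0.5:
        cat = -1
    else:
        cat = -2
    return copynum, cat


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive gene coordinates."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int


def annotate_segments(
    segments: list[Segment], gene_intervals: list[GeneInterval]
) -> pd.DataFrame:
    """Assign CNV categories to genes by full segment containment.

    A gene gets a segment's category iff segment.start <= gene.start and
    gene.end <= segment.end on the same chromosome, per sample. Genes
    inside no segment of a sample are copy-neutral (category 0,
    copynum 2). When several segments of one sample contain a gene, the
    most extreme call wins (largest |copynum - 2|; amplification wins
    ties).
    """
    seg_chroms = {s.chromosome for s in segments}
    gene_chroms = {g.chromosome for g in gene_intervals}
    if segments and gene_intervals and not (seg_chroms & gene_chroms):
        raise ValueError(
            f"no shared chromosome labels: segments use {sorted(seg_chroms)}, "
            f"genes use {sorted(gene_chroms)}"
        )
    samples = sorted({s.sample_id for s in segments})
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in gene_intervals:
        by_chrom.setdefault(g.chromosome, []).append(g)
    best: dict[tuple[str, str], tuple[float, int]] = {}
    for seg in segments:
        copynum, cat = discretize_cnv(seg.segment_mean)
        for gene in by_chrom.get(seg.chromosome, []):
            if seg.start <= gene.start and gene.end <= seg.end:
                key = (gene.gene_symbol, seg.sample_id)
                prev = best.get(key)
                # most extreme call wins; amplification wins exact ties
                if prev is None or (abs(copynum - 2.0), copynum) > (abs(prev[0] - 2.0), prev[0]):
                    best[key] = (copynum, cat)
    rows = []
    for gene in gene_intervals:
        for sample in samples:
            copynum, cat = best.get((gene.gene_symbol, sample), (2.0, 0))
            rows.append((gene.gene_symbol, sample, copynum, cat))
    return pd.DataFrame(rows, columns=["gene", "sample", "copynum", "category"])


def cnv_group_test(
    gene_cnv: pd.DataFrame, group_labels: pd.Series | dict
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chi-square test of the 5-category CNV distribution across groups.

    Returns the per-contrast chi-square results (all unordered group
    pairs plus the omnibus all-group test) and per-group amplification
    to deletion ratios amp:del = #{+1,+2} / #{-1,-2}.
    """
    labels = pd.Series(group_labels)
    df = gene_cnv.copy()
    df["group"] = df["sample"].map(labels)
    df = df.dropna(subset=["group"])
    groups = sorted(df["group"].unique())
    table = pd.crosstab(df["group"], df["category"]).reindex(
        index=groups, columns=list(CNV_CATEGORIES), fill_value=0
    )
    rows = []
    combos = [tuple(groups)] if len(groups) <= 2 else (
        [tuple(groups)] + list(itertools.combinations(groups, 2))
    )
    for combo in combos:
        sub = table.loc[list(combo)]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if sub.shape[1] < 2 or (sub.to_numpy().sum(axis=1) == 0).any():
            stat, p, dof = 0.0, 1.0, 0
        else:
            stat, p, dof, _ = stats.chi2_contingency(sub.to_numpy())
        rows.append(("_vs_".join(combo), stat, dof, p))
    tests = pd.DataFrame(rows, columns=["contrast", "chi2", "dof", "p"]).set_index("contrast")
    ratio_rows = []
    for g in groups:
        amp = int(((df["group"] == g) & (df["category"] > 0)).sum())
        dele = int(((df["group"] == g) & (df["category"] < 0)).sum())
        ratio_rows.append((g, amp, dele, amp / dele if dele else np.inf))
    ratios = pd.DataFrame(
        ratio_rows, columns=["group", "n_amp", "n_del", "amp_del_ratio"]
    ).set_index("group")
    return tests, ratios


def region_summary(
    betas: pd.DataFrame,
    annotation: list[ProbeAnnotation],
    group_labels: pd.Series | dict,
) -> pd.DataFrame:
    """Mean beta per region class x group, with pairwise Welch t-tests.

    The mean is over all probe-sample beta values of the region's probes
    and the group's samples; each group pair is compared by a Welch
    (unequal-variance) two-sample t-test on those pooled values.
    """
    labels = pd.Series(group_labels)
    region_of = {a.probe_id: a.region_class for a in annotation}
    groups = sorted(labels.dropna().unique())
    rows = []
    for region in REGION_CLASSES:
        probes = [p for p in betas.index if region_of.get(p) == region]
        if not probes:
            continue
        pooled = {}
        for g in groups:
            samples = [s for s in betas.columns if labels.get(s) == g]
            vals = betas.loc[probes, samples].to_numpy().ravel()
            pooled[g] = vals
            rows.append(
                {
                    "region_class": region,
                    "group": g,
                    "kind": "mean",
                    "contrast": "",
                    "mean_beta": float(vals.mean()),
                    "n_probes": len(probes),
                    "t": np.nan,
                    "p": np.nan,
                }
            )
        for g1, g2 in itertools.combinations(groups, 2):
            if np.ptp(pooled[g1]) == 0 and np.ptp(pooled[g2]) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(pooled[g1], pooled[g2], equal_var=False)
            rows.append(
                {
                    "region_class": region,
                    "group": "",
                    "kind": "test",
                    "contrast": f"{g1}_vs_{g2}",
                    "mean_beta": np.nan,
                    "n_probes": len(probes),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def region_enrichment(
    methylation_classes: pd.Series, annotation: list[ProbeAnnotation]
) -> pd.DataFrame:
    """Enrichment of hyper/hypo probes in each region class.

    For each (region, class) a 2x2 table {in region vs out} x {in class
    vs not} is tested: Fisher's exact test when any expected cell is
    < 5, chi-square otherwise. No probes in a class -> OR reported NA
    with p = 1.
    """
    region_of = {a.probe_id: a.region_class for a in annotation}
    probes = [p for p in methylation_classes.index if p in region_of]
    cls = methylation_classes.loc[probes]
    rows = []
    for region in REGION_CLASSES:
        in_region = np.array([region_of[p] == region for p in probes])
        for klass in ("hyper", "hypo"):
            in_class = (cls == klass).to_numpy()
            a = int((in_region & in_class).sum())
            b = int((in_region & ~in_class).sum())
            c = int((~in_region & in_class).sum())
            d = int((~in_region & ~in_class).sum())
            if in_class.sum() == 0:
                rows.append((region, klass, a, np.nan, 1.0, "none"))
                continue
            tab = np.array([[a, b], [c, d]])
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
            expected = stats.contingency.expected_freq(tab) if tab.sum() else np.zeros((2, 2))
            if (expected < 5).any():
                _, p = stats.fisher_exact(tab)
                method = "fisher"
            else:
                _, p, _, _ = stats.chi2_contingency(tab, correction=False)
                method = "chi2"
            rows.append((region, klass, a, odds, float(p), method))
    return pd.DataFrame(
        rows, columns=["region_class", "class", "n_in_region", "odds_ratio", "p", "method"]
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation and p-value between two numeric vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
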