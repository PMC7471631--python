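"""End-to-end pipeline: deconvolution through survival, file-to-file.

Each stage reads only written files (from the cohort directory or an
earlier stage's output) and writes tidy TSVs, so the pipeline is
restartable and two same-seed runs produce byte-identical results. A
``manifest.json`` records seeds, stage completion and feature counts at
every filter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tmescape import cerna, consensus, deconvolution, differential, epigenome
from tmescape import pathways as pw
from tmescape import survival as surv
from tmescape.epigenome import GeneInterval
from tmescape.io import (
    read_edges,
    read_expression,
    read_gmt,
    read_interactions,
    read_methylation,
    read_probe_annotation,
    read_segments,
    read_survival,
)

logger = logging.getLogger(__name__)

STAGES = (
    "deconvolution",
    "clustering",
    "differential_expression",
    "methylation",
    "pathway_crosstalk",
    "cnv",
    "cerna",
    "survival",
)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full run.

    Thresholds default to the pipeline's standard values: DEG raw
    p < 0.01 with BH-adjusted p < 0.05; methylation fold change
    > 1.25 / < 0.8 at FDR < 0.01; pathway P_G < 0.05.
    """

    cohort_dir: str = "."
    out_dir: str = "results"
    stages: tuple[str, ...] = STAGES
    expression_unit: str = "FPKM"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    reps: int = 100
    p_item: float = 0.8
    cluster_method: str = "kmeans"
    force_k: int | None = None
    nu_grid: tuple[float, ...] = deconvolution.DEFAULT_NU_GRID
    n_permutations: int = 0
    n_boot: int = 200
    min_db_support: int = 3
    p_g_threshold: float = 0.05
    seed: int = 0
    group_names: tuple[str, ...] = ("A", "B", "C")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(getattr(cfg, k), tuple) else v)
        return cfg


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; return (and write) the manifest."""
    cdir = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "counts": {}}
    rng = np.random.default_rng(config.seed)

    labels: pd.Series | None = None
    contrasts: list[tuple[str, str]] = []
    deg_tables: dict[tuple[str, str], pd.DataFrame] = {}

    def _fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = f"failed: {exc}"
        _dump_manifest(manifest, out)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc

    # --- deconvolution ---------------------------------------------------
    if "deconvolution" in config.stages:
        try:
            expr, _ = read_expression(cdir / "expression.tsv", unit=config.expression_unit)
            signature = pd.read_csv(cdir / "signature.tsv", sep="\t", index_col=0)
            tpm = deconvolution.to_tpm(expr)
            fractions = deconvolution.estimate_fractions(
                tpm,
                signature,
                nu_grid=config.nu_grid,
                n_permutations=config.n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            _write(fractions.fractions, out / "fractions.tsv")
            _write(fractions.fit_stats, out / "fit_stats.tsv")
            manifest["stages"]["deconvolution"] = "completed"
            manifest["counts"]["n_samples"] = fractions.fractions.shape[0]
        except Exception as exc:  # noqa: BLE001 - stage-named halt
            _fail("deconvolution", exc)

    # --- clustering ------------------------------------------------------
    if "clustering" in config.stages:
        try:
            fr = pd.read_csv(out / "fractions.tsv", sep="\t", index_col=0)
            result = consensus.consensus_cluster(
                fr.to_numpy(),
                k_range=config.k_range,
                reps=config.reps,
                p_item=config.p_item,
                method=config.cluster_method,
                seed=int(rng.integers(2**31 - 1)),
                force_k=config.force_k,
            )
            names = list(config.group_names) + [
                f"G{i}" for i in range(len(config.group_names), result.chosen_k)
            ]
            labels = pd.Series(
                [names[l] for l in result.labels], index=fr.index, name="group"
            )
            labels.to_csv(out / "labels.tsv", sep="\t", lineterminator="\n")
            cdf_rows = [
                (k, float(g), float(v))
                for k in result.k_range
                for g, v in zip(consensus.CDF_GRID, result.cdf[k])
            ]
            _write(
                pd.DataFrame(cdf_rows, columns=["k", "consensus", "cdf"]),
                out / "consensus_cdf.tsv",
                index=False,
            )
            for k in result.k_range:
                _write(
                    pd.DataFrame(result.consensus[k], index=fr.index, columns=fr.index),
                    out / f"consensus_k{k}.tsv",
                )
            manifest["stages"]["clustering"] = "completed"
            manifest["counts"]["chosen_k"] = result.chosen_k
        except Exception as exc:
            _fail("clustering", exc)

    if labels is None and (out / "labels.tsv").exists():
        labels = pd.read_csv(out / "labels.tsv", sep="\t", index_col=0)["group"]
    if labels is not None:
        contrasts = differential.pairwise_contrasts(labels)

    # --- differential expression ----------------------------------------
    if "differential_expression" in config.stages:
        try:
            expr, _ = read_expression(cdir / "expression.tsv", unit=config.expression_unit)
            tpm = deconvolution.to_tpm(expr)
            log_expr = np.log2(tpm.values + 1.0)
            sets = {}
            for c in contrasts:
                table = differential.moderated_ttest(log_expr, labels, c)
                deg_tables[c] = table
                _write(table, out / f"deg_{c[0]}_vs_{c[1]}.tsv")
                degs = differential.call_degs(table)
                sets[f"{c[0]}_vs_{c[1]}"] = degs["all"]
                manifest["counts"][f"degs_{c[0]}_vs_{c[1]}"] = len(degs["all"])
            venn = differential.intersect_sets(sets)
            _write(
                pd.DataFrame(
                    [("+".join(sorted(k)), v) for k, v in sorted(venn.items(), key=lambda x: sorted(x[0]))],
                    columns=["region", "count"],
                ),
                out / "deg_venn.tsv",
                index=False,
            )
            manifest["counts"]["common_degs"] = venn.get(
                frozenset(sets), 0
            )
            manifest["stages"]["differential_expression"] = "completed"
        except Exception as exc:
            _fail("differential_expression", exc)

    # --- methylation -----------------------------------------------------
    if "methylation" in config.stages:
        try:
            betas, _ = read_methylation(cdir / "methylation.tsv")
            annot = read_probe_annotation(cdir / "probe_annotation.tsv")
            summary = epigenome.region_summary(betas, annot, labels)
            _write(summary, out / "methylation_regions.tsv", index=False)
            for c in contrasts:
                table = differential.moderated_ttest(betas, labels, c, mode="methylation")
                table = differential.classify_methylation(table)
                _write(table, out / f"dmp_{c[0]}_vs_{c[1]}.tsv")
                enrich = epigenome.region_enrichment(table["class"], annot)
                _write(enrich, out / f"region_enrichment_{c[0]}_vs_{c[1]}.tsv", index=False)
                manifest["counts"][f"dmp_{c[0]}_vs_{c[1]}"] = int(
                    (table["class"] != "ns").sum()
                )
            manifest["stages"]["methylation"] = "completed"
        except Exception as exc:
            _fail("methylation", exc)

    # --- pathway crosstalk -----------------------------------------------
    if "pathway_crosstalk" in config.stages:
        try:
            gene_sets = read_gmt(cdir / "pathways.gmt")
            edges = read_edges(cdir / "pathway_edges.tsv")
            expr, _ = read_expression(cdir / "expression.tsv", unit=config.expression_unit)
            tpm = deconvolution.to_tpm(expr)
            log_expr = np.log2(tpm.values + 1.0)
            for c in contrasts:
                table = deg_tables.get(c)
                if table is None:
                    table = differential.moderated_ttest(log_expr, labels, c)
                scores = pw.score_pathways(
                    gene_sets,
                    edges,
                    table,
                    universe=list(log_expr.index),
                    n_boot=config.n_boot,
                    seed=int(rng.integers(2**31 - 1)),
                )
                _write(scores, out / f"pathway_scores_{c[0]}_vs_{c[1]}.tsv")
                sig = scores.index[scores["p_g"] < config.p_g_threshold]
                manifest["counts"][f"sig_pathways_{c[0]}_vs_{c[1]}"] = len(sig)
                members = {p: gene_sets[p] for p in sig}
                if len(members) >= 2:
                    ct = pw.crosstalk(log_expr, labels, members, c)
                    _write(ct.rd, out / f"crosstalk_rd_{c[0]}_vs_{c[1]}.tsv")
                    for g, M in ct.rm.items():
                        _write(M, out / f"crosstalk_rm_{g}_{c[0]}_vs_{c[1]}.tsv")
            manifest["stages"]["pathway_crosstalk"] = "completed"
        except Exception as exc:
            _fail("pathway_crosstalk", exc)

    # --- CNV --------------------------------------------------------------
    if "cnv" in config.stages:
        try:
            segments = read_segments(cdir / "segments.seg")
            gi_df = pd.read_csv(cdir / "gene_intervals.tsv", sep="\t")
            gene_intervals = [
                GeneInterval(r.gene, r.chromosome, int(r.start), int(r.end))
                for r in gi_df.itertuples(index=False)
            ]
            gene_cnv = epigenome.annotate_segments(segments, gene_intervals)
            _write(gene_cnv, out / "gene_cnv.tsv", index=False)
            tests, ratios = epigenome.cnv_group_test(gene_cnv, labels)
            _write(tests, out / "cnv_tests.tsv")
            _write(ratios, out / "cnv_ratios.tsv")
            manifest["counts"]["cnv_events"] = int((gene_cnv["category"] != 0).sum())
            manifest["stages"]["cnv"] = "completed"
        except Exception as exc:
            _fail("cnv", exc)

    # --- ceRNA -------------------------------------------------------------
    if "cerna" in config.stages:
        try:
            mirna, _ = read_expression(cdir / "mirna_expression.tsv", unit="FPKM")
            lncrna, _ = read_expression(cdir / "lncrna_expression.tsv", unit="FPKM")
            expr, _ = read_expression(cdir / "expression.tsv", unit=config.expression_unit)
            lnc_mi = read_interactions(cdir / "interactions_lnc_mi.tsv", "lnc_mi", "mircode_like")
            targets = [
                read_interactions(cdir / f"interactions_{db}.tsv", "mi_gene", db)
                for db in ("targetdb1", "targetdb2", "targetdb3")
            ]
            log = lambda m: np.log2(m.values + 1.0)
            all_rows = []
            for c in contrasts:
                deg_g = differential.call_degs(
                    deg_tables.get(c)
                    if c in deg_tables
                    else differential.moderated_ttest(
                        np.log2(deconvolution.to_tpm(expr).values + 1.0), labels, c
                    )
                )["all"]
                deg_m = differential.call_degs(
                    differential.moderated_ttest(log(mirna), labels, c)
                )["all"]
                deg_l = differential.call_degs(
                    differential.moderated_ttest(log(lncrna), labels, c)
                )["all"]
                triplets = cerna.build_cerna(
                    deg_l, deg_m, deg_g, lnc_mi, targets,
                    min_db_support=config.min_db_support,
                    contrast=f"{c[0]}_vs_{c[1]}",
                )
                manifest["counts"][f"cerna_{c[0]}_vs_{c[1]}"] = len(triplets)
                all_rows += [
                    (t.contrast, t.lncrna_id, t.mirna_id, t.gene_id, ";".join(sorted(t.supporting_dbs)))
                    for t in triplets
                ]
            _write(
                pd.DataFrame(
                    all_rows, columns=["contrast", "lncrna", "mirna", "gene", "dbs"]
                ),
                out / "cerna_triplets.tsv",
                index=False,
            )
            manifest["stages"]["cerna"] = "completed"
        except Exception as exc:
            _fail("cerna", exc)

    # --- survival ----------------------------------------------------------
    if "survival" in config.stages:
        try:
            st = read_survival(cdir / "survival.tsv")
            st = st.drop(columns=[c for c in ("group",) if c in st.columns])
            st["group"] = st["sample"].map(labels)
            stat, dof, p = surv.logrank(st)
            rows = []
            for g, sub in st.groupby("group"):
                curve = surv.km_estimate(sub["time"], sub["event"])
                rows += [
                    (g, t, s, n, v)
                    for t, s, n, v in zip(
                        curve.event_times, curve.survival, curve.at_risk, curve.greenwood_var
                    )
                ]
            _write(
                pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk", "greenwood_var"]),
                out / "km_curves.tsv",
                index=False,
            )
            _write(
                pd.DataFrame([(stat, dof, p)], columns=["chi2", "dof", "p"]),
                out / "logrank.tsv",
                index=False,
            )
            manifest["counts"]["logrank_p"] = p
            manifest["stages"]["survival"] = "completed"
        except Exception as exc:
            _fail("survival", exc)

    _dump_manifest(manifest, out)
    return manifest


def _dump_manifest(manifest: dict, out: Path) -> None:
    import tmescape

    manifest["version"] = tmescape.__version__
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
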