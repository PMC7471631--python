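"""Synthetic multi-omic cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
bulk expression as noisy linear mixtures of an immune signature matrix
(22 cell types by default, LM22-style), three TME groups (A, B, C) with
group-specific immune composition, monotone differential gene sets
("Down": C > A > B; "Up": B > A > C), region- and group-structured
methylation betas (group B lowest), copy-number segments with
group-specific amplification:deletion odds (B-like 1.8:1), exponential
survival with group hazards ordered B worst / C best, and toy
interaction tables with embedded ceRNA triplets.

Expression noise is multiplicative log-normal; methylation betas are
Beta-distributed with group effects applied on the logit scale except
for the planted region effect, which is a direct shift of the mean
beta; survival uses exponential event times with uniform censoring.
All randomness flows from a single numpy ``default_rng(seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tmescape.io import (
    REGION_CLASSES,
    ExpressionMatrix,
    InteractionTable,
    ProbeAnnotation,
    Segment,
    write_edges,
    write_expression,
    write_gmt,
    write_interactions,
    write_methylation,
    write_probe_annotation,
    write_segments,
    write_survival,
)
from tmescape.epigenome import GeneInterval


# ---------------------------------------------------------------------------
# signature + mixtures
# ---------------------------------------------------------------------------


def make_signature(
    n_genes: int = 220,
    n_cell_types: int = 22,
    markers_per_type: int = 10,
    fold: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a marker-structured reference signature matrix.

    Every cell type receives ``markers_per_type`` exclusive marker genes
    whose value exceeds that gene's value in every other type by at
    least ``fold``. Non-marker entries are a log-normal background.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if n_genes < n_cell_types * markers_per_type:
        raise ValueError(
            f"need n_genes >= n_cell_types * markers_per_type "
            f"({n_cell_types * markers_per_type}), got {n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = [f"SG{i:04d}" for i in range(n_genes)]
    types = [f"CT{i:02d}" for i in range(n_cell_types)]
    S = rng.lognormal(mean=1.0, sigma=0.5, size=(n_genes, n_cell_types))
    for t in range(n_cell_types):
        rows = slice(t * markers_per_type, (t + 1) * markers_per_type)
        other_max = np.delete(S[rows], t, axis=1).max(axis=1)
        S[rows, t] = other_max * fold * (1.0 + rng.uniform(0.1, 0.5, markers_per_type))
    return pd.DataFrame(S, index=genes, columns=types)


def simulate_mixtures(
    signature: pd.DataFrame,
    n_samples: int,
    dirichlet_alpha: float | np.ndarray = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    fractions: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Mix signature columns with Dirichlet fractions and log-normal noise.

    Column j of the output is ``S @ f_j * exp(eps)`` with per-gene,
    per-sample ``eps ~ Normal(0, noise_sd^2)``. Returns the expression
    matrix (unit FPKM, arbitrary linear scale) and the true fractions.
    Supply ``fractions`` to mix pre-specified compositions instead.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    S = signature.to_numpy(dtype=float)
    k = S.shape[1]
    if fractions is None:
        alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (k,))
        F = rng.dirichlet(alpha, size=n_samples)
        samples = [f"S{j:04d}" for j in range(n_samples)]
        fractions = pd.DataFrame(F, index=samples, columns=signature.columns)
    else:
        F = fractions.to_numpy(dtype=float)
        samples = list(fractions.index)
    X = S @ F.T
    if noise_sd > 0:
        X = X * np.exp(rng.normal(0.0, noise_sd, size=X.shape))
    expr = ExpressionMatrix(
        values=pd.DataFrame(X, index=signature.index, columns=samples), unit="FPKM"
    )
    return expr, fractions


def simulate_fraction_groups(
    group_sizes: dict[str, int],
    n_types: int = 22,
    boost: float = 4.0,
    concentration: float = 300.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cell-fraction profiles for labeled groups, well separated on the simplex.

    Each group's Dirichlet mean boosts a disjoint block of three cell
    types by ``boost``; ``concentration`` controls within-group spread.
    Returns (fractions, labels); the realized centroid separation (in
    pooled within-group sd units) is stored in ``fractions.attrs``.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(group_sizes)
    rows, labels, ids = [], [], []
    centroids = {}
    offset = 0
    for gi, g in enumerate(groups):
        mean = np.ones(n_types)
        block = np.arange(3 * gi, 3 * gi + 3) % n_types
        mean[block] *= boost
        mean /= mean.sum()
        F = rng.dirichlet(mean * concentration, size=group_sizes[g])
        centroids[g] = F.mean(axis=0)
        rows.append(F)
        labels += [g] * group_sizes[g]
        ids += [f"S{offset + j:04d}" for j in range(group_sizes[g])]
        offset += group_sizes[g]
    F = np.vstack(rows)
    fractions = pd.DataFrame(F, index=ids, columns=[f"CT{i:02d}" for i in range(n_types)])
    label_s = pd.Series(labels, index=ids, name="group")
    within_sd = float(
        np.mean([F[np.array(labels) == g].std(axis=0).mean() for g in groups])
    )
    min_sep = min(
        float(np.linalg.norm(centroids[a] - centroids[b]))
        for i, a in enumerate(groups)
        for b in groups[i + 1 :]
    )
    fractions.attrs["separation_sigma"] = min_sep / max(within_sd, 1e-12)
    return fractions, label_s


def make_labeled_blobs(
    n_samples: int = 150,
    n_features: int = 10,
    n_groups: int = 3,
    separation: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian point clouds with centers ``separation`` sds apart."""
    rng = np.random.default_rng(seed)
    sizes = np.full(n_groups, n_samples // n_groups)
    sizes[: n_samples % n_groups] += 1
    X, y = [], []
    for g in range(n_groups):
        center = np.zeros(n_features)
        center[g % n_features] = separation
        X.append(rng.normal(0.0, 1.0, size=(sizes[g], n_features)) + center)
        y += [g] * sizes[g]
    return np.vstack(X), np.array(y)


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Generator configuration; defaults define the study conditions."""

    group_sizes: dict[str, int] = field(default_factory=lambda: {"A": 100, "B": 100, "C": 100})
    # signature / fractions
    n_signature_genes: int = 220
    n_cell_types: int = 22
    markers_per_type: int = 10
    signature_fold: float = 5.0
    fraction_boost: float = 4.0
    fraction_concentration: float = 300.0
    expression_noise_sd: float = 0.1
    # differential gene sets (monotone across groups)
    n_extra_genes: int = 200
    n_deg_down: int = 40  # C > A > B
    n_deg_up: int = 40  # B > A > C
    deg_lfc: float = 2.0  # per-step log2 effect
    # methylation
    n_probes_per_region: int = 40
    beta_concentration: float = 60.0
    group_b_logit_shift: float = -0.4
    planted_region: str = "TSS1500"
    planted_group: str = "B"
    planted_beta_shift: float = -0.2
    # CNV
    cnv_events_per_sample: float = 12.0
    amp_del_odds: dict[str, float] = field(
        default_factory=lambda: {"A": 1.1, "B": 1.8, "C": 1.0}
    )
    n_cnv_genes: int = 60
    n_chromosomes: int = 5
    # small RNA / ceRNA
    n_mirna: int = 30
    n_lncrna: int = 30
    smallrna_lfc: float = 3.0
    n_decoy_interactions: int = 40
    cerna_contrast: tuple[str, str] = ("B", "C")
    # survival (per-day exponential hazards; B worst, C best)
    hazards: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0 / 1000, "B": 1.5 / 1000, "C": 0.5 / 1000}
    )
    censor_horizon_days: float = 3000.0

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """A no-effect cohort: identical groups in every omics layer."""
        cfg = cls(
            fraction_boost=1.0,
            deg_lfc=0.0,
            group_b_logit_shift=0.0,
            planted_beta_shift=0.0,
            smallrna_lfc=0.0,
            amp_del_odds={"A": 1.0, "B": 1.0, "C": 1.0},
            hazards={"A": 1.0 / 1000, "B": 1.0 / 1000, "C": 1.0 / 1000},
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class OmicsBundle:
    """One synthetic cohort: every omics layer plus the ground truth."""

    expression: ExpressionMatrix
    signature: pd.DataFrame
    true_fractions: pd.DataFrame
    true_groups: pd.Series
    methylation: pd.DataFrame
    probe_annotation: list[ProbeAnnotation]
    segments: list[Segment]
    gene_intervals: list[GeneInterval]
    mirna_expr: ExpressionMatrix
    lncrna_expr: ExpressionMatrix
    interactions: dict[str, InteractionTable]
    survival: pd.DataFrame
    params: dict

    def __post_init__(self) -> None:
        samples = set(self.expression.sample_ids)
        for name, ids in [
            ("fractions", set(self.true_fractions.index)),
            ("groups", set(self.true_groups.index)),
            ("methylation", set(self.methylation.columns)),
            ("mirna", set(self.mirna_expr.sample_ids)),
            ("lncrna", set(self.lncrna_expr.sample_ids)),
            ("survival", set(self.survival["sample"])),
        ]:
            if ids != samples:
                raise ValueError(f"sample ids of layer {name} differ from expression")
        arr = self.methylation.to_numpy(dtype=float)
        if arr.size and ((arr < 0) | (arr > 1)).any():
            raise ValueError("beta values outside [0, 1]")
        if not np.allclose(self.true_fractions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("true fractions must sum to 1 per sample")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> OmicsBundle:
    """Generate a complete three-group multi-omic cohort.

    Deterministic under a fixed seed; every generator parameter is
    recorded in the returned bundle's ``params`` together with the
    planted ground truth (group labels, differential sets, ceRNA
    triplets, CNV odds, hazards).
    """
    cfg = config or CohortConfig()
    if any(n < 2 for n in cfg.group_sizes.values()):
        raise ValueError("every group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    groups = sorted(cfg.group_sizes)

    signature = make_signature(
        cfg.n_signature_genes,
        cfg.n_cell_types,
        cfg.markers_per_type,
        cfg.signature_fold,
        seed=int(rng.integers(2**31 - 1)),
    )
    fractions, labels = simulate_fraction_groups(
        cfg.group_sizes,
        n_types=cfg.n_cell_types,
        boost=cfg.fraction_boost,
        concentration=cfg.fraction_concentration,
        seed=int(rng.integers(2**31 - 1)),
    )
    sig_expr, _ = simulate_mixtures(
        signature,
        n_samples=len(fractions),
        noise_sd=cfg.expression_noise_sd,
        seed=int(rng.integers(2**31 - 1)),
        fractions=fractions,
    )
    samples = list(fractions.index)
    n = len(samples)
    group_arr = labels.to_numpy()

    # extra (non-signature) genes with monotone group effects
    down_genes = [f"DN{i:04d}" for i in range(cfg.n_deg_down)]
    up_genes = [f"UP{i:04d}" for i in range(cfg.n_deg_up)]
    n_null = cfg.n_extra_genes - cfg.n_deg_down - cfg.n_deg_up
    null_genes = [f"EG{i:04d}" for i in range(max(n_null, 0))]
    extra = down_genes + up_genes + null_genes
    base = rng.lognormal(mean=3.0, sigma=0.6, size=len(extra))
    # per-group log2 steps: Down = continuous decrease C -> A -> B
    step = {"down": {"C": 1, "A": 0, "B": -1}, "up": {"C": -1, "A": 0, "B": 1}}
    lfc = np.zeros((len(extra), n))
    for i, g in enumerate(extra):
        kind = "down" if g.startswith("DN") else "up" if g.startswith("UP") else None
        if kind:
            for gi, grp in enumerate(group_arr):
                lfc[i, gi] = cfg.deg_lfc * step[kind].get(grp, 0)
    extra_X = base[:, None] * 2.0**lfc
    extra_X = extra_X * np.exp(rng.normal(0, cfg.expression_noise_sd, size=extra_X.shape))
    expression = ExpressionMatrix(
        values=pd.concat(
            [sig_expr.values, pd.DataFrame(extra_X, index=extra, columns=samples)]
        ),
        unit="FPKM",
    )

    # methylation: Beta(mean * c, (1 - mean) * c) with logit-scale group-B
    # shift everywhere and a direct mean-beta shift in the planted region
    probes, annot, rows = [], [], []
    gene_pool = down_genes + up_genes + null_genes
    for r_i, region in enumerate(REGION_CLASSES):
        for p_i in range(cfg.n_probes_per_region):
            pid = f"cg{r_i}{p_i:04d}"
            probes.append(pid)
            annot.append(
                ProbeAnnotation(
                    probe_id=pid,
                    chromosome=f"chr{1 + p_i % cfg.n_chromosomes}",
                    position=1000 + 10 * p_i,
                    gene_symbol=gene_pool[(r_i * cfg.n_probes_per_region + p_i) % len(gene_pool)],
                    region_class=region,
                    cpg_class="island",
                )
            )
            base_mean = rng.uniform(0.35, 0.7)
            means = np.full(n, base_mean)
            if cfg.group_b_logit_shift:
                mask = group_arr == "B"
                means[mask] = _logistic(
                    np.log(base_mean / (1 - base_mean)) + cfg.group_b_logit_shift
                )
            if region == cfg.planted_region and cfg.planted_beta_shift:
                mask = group_arr == cfg.planted_group
                means[mask] = np.clip(means[mask] + cfg.planted_beta_shift, 0.02, 0.98)
            c = cfg.beta_concentration
            rows.append(rng.beta(means * c, (1 - means) * c))
    methylation = pd.DataFrame(rows, index=probes, columns=samples)

    # CNV: gene catalog + event segments fully containing one gene each
    gene_intervals = []
    for i in range(cfg.n_cnv_genes):
        chrom = f"chr{1 + i % cfg.n_chromosomes}"
        start = 10_000 + (i // cfg.n_chromosomes) * 50_000
        gene_intervals.append(
            GeneInterval(gene_symbol=f"CNVG{i:03d}", chromosome=chrom, start=start, end=start + 20_000)
        )
    segments: list[Segment] = []
    amp_x, del_x = np.log2(3.0) - 1.0, -1.0  # copynum 3 (+1) / copynum 1 (-1)
    for si, sample in enumerate(samples):
        odds = cfg.amp_del_odds.get(group_arr[si], 1.0)
        p_amp = odds / (1.0 + odds)
        n_events = rng.poisson(cfg.cnv_events_per_sample)
        for gi in rng.choice(cfg.n_cnv_genes, size=min(n_events, cfg.n_cnv_genes), replace=False):
            gene = gene_intervals[int(gi)]
            is_amp = rng.random() < p_amp
            x = amp_x if is_amp else del_x
            if rng.random() < 0.15:  # occasional high-level event
                x = 1.0 if is_amp else np.log2(0.4) - 1.0
            segments.append(
                Segment(
                    sample_id=sample,
                    chromosome=gene.chromosome,
                    start=max(gene.start - 1000, 1),
                    end=gene.end + 1000,
                    n_probes=int(rng.integers(10, 200)),
                    segment_mean=round(float(x + rng.normal(0, 0.02)), 4),
                )
            )

    # small RNAs with a planted ceRNA triplet differential in cerna_contrast
    c1, c2 = cfg.cerna_contrast
    mirna_ids = ["miR-CE1-3p"] + [
        f"miR-{i:03d}-{'3p' if i % 2 else '5p'}" for i in range(1, cfg.n_mirna)
    ]
    lncrna_ids = ["LNC-CE1"] + [f"LNC-{i:03d}" for i in range(1, cfg.n_lncrna)]
    cerna_gene = down_genes[0] if down_genes else "DN0000"

    def _small_rna(ids: list[str], planted: str) -> ExpressionMatrix:
        base = rng.lognormal(mean=2.0, sigma=0.5, size=len(ids))
        X = np.tile(base[:, None], (1, n))
        if cfg.smallrna_lfc and planted in ids:
            i = ids.index(planted)
            X[i, group_arr == c1] *= 2.0**cfg.smallrna_lfc
        X = X * np.exp(rng.normal(0, max(cfg.expression_noise_sd, 0.05), size=X.shape))
        return ExpressionMatrix(values=pd.DataFrame(X, index=ids, columns=samples), unit="FPKM")

    mirna_expr = _small_rna(mirna_ids, "miR-CE1-3p")
    lncrna_expr = _small_rna(lncrna_ids, "LNC-CE1")

    def _decoys(left: list[str], right: list[str], k: int) -> set[tuple[str, str]]:
        return {
            (left[int(i)], right[int(j)])
            for i, j in zip(
                rng.integers(1, len(left), size=k), rng.integers(1, len(right), size=k)
            )
        }

    interactions = {
        "lnc_mi": InteractionTable(
            kind="lnc_mi",
            source_db="mircode_like",
            pairs={("LNC-CE1", "miR-CE1-3p")} | _decoys(lncrna_ids, mirna_ids, cfg.n_decoy_interactions),
        )
    }
    for db in ("targetdb1", "targetdb2", "targetdb3"):
        interactions[db] = InteractionTable(
            kind="mi_gene",
            source_db=db,
            pairs={("miR-CE1-3p", cerna_gene)} | _decoys(mirna_ids, gene_pool, cfg.n_decoy_interactions),
        )

    # survival: exponential event times, uniform censoring
    hazard = np.array([cfg.hazards[g] for g in group_arr])
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, cfg.censor_horizon_days, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame(
        {"sample": samples, "time": time, "event": event, "group": group_arr}
    )

    params = {
        "seed": seed,
        "config": _config_dict(cfg),
        "ground_truth": {
            "groups": dict(zip(samples, group_arr)),
            "deg_down": down_genes,
            "deg_up": up_genes,
            "planted_region": cfg.planted_region,
            "planted_group": cfg.planted_group,
            "planted_beta_shift": cfg.planted_beta_shift,
            "amp_del_odds": cfg.amp_del_odds,
            "hazards": cfg.hazards,
            "cerna_triplets": [["LNC-CE1", "miR-CE1-3p", cerna_gene]],
            "cerna_contrast": list(cfg.cerna_contrast),
        },
    }
    return OmicsBundle(
        expression=expression,
        signature=signature,
        true_fractions=fractions,
        true_groups=labels,
        methylation=methylation,
        probe_annotation=annot,
        segments=segments,
        gene_intervals=gene_intervals,
        mirna_expr=mirna_expr,
        lncrna_expr=lncrna_expr,
        interactions=interactions,
        survival=survival,
        params=params,
    )


def make_toy_pathways(
    bundle: OmicsBundle, n_pathways: int = 6, size: int = 10, seed: int = 0
) -> tuple[dict[str, set[str]], dict[str, list[tuple[str, str, int]]]]:
    """Small pathway collection over the cohort's genes, with chain topology.

    The first pathway is loaded with planted down-regulated genes and the
    second with up-regulated ones, so impact scores have signal to find;
    the rest draw from unaffected genes. Each pathway gets a signed
    chain g1 -> g2 -> ... (alternating activation/inhibition).
    """
    rng = np.random.default_rng(seed)
    truth = bundle.params["ground_truth"]
    down, up = truth["deg_down"], truth["deg_up"]
    null = [
        g
        for g in bundle.expression.gene_ids
        if g.startswith("EG") or g.startswith("SG")
    ]
    sets: dict[str, set[str]] = {}
    edges: dict[str, list[tuple[str, str, int]]] = {}
    for i in range(n_pathways):
        if i == 0 and len(down) >= size // 2:
            members = list(rng.choice(down, size // 2, replace=False)) + list(
                rng.choice(null, size - size // 2, replace=False)
            )
        elif i == 1 and len(up) >= size // 2:
            members = list(rng.choice(up, size // 2, replace=False)) + list(
                rng.choice(null, size - size // 2, replace=False)
            )
        else:
            members = list(rng.choice(null, size, replace=False))
        name = f"PW{i:02d}"
        sets[name] = set(members)
        edges[name] = [
            (members[j], members[j + 1], 1 if j % 2 == 0 else -1)
            for j in range(len(members) - 1)
        ]
    return sets, edges


def _config_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["cerna_contrast"] = list(d["cerna_contrast"])
    return d


def write_bundle(bundle: OmicsBundle, directory) -> None:
    """Write every layer of a cohort as standard-format files + truth JSON."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expression, out / "expression.tsv")
    bundle.signature.to_csv(out / "signature.tsv", sep="\t", lineterminator="\n")
    bundle.true_fractions.to_csv(out / "true_fractions.tsv", sep="\t", lineterminator="\n")
    write_methylation(bundle.methylation, out / "methylation.tsv")
    write_probe_annotation(bundle.probe_annotation, out / "probe_annotation.tsv")
    write_segments(bundle.segments, out / "segments.seg")
    pd.DataFrame(
        [(g.gene_symbol, g.chromosome, g.start, g.end) for g in bundle.gene_intervals],
        columns=["gene", "chromosome", "start", "end"],
    ).to_csv(out / "gene_intervals.tsv", sep="\t", index=False, lineterminator="\n")
    write_expression(bundle.mirna_expr, out / "mirna_expression.tsv")
    write_expression(bundle.lncrna_expr, out / "lncrna_expression.tsv")
    for name, table in bundle.interactions.items():
        write_interactions(table, out / f"interactions_{name}.tsv")
    write_survival(bundle.survival, out / "survival.tsv")
    bundle.true_groups.rename("group").to_csv(out / "true_groups.tsv", sep="\t", lineterminator="\n")
    sets, edges = make_toy_pathways(bundle, seed=bundle.params["seed"])
    write_gmt(sets, out / "pathways.gmt")
    write_edges(edges, out / "pathway_edges.tsv")
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.params, fh, indent=2, sort_keys=True)
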