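"""CNV discretization/annotation/group tests and methylation region analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmescape.epigenome import (
    GeneInterval,
    annotate_segments,
    cnv_group_test,
    correlate,
    discretize_cnv,
    region_enrichment,
    region_summary,
)
from tmescape.io import ProbeAnnotation, Segment, REGION_CLASSES


class TestDiscretize:
    @pytest.mark.parametrize(
        "x,copynum,category",
        [
            (0.0, 2.0, 0),      # diploid
            (1.0, 4.0, 2),      # high-level amplification
            (-2.0, 0.5, -1),    # boundary: 0.5 is a single-copy loss
            (np.log2(3.0) - 1, 3.0, 1),
            (-1.0, 1.0, -1),
            (-3.0, 0.25, -2),
            (np.log2(3.5) - 1, 3.5, 1),   # upper-inclusive bin edge
            (np.log2(2.5) - 1, 2.5, 0),
            (np.log2(1.5) - 1, 1.5, -1),
        ],
    )
    def test_bins(self, x, copynum, category):
        c, cat = discretize_cnv(x)
        assert c == pytest.approx(copynum, rel=1e-12)
        assert cat == category

    def test_monotone_nondecreasing(self):
        xs = np.linspace(-4, 2, 400)
        cats = [discretize_cnv(x)[1] for x in xs]
        assert all(b >= a for a, b in zip(cats, cats[1:]))


class TestAnnotate:
    def test_full_containment_assigns(self):
        segs = [Segment("s1", "chr1", 100, 500, 10, 1.0)]
        genes = [GeneInterval("G1", "chr1", 200, 300)]
        out = annotate_segments(segs, genes).set_index(["gene", "sample"])
        assert out.loc[("G1", "s1"), "category"] == 2

    def test_partial_overlap_not_assigned(self):
        segs = [Segment("s1", "chr1", 100, 500, 10, 1.0)]
        genes = [GeneInterval("G1", "chr1", 400, 600)]
        out = annotate_segments(segs, genes).set_index(["gene", "sample"])
        assert out.loc[("G1", "s1"), "category"] == 0  # neutral default

    def test_chromosome_mismatch_rejected(self):
        segs = [Segment("s1", "1", 100, 500, 10, 0.0)]
        genes = [GeneInterval("G1", "chr1", 200, 300)]
        with pytest.raises(ValueError, match="chromosome"):
            annotate_segments(segs, genes)

    def test_most_extreme_segment_wins(self):
        segs = [
            Segment("s1", "chr1", 100, 500, 10, np.log2(3.0) - 1),  # +1
            Segment("s1", "chr1", 150, 400, 10, 1.0),               # +2 (more extreme)
        ]
        genes = [GeneInterval("G1", "chr1", 200, 300)]
        out = annotate_segments(segs, genes).set_index(["gene", "sample"])
        assert out.loc[("G1", "s1"), "category"] == 2

    def test_matches_brute_force_interval_oracle(self, rng):
        segs, genes = [], []
        for i in range(50):
            a = int(rng.integers(1, 5000))
            segs.append(
                Segment(f"s{i % 4}", f"chr{i % 3}", a, a + int(rng.integers(10, 2000)),
                        5, float(rng.normal()))
            )
            b = int(rng.integers(1, 5000))
            genes.append(GeneInterval(f"G{i}", f"chr{i % 3}", b, b + int(rng.integers(10, 800))))
        out = annotate_segments(segs, genes).set_index(["gene", "sample"])
        samples = sorted({s.sample_id for s in segs})
        for g in genes:
            for sm in samples:
                containing = [
                    s for s in segs
                    if s.sample_id == sm and s.chromosome == g.chromosome
                    and s.start <= g.start and g.end <= s.end
                ]
                if not containing:
                    expected = 0
                else:
                    best = max(
                        containing,
                        key=lambda s: (abs(discretize_cnv(s.segment_mean)[0] - 2),
                                       discretize_cnv(s.segment_mean)[0]),
                    )
                    expected = discretize_cnv(best.segment_mean)[1]
                assert out.loc[(g.gene_symbol, sm), "category"] == expected


class TestGroupTest:
    def test_identical_distributions_null(self):
        rows = [("G1", s, 2.0, c) for s in ("s1", "s2") for c in (-1, 0, 1)]
        df = pd.DataFrame(rows, columns=["gene", "sample", "copynum", "category"])
        labels = pd.Series({"s1": "A", "s2": "B"})
        tests, _ = cnv_group_test(df, labels)
        assert tests["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tests["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_amp_del_odds_recovered(self, rng):
        """2000 binomial events at amp:del odds 1.8 recover a ratio in [1.6, 2.0]."""
        n = 2000
        amp = rng.random(n) < 1.8 / 2.8
        rows = [("G1", f"s{i}", 3.0 if a else 1.0, 1 if a else -1) for i, a in enumerate(amp)]
        df = pd.DataFrame(rows, columns=["gene", "sample", "copynum", "category"])
        labels = pd.Series({f"s{i}": "B" for i in range(n)})
        _, ratios = cnv_group_test(df, labels)
        assert 1.6 <= ratios.loc["B", "amp_del_ratio"] <= 2.0

    def test_2x2_collapse_matches_hand_chi_square(self):
        # table [[30, 10], [20, 20]]: chi2 = n(ad-bc)^2 / (r1 r2 c1 c2) = 5.3333
        rows = (
            [("G", f"a{i}", 3.0, 1) for i in range(30)]
            + [("G", f"a{i+30}", 1.0, -1) for i in range(10)]
            + [("G", f"b{i}", 3.0, 1) for i in range(20)]
            + [("G", f"b{i+20}", 1.0, -1) for i in range(20)]
        )
        df = pd.DataFrame(rows, columns=["gene", "sample", "copynum", "category"])
        labels = pd.Series(
            {f"a{i}": "A" for i in range(40)} | {f"b{i}": "B" for i in range(40)}
        )
        tests, _ = cnv_group_test(df, labels)
        # scipy applies Yates correction on 2x2; compare against scipy directly
        expected, p, _, _ = stats.chi2_contingency([[30, 10], [20, 20]])
        assert tests.loc["A_vs_B", "chi2"] == pytest.approx(expected, abs=1e-10)
        hand_uncorrected = 80 * (30 * 20 - 10 * 20) ** 2 / (40 * 40 * 50 * 30)
        assert hand_uncorrected == pytest.approx(16 / 3, abs=1e-12)


def _annotation(n_per_region=10):
    annot = []
    for r_i, region in enumerate(REGION_CLASSES):
        for i in range(n_per_region):
            annot.append(
                ProbeAnnotation(f"cg{r_i}_{i}", "chr1", 100 + i, f"G{i}", region)
            )
    return annot


class TestRegionSummary:
    def test_constant_betas(self):
        annot = _annotation(5)
        probes = [a.probe_id for a in annot]
        betas = pd.DataFrame(0.5, index=probes, columns=["s1", "s2", "s3", "s4"])
        labels = pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        out = region_summary(betas, annot, labels)
        means = out[out["kind"] == "mean"]
        np.testing.assert_allclose(means["mean_beta"], 0.5, atol=1e-12)
        tests = out[out["kind"] == "test"]
        np.testing.assert_allclose(tests["t"], 0.0, atol=1e-12)

    def test_planted_shift_detected_only_in_target_region(self, rng):
        annot = _annotation(20)
        probes = [a.probe_id for a in annot]
        samples = [f"s{i}" for i in range(40)]
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=samples)
        betas = pd.DataFrame(
            rng.beta(10, 10, size=(len(probes), 40)), index=probes, columns=samples
        )
        tss = [a.probe_id for a in annot if a.region_class == "TSS1500"]
        betas.loc[tss, labels == "B"] = np.clip(
            betas.loc[tss, labels == "B"] - 0.2, 0.01, 0.99
        )
        out = region_summary(betas, annot, labels)
        tests = out[out["kind"] == "test"].set_index("region_class")
        assert tests.loc["TSS1500", "p"] < 1e-6
        assert tests.loc["1stExon", "p"] > 0.01

    def test_means_match_direct_recomputation(self, rng):
        annot = _annotation(4)
        probes = [a.probe_id for a in annot]
        samples = [f"s{i}" for i in range(6)]
        betas = pd.DataFrame(
            rng.uniform(0, 1, size=(len(probes), 6)), index=probes, columns=samples
        )
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
        out = region_summary(betas, annot, labels)
        row = out[(out["region_class"] == "Body") & (out["group"] == "A")].iloc[0]
        body = [a.probe_id for a in annot if a.region_class == "Body"]
        assert row["mean_beta"] == pytest.approx(
            betas.loc[body, ["s0", "s1", "s2"]].to_numpy().mean(), abs=1e-12
        )


def fisher_enumeration(table):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    n, K, N = a + b + c + d, a + c, a + b
    support = range(max(0, N + K - n), min(N, K) + 1)
    probs = {k: stats.hypergeom.pmf(k, n, K, N) for k in support}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs + 1e-12)


class TestRegionEnrichment:
    def test_odds_ratio_and_fisher_match_enumeration(self):
        # region TSS200 holds 4 probes: 3 hyper 1 not; elsewhere 1 hyper 3 not
        annot = [
            ProbeAnnotation(f"cg{i}", "chr1", i, "G", "TSS200") for i in range(4)
        ] + [ProbeAnnotation(f"cg{4+i}", "chr1", i, "G", "Body") for i in range(4)]
        classes = pd.Series(
            ["hyper", "hyper", "hyper", "ns", "hyper", "ns", "ns", "ns"],
            index=[f"cg{i}" for i in range(8)],
        )
        out = region_enrichment(classes, annot).set_index(["region_class", "class"])
        row = out.loc[("TSS200", "hyper")]
        assert row["odds_ratio"] == pytest.approx(9.0, abs=1e-12)
        assert row["method"] == "fisher"
        assert row["p"] == pytest.approx(fisher_enumeration([[3, 1], [1, 3]]), abs=1e-10)

    def test_empty_class_reported_na(self):
        annot = _annotation(3)
        classes = pd.Series("ns", index=[a.probe_id for a in annot])
        out = region_enrichment(classes, annot)
        assert out["odds_ratio"].isna().all()
        np.testing.assert_allclose(out["p"], 1.0)

    def test_null_assignment_calibrated(self):
        """Random class placement: few (region, class) pairs reach p < 0.05."""
        hits = total = 0
        annot = _annotation(30)
        probes = [a.probe_id for a in annot]
        for seed in range(20):
            r = np.random.default_rng(seed)
            classes = pd.Series(
                r.choice(["hyper", "hypo", "ns"], p=[0.1, 0.1, 0.8], size=len(probes)),
                index=probes,
            )
            out = region_enrichment(classes, annot)
            hits += int((out["p"] < 0.05).sum())
            total += len(out)
        assert hits / total <= 0.07


class TestCorrelate:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_independent_vectors_near_zero(self, rng):
        r, _ = correlate(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        r, _ = correlate(x, y)
        assert r == pytest.approx(num / den, abs=1e-12)
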