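"""Moderated t-test, threshold calls, Venn intersection, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmescape.differential import (
    call_degs,
    classify_methylation,
    intersect_sets,
    kruskal_by_column,
    moderated_ttest,
    pairwise_contrasts,
)


def _toy_matrix(rng, n_features=100, n1=8, n2=8, shift=0.0):
    X = rng.normal(5.0, 1.0, size=(n_features, n1 + n2))
    X[:, :n1] += shift
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    labels = pd.Series(["G1"] * n1 + ["G2"] * n2, index=cols)
    return pd.DataFrame(X, index=[f"f{i}" for i in range(n_features)], columns=cols), labels


class TestModeratedTTest:
    def test_identical_group_means_all_ns(self):
        base = np.tile(np.arange(1.0, 6.0)[:, None], (1, 6))
        m = pd.DataFrame(base, index=list("vwxyz"), columns=[f"s{i}" for i in range(6)])
        m += np.array([0.1, -0.1, 0.2, 0.1, -0.1, 0.2])  # same pattern per group
        labels = pd.Series(["G1"] * 3 + ["G2"] * 3, index=m.columns)
        t = moderated_ttest(m, labels, ("G1", "G2"))
        np.testing.assert_allclose(t["log2_fold_change"], 0.0, atol=1e-12)
        assert (t["direction"] == "ns").all()

    def test_zero_prior_df_recovers_classic_pooled_t(self, rng):
        """d0 = 0 must reproduce the textbook pooled two-sample t exactly."""
        m, labels = _toy_matrix(rng, n_features=60, shift=0.4)
        ours = moderated_ttest(m, labels, ("G1", "G2"), d0_override=0.0)
        ref_t, ref_p = stats.ttest_ind(
            m.loc[:, labels == "G1"], m.loc[:, labels == "G2"], axis=1, equal_var=True
        )
        np.testing.assert_allclose(ours["t"], ref_t, atol=1e-8)
        np.testing.assert_allclose(ours["raw_p"], ref_p, atol=1e-8)

    def test_fold_change_consistent_with_log2(self, rng):
        m, labels = _toy_matrix(rng, n_features=30, shift=0.8)
        t = moderated_ttest(m, labels, ("G1", "G2"))
        np.testing.assert_allclose(t["fold_change"], 2.0 ** t["log2_fold_change"], rtol=1e-12)
        assert (t["adjusted_p"] >= t["raw_p"] - 1e-15).all()

    def test_moderation_shrinks_extreme_variances(self, rng):
        m, labels = _toy_matrix(rng, n_features=200)
        t = moderated_ttest(m, labels, ("G1", "G2"))
        assert t.attrs["d0"] > 0

    def test_effect_monotonicity(self, rng):
        """A larger injected shift never shrinks |moderated t| (fixed noise)."""
        noise = rng.normal(0, 1, size=(50, 12))
        cols = [f"s{i}" for i in range(12)]
        labels = pd.Series(["G1"] * 6 + ["G2"] * 6, index=cols)
        t_abs = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            X = noise.copy()
            X[0, :6] += shift
            m = pd.DataFrame(X, index=[f"f{i}" for i in range(50)], columns=cols)
            tab = moderated_ttest(m, labels, ("G1", "G2"))
            t_abs.append(abs(tab.loc["f0", "t"]))
        assert all(b >= a for a, b in zip(t_abs, t_abs[1:]))

    def test_type_i_error_calibrated_on_null(self):
        """Raw p < 0.05 fraction on pure-noise data stays near 5%."""
        rates = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            m, labels = _toy_matrix(r, n_features=300)
            t = moderated_ttest(m, labels, ("G1", "G2"))
            rates.append((t["raw_p"] < 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07

    def test_too_few_samples_rejected(self, rng):
        m, _ = _toy_matrix(rng, n1=1, n2=3)
        labels = pd.Series(["G1"] + ["G2"] * 3, index=m.columns)
        with pytest.raises(ValueError, match=">= 2"):
            moderated_ttest(m, labels, ("G1", "G2"))


class TestAgainstReferenceImplementation:
    def test_moderated_t_matches_limma(self, rng, tmp_path):
        """Cross-check the empirical-Bayes moderated t against limma in R."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        # draw true variances from a scaled inverse-chi-square so the
        # prior df is finite and the generic moment-matching path runs
        sd = np.sqrt(4.0 / rng.chisquare(4.0, size=80))
        m, labels = _toy_matrix(rng, n_features=80)
        m = m.sub(m.mean(axis=1), axis=0).mul(sd, axis=0)
        m.iloc[:, :8] += 0.3
        m.to_csv(tmp_path / "m.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names = 1))
            design <- cbind(G1 = rep(c(1, 0), each = 8), G2 = rep(c(0, 1), each = 8))
            fit <- eBayes(contrasts.fit(lmFit(x, design),
                                        makeContrasts(G1 - G2, levels = design)))
            write.table(data.frame(t = fit$t[, 1], p = fit$p.value[, 1]),
                        commandArgs(TRUE)[2], sep = "\t", quote = FALSE)
            """,
            encoding="utf-8",
        )
        res = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "m.tsv"), str(tmp_path / "out.tsv")],
            capture_output=True, text=True, timeout=120,
        )
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        ours = moderated_ttest(m, labels, ("G1", "G2"))
        assert np.isfinite(ours.attrs["d0"])
        np.testing.assert_allclose(ours["t"], ref["t"], rtol=1e-9)
        np.testing.assert_allclose(ours["raw_p"], ref["p"], rtol=1e-9)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        """BH on (0.01, 0.02, 0.03, 0.04) adjusts every p to 0.04.

        Step-up by hand: p_(i) * m / i = .04, .04, .04, .04; the
        cumulative minimum from the largest rank leaves all at 0.04.
        """
        from tmescape.differential import bh_adjust

        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_hand_computed_mixed_list(self):
        # ranks: .002*3/1=.006, .02*3/2=.03, .9*3/3=.9
        from tmescape.differential import bh_adjust

        np.testing.assert_allclose(bh_adjust([0.9, 0.002, 0.02]), [0.9, 0.006, 0.03], atol=1e-12)


class TestThresholdCalls:
    def _table(self, rows):
        df = pd.DataFrame(
            rows, columns=["feature_id", "log2_fold_change", "fold_change", "raw_p", "adjusted_p"]
        ).set_index("feature_id")
        return df

    def test_dual_threshold_up_set(self):
        t = self._table([("f1", 1.0, 2.0, 0.005, 0.04)])
        assert call_degs(t)["up"] == {"f1"}

    def test_raw_p_failure_excludes(self):
        t = self._table([("f1", 1.0, 2.0, 0.02, 0.04)])
        assert call_degs(t)["all"] == set()

    def test_methylation_classes(self):
        t = self._table(
            [
                ("hyper1", np.log2(1.30), 1.30, 0.001, 0.005),
                ("border", np.log2(1.25), 1.25, 0.001, 0.005),
                ("failfdr", np.log2(0.79), 0.79, 0.001, 0.02),
                ("hypo1", np.log2(0.75), 0.75, 0.001, 0.005),
            ]
        )
        out = classify_methylation(t)
        assert out.loc["hyper1", "class"] == "hyper"
        assert out.loc["border", "class"] == "ns"  # strict inequality
        assert out.loc["failfdr", "class"] == "ns"  # FDR conjunct fails
        assert out.loc["hypo1", "class"] == "hypo"


class TestIntersectSets:
    def test_center_count(self):
        counts = intersect_sets({"A": {1, 2}, "B": {2, 3}, "C": {2}})
        assert counts[frozenset({"A", "B", "C"})] == 1

    def test_disjoint_sets_have_no_overlap_regions(self):
        counts = intersect_sets({"A": {1}, "B": {2}, "C": {3}})
        assert all(len(k) == 1 for k in counts)

    def test_matches_exhaustive_tally_and_preserves_total(self, rng):
        sets = {
            name: set(rng.integers(0, 300, size=100).tolist()) for name in "ABC"
        }
        counts = intersect_sets(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        for pattern, c in counts.items():
            brute = sum(
                1
                for e in union
                if {n for n in sets if e in sets[n]} == set(pattern)
            )
            assert brute == c


def test_kruskal_flags_shifted_column(rng):
    X = rng.normal(size=(30, 3))
    X[:10, 0] += 3.0
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(30)], columns=["c1", "c2", "c3"])
    labels = pd.Series(["A"] * 10 + ["B"] * 10 + ["C"] * 10, index=df.index)
    res = kruskal_by_column(df, labels)
    assert res.loc["c1", "p"] < 0.01
    assert res.loc["c2", "p"] > 0.01


def test_pairwise_contrasts_alphabetical():
    assert pairwise_contrasts(["C", "A", "B", "A"]) == [("A", "B"), ("A", "C"), ("B", "C")]
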