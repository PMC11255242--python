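import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rloopscan import expr_assoc, simgen

from _oracles import enumerate_mwu, reference_bh


class TestNormalizeCounts:
    def test_hand_computed_factors(self):
        counts = pd.DataFrame({"s1": [10, 10], "s2": [20, 20]}, index=["g1", "g2"])
        factors, normalized = expr_assoc.normalize_counts(counts)
        assert factors["s2"] / factors["s1"] == pytest.approx(2.0)
        np.testing.assert_allclose(normalized["s1"], normalized["s2"])

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 30], "b": [5, 9, 30]})
        factors, _ = expr_assoc.normalize_counts(counts)
        np.testing.assert_allclose(factors, [1.0, 1.0])

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 3)), columns=list("abc"))
        f1, _ = expr_assoc.normalize_counts(counts)
        scaled = counts.copy()
        scaled["b"] *= 3
        f2, _ = expr_assoc.normalize_counts(scaled)
        # factors are defined up to a common scale; the ratio to another
        # sample carries the homogeneity
        assert (f2["b"] / f2["a"]) / (f1["b"] / f1["a"]) == pytest.approx(
            3.0, rel=1e-9
        )

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            expr_assoc.normalize_counts(pd.DataFrame({"a": [0], "b": [0]}))

    def test_zero_genes_excluded_from_estimation(self):
        counts = pd.DataFrame({"a": [10, 0, 10], "b": [20, 100, 20]})
        factors, _ = expr_assoc.normalize_counts(counts)
        # the zero-containing gene must not influence the ratio
        assert factors["b"] / factors["a"] == pytest.approx(2.0)


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            expr_assoc.bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(expr_assoc.bh_adjust([0.2]), [0.2])

    def test_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = expr_assoc.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(
                expr_assoc.bh_adjust(p), reference_bh(list(p)), atol=1e-12
            )

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            expr_assoc.bh_adjust([0.5, 1.2])


class TestMannWhitneyU:
    def test_disjoint_example(self):
        u, p = expr_assoc.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = expr_assoc.mann_whitney_u(x, x)
        assert p == 1.0

    def test_u_conservation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(size=rng.integers(3, 30))
            ux, _ = expr_assoc.mann_whitney_u(x, y)
            uy, _ = expr_assoc.mann_whitney_u(y, x)
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_equals_enumeration_small_sweep(self):
        rng = np.random.default_rng(3)
        for n in range(1, 6):
            for m in range(1, 6):
                x = rng.normal(size=n)
                y = rng.normal(size=m)
                u, p = expr_assoc.mann_whitney_u(x, y)
                u_ref, p_ref = enumerate_mwu(x, y)
                assert u == pytest.approx(u_ref)
                assert p == pytest.approx(p_ref)

    def test_large_sample_matches_scipy_approx(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 1, 60)
        y = rng.normal(0.0, 1, 80)
        u, p = expr_assoc.mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            expr_assoc.mann_whitney_u([], [1.0])

    def test_null_counts_sum(self):
        counts = expr_assoc.u_null_counts(4, 5)
        from math import comb

        assert sum(counts) == comb(9, 4)
        assert len(counts) == 21


class TestDETest:
    def _null_counts(self, seed, n_genes=2000, phi=0.1):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(5.3, 1.0, n_genes)
        return pd.DataFrame(
            {
                f"s{i}": rng.poisson(rng.gamma(1 / phi, mu * phi))
                for i in range(4)
            },
            index=[f"g{j}" for j in range(n_genes)],
        )

    def test_identical_condition_means_zero_lfc(self):
        counts = pd.DataFrame(
            {"c1": [100, 50], "c2": [100, 50], "k1": [100, 50], "k2": [100, 50]},
            index=["g1", "g2"],
        )
        de = expr_assoc.de_test(counts, ["control", "control", "kd", "kd"])
        np.testing.assert_allclose(de.table.log2fc, 0.0)

    def test_null_fdr_controlled(self):
        counts = self._null_counts(0)
        de = expr_assoc.de_test(counts, ["control", "control", "kd", "kd"])
        assert (de.table.q_value <= 0.05).mean() <= 0.01

    def test_estimator_consistency(self):
        rng = np.random.default_rng(1)
        n = 2000
        affected = 200  # embedded among null genes so normalization anchors
        mu = np.full(n, 200.0)
        kd_mu = mu.copy()
        kd_mu[:affected] /= 2
        phi = 0.1
        data = {}
        for i, cond_mu in enumerate([mu, mu, kd_mu, kd_mu]):
            data[f"s{i}"] = rng.poisson(rng.gamma(1 / phi, cond_mu * phi))
        counts = pd.DataFrame(data, index=[f"g{j}" for j in range(n)])
        de = expr_assoc.de_test(counts, ["control", "control", "kd", "kd"])
        assert abs(np.median(de.table.log2fc.iloc[:affected]) - (-1.0)) < 0.2
        assert abs(np.median(de.table.log2fc.iloc[affected:])) < 0.1

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(
            {"c1": [100, 0], "c2": [90, 0], "k1": [110, 0], "k2": [95, 0]},
            index=["g1", "gz"],
        )
        de = expr_assoc.de_test(counts, ["control", "control", "kd", "kd"])
        assert de.excluded == ["gz"]
        assert list(de.table.gene_id) == ["g1"]

    def test_replicate_requirement(self):
        counts = pd.DataFrame({"c1": [1], "k1": [2]})
        with pytest.raises(ValueError):
            expr_assoc.de_test(counts, ["control", "kd"])


class TestClassifyGenes:
    def _table(self, lfc, q):
        return pd.DataFrame({"log2fc": lfc, "q_value": q})

    def test_down(self):
        cls = expr_assoc.classify_genes(self._table([-2.0], [0.01]), 1.0, 0.05)
        assert list(cls) == ["down"]

    def test_nochange(self):
        cls = expr_assoc.classify_genes(self._table([0.2], [0.5]), 1.0, 0.05)
        assert list(cls) == ["nochange"]

    def test_partition(self):
        rng = np.random.default_rng(0)
        table = self._table(rng.normal(0, 2, 100), rng.random(100))
        cls = expr_assoc.classify_genes(table)
        assert cls.isin(["down", "up", "nochange"]).all()
        assert len(cls) == 100


class TestAssociationReport:
    def _constructed(self, rng):
        n = 90
        classes = pd.Series(
            ["down"] * 15 + ["up"] * 15 + ["nochange"] * 60,
            index=[f"g{i}" for i in range(n)],
        )
        lengths = pd.Series(
            np.concatenate(
                [
                    rng.lognormal(11.0, 0.3, 15),  # down genes long
                    rng.lognormal(9.0, 0.3, 15),
                    rng.lognormal(9.0, 0.3, 60),
                ]
            ),
            index=classes.index,
        )
        motifs = pd.Series(rng.integers(0, 3, n), index=classes.index)
        return classes, lengths, motifs

    def test_down_length_signal(self):
        rng = np.random.default_rng(0)
        classes, lengths, motifs = self._constructed(rng)
        report = expr_assoc.association_report(classes, lengths, motifs)
        tests = report.tests.set_index(["comparison", "covariate"])
        assert tests.loc[("down_vs_nochange", "gene_length"), "p_value"] < 0.05
        assert tests.loc[("up_vs_nochange", "gene_length"), "p_value"] > 0.05

    def test_class_sizes_sum(self):
        rng = np.random.default_rng(1)
        classes, lengths, motifs = self._constructed(rng)
        report = expr_assoc.association_report(classes, lengths, motifs)
        assert report.summary.n.sum() == len(classes)

    def test_small_class_skipped(self):
        classes = pd.Series(["down", "nochange", "nochange", "nochange"],
                            index=list("abcd"))
        lengths = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        motifs = pd.Series([1, 0, 0, 0], index=list("abcd"))
        report = expr_assoc.association_report(classes, lengths, motifs)
        down_rows = report.tests[report.tests.comparison == "down_vs_nochange"]
        assert down_rows.skipped.all()

    def test_permuted_labels_uniform_p(self):
        rng = np.random.default_rng(2)
        n = 60
        lengths = pd.Series(
            rng.lognormal(10, 0.5, n), index=[f"g{i}" for i in range(n)]
        )
        motifs = pd.Series(rng.integers(0, 4, n), index=lengths.index)
        pvals = []
        for _ in range(200):
            labels = np.array(["down"] * 12 + ["nochange"] * 48)
            rng.shuffle(labels)
            classes = pd.Series(labels, index=lengths.index)
            report = expr_assoc.association_report(classes, lengths, motifs)
            tests = report.tests.set_index(["comparison", "covariate"])
            pvals.append(tests.loc[("down_vs_nochange", "gene_length"), "p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestCrossSpecies:
    def _report(self, n_down, n_up, p_len=0.01):
        summary = pd.DataFrame(
            {
                "class": ["down", "up", "nochange"],
                "n": [n_down, n_up, 100],
            }
        )
        tests = pd.DataFrame(
            {
                "comparison": ["down_vs_nochange", "down_vs_nochange"],
                "covariate": ["gene_length", "motif_count"],
                "U": [1.0, 1.0],
                "p_value": [p_len, 0.5],
                "skipped": [False, False],
            }
        )
        return expr_assoc.AssociationReport(summary=summary, tests=tests)

    def _lengths(self, scale, n=50):
        rng = np.random.default_rng(0)
        return pd.Series(
            rng.lognormal(scale, 0.3, n), index=[f"g{i}" for i in range(n)]
        )

    def test_ratio_and_medians(self):
        la, lb = self._lengths(11.0), self._lengths(9.0)
        orth = pd.DataFrame({"gene_a": la.index, "gene_b": lb.index})
        out = expr_assoc.cross_species_compare(
            self._report(20, 10), self._report(5, 5), la, lb, orth
        )
        assert out["affected_ratio_a_over_b"] == 3.0
        assert out["median_length_a"] > out["median_length_b"]

    def test_identical_reports_ratio_one(self):
        la = self._lengths(10.0)
        orth = pd.DataFrame({"gene_a": la.index, "gene_b": la.index})
        out = expr_assoc.cross_species_compare(
            self._report(8, 4), self._report(8, 4), la, la, orth
        )
        assert out["affected_ratio_a_over_b"] == 1.0

    def test_empty_map_error(self):
        la = self._lengths(10.0)
        with pytest.raises(ValueError):
            expr_assoc.cross_species_compare(
                self._report(1, 1), self._report(1, 1), la, la, pd.DataFrame()
            )
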