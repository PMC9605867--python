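import numpy as np
import pandas as pd
import pytest

from satmap import enrichment
from satmap.enrichment import ContingencyTable2x2, LengthClassScheme
from satmap.loci import signal_density
from satmap.simulate import gen_annotation_pool
from satmap.sumstats import SatmapError

from conftest import make_signals


def gene_table(rows):
    df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "is_candidate"])
    return df


class TestProximityFraction:
    def test_query_equals_reference(self):
        q = make_signals([(1, 100), (2, 200)])
        frac, hit = enrichment.proximity_fraction(q, q, window_bp=100_000)
        assert frac == 1.0 and hit.all()

    def test_hand_derived_half(self):
        q = make_signals([(1, 500_000), (2, 200_000)])
        r = make_signals([(1, 450_000)])
        frac, hit = enrichment.proximity_fraction(q, r, window_bp=100_000)
        assert frac == 0.5 and list(hit) == [True, False]

    def test_window_zero_is_exact_overlap(self):
        q = make_signals([(1, 100), (1, 200), (1, 300)])
        r = make_signals([(1, 200), (1, 400)])
        frac, _ = enrichment.proximity_fraction(q, r, window_bp=0)
        assert frac == pytest.approx(1 / 3)


class TestLengthClassScheme:
    def test_default_has_22_classes(self):
        assert LengthClassScheme().n_classes == 22

    def test_every_length_maps_to_exactly_one_class(self):
        scheme = LengthClassScheme()
        lengths = [1, 9_999, 10_000, 99_999, 100_000, 999_999, 1_000_000,
                   1_499_999, 1_500_000, 2_000_000, 50_000_000]
        classes = scheme.classify(lengths)
        assert classes.min() >= 0 and classes.max() == 21
        # boundaries: 10 kb starts class 1, 100 kb starts class 10, 2 Mb is last
        assert list(classes[:4]) == [0, 0, 1, 9]
        assert classes[4] == 10 and classes[6] == 19 and classes[10] == 21


class TestGeneProximityTable:
    def test_no_gene_near_any_signal(self):
        sig = make_signals([(1, 1_000_000), (1, 2_000_000)])
        genes = gene_table([("G", 2, 100, 200, True)])
        t = enrichment.gene_proximity_table(sig, np.array([1, 1]), genes)
        assert t.a == 0 and t.c == 0 and t.b == 2

    def test_edge_distance_rule(self):
        # signal at 200 kb, gene [290 kb, 350 kb]: edge distance 90 kb -> proximal
        sig = make_signals([(1, 200_000)])
        genes = gene_table([("G", 1, 290_000, 350_000, True)])
        t = enrichment.gene_proximity_table(sig, np.array([1]), genes, window_bp=100_000)
        assert t.a == 1
        far = gene_table([("G", 1, 300_001, 350_000, True)])
        t2 = enrichment.gene_proximity_table(sig, np.array([1]), far, window_bp=100_000)
        assert t2.a == 0

    def test_signal_inside_gene_is_proximal(self):
        sig = make_signals([(1, 320_000)])
        genes = gene_table([("G", 1, 290_000, 350_000, True)])
        t = enrichment.gene_proximity_table(sig, np.array([0]), genes)
        assert t.c == 1

    def test_hand_derived_6_4_2_8(self):
        rows = []
        densities = []
        # 10 high-density signals, 6 gene-proximal; 10 zero-density, 2 proximal
        for i in range(10):
            rows.append((1, 1_000_000 * (i + 1)))
            densities.append(5)
        for i in range(10):
            rows.append((2, 1_000_000 * (i + 1)))
            densities.append(0)
        sig = make_signals(rows)
        genes = gene_table(
            [(f"G{i}", 1, 1_000_000 * (i + 1) - 10, 1_000_000 * (i + 1) + 10, True) for i in range(6)]
            + [(f"H{i}", 2, 1_000_000 * (i + 1) - 10, 1_000_000 * (i + 1) + 10, True) for i in range(2)]
        )
        t = enrichment.gene_proximity_table(sig, np.array(densities), genes)
        assert (t.a, t.b, t.c, t.d) == (6, 4, 2, 8)
        assert enrichment.odds_ratio(t) == pytest.approx(6.0)

    def test_requires_candidates(self):
        sig = make_signals([(1, 100)])
        genes = gene_table([("G", 1, 50, 60, False)])
        with pytest.raises(SatmapError):
            enrichment.gene_proximity_table(sig, np.array([0]), genes)


class TestOddsRatio:
    def test_symmetric_table_gives_one(self):
        assert enrichment.odds_ratio(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_zero_cell_haldane_corrected_and_flagged(self):
        value, flagged = enrichment.odds_ratio(
            ContingencyTable2x2(6, 4, 0, 8), return_flag=True
        )
        assert flagged
        assert value == pytest.approx((6.5 * 8.5) / (4.5 * 0.5))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 0)


class TestEnrichmentNull:
    def test_reproducible_under_seed(self, small_genome):
        _, signals, genes = small_genome
        d = signal_density(signals)
        r1 = enrichment.enrichment_null(genes, signals, d, n_samples=50, seed=5)
        r2 = enrichment.enrichment_null(genes, signals, d, n_samples=50, seed=5)
        r3 = enrichment.enrichment_null(genes, signals, d, n_samples=50, seed=6)
        assert np.array_equal(r1.null_or, r2.null_or)
        assert not np.array_equal(r1.null_or, r3.null_or)

    def test_pvalue_uses_add_one_estimator(self, small_genome):
        _, signals, genes = small_genome
        d = signal_density(signals)
        r = enrichment.enrichment_null(genes, signals, d, n_samples=50, seed=5)
        assert 1 / 51 <= r.p_value <= 1.0

    def test_exhausted_length_class_names_class(self):
        sig = make_signals([(1, 100_000)])
        genes = gene_table(
            [("A", 1, 1, 2_500_000, True), ("B", 1, 10, 20, False)]
        )
        with pytest.raises(SatmapError, match="class 21"):
            enrichment.enrichment_null(genes, sig, np.array([0]), n_samples=5, seed=0)


class TestAnnotationMatching:
    def test_identical_annotations_sample_uniformly(self):
        pool = gen_annotation_pool(400, n_annotations=3, seed=1)
        for c in ("annot_1", "annot_2", "annot_3"):
            pool[c] = 1
        pool["selected"] = (np.arange(400) < 50).astype(int)
        res = enrichment.match_snps_by_annotation_model(pool, n_sets=3, set_size=30, seed=2)
        assert np.allclose(res.probabilities, res.probabilities[0])

    def test_planted_coefficient_recovered_and_balanced(self):
        coef = np.zeros(4)
        coef[0] = 2.5
        pool = gen_annotation_pool(
            6000, n_annotations=4, coefficients=coef, intercept=-2.5, seed=11
        )
        res = enrichment.match_snps_by_annotation_model(pool, n_sets=40, set_size=400, seed=3)
        assert res.coefficients["annot_1"] > 1.0
        sel = pool.loc[pool["selected"] == 1, "annot_1"].mean()
        sampled_means = [pool.iloc[idx]["annot_1"].mean() for idx in res.sets]
        assert abs(np.mean(sampled_means) - sel) < 0.05
        # annotations not in the model stay near the selected set's mean too
        assert res.summary.loc["annot_2", "mean_p"] > 0.2

    def test_all_selected_or_none_rejected(self):
        pool = gen_annotation_pool(100, n_annotations=2, seed=4)
        pool["selected"] = 1
        with pytest.raises(SatmapError):
            enrichment.match_snps_by_annotation_model(pool, n_sets=1, set_size=10)

    def test_perfect_separation_raises(self):
        pool = gen_annotation_pool(300, n_annotations=2, seed=5)
        pool["selected"] = pool["annot_1"]
        with pytest.raises(SatmapError, match="separation"):
            enrichment.match_snps_by_annotation_model(pool, n_sets=1, set_size=10)


class TestBinMatching:
    def test_targets_equal_pool_gives_permutation(self):
        pool = gen_annotation_pool(500, seed=6)
        matched = enrichment.match_snps_by_bins(pool, np.arange(500), seed=7)
        assert sorted(matched) == list(range(500))

    def test_joint_class_histogram_preserved(self):
        pool = gen_annotation_pool(5000, seed=8)
        rng = np.random.default_rng(9)
        targets = rng.choice(5000, size=600, replace=False)
        matched = enrichment.match_snps_by_bins(pool, targets, seed=10)
        assert matched.size == 600
        ld_edges = np.quantile(pool["ld_score"], [0.25, 0.5, 0.75])

        def hist(idx):
            maf_cls = np.digitize(pool["maf"].to_numpy()[idx], enrichment.DEFAULT_MAF_BREAKS)
            ld_cls = np.digitize(pool["ld_score"].to_numpy()[idx], ld_edges)
            return np.bincount(maf_cls * 4 + ld_cls, minlength=28)

        assert np.array_equal(hist(targets), hist(matched))

    def test_underfilled_class_raises(self):
        pool = gen_annotation_pool(50, seed=12)
        pool.loc[:, "maf"] = 0.25
        pool.loc[0, "maf"] = 0.005  # lone SNP in the rare-MAF class
        with pytest.raises(SatmapError):
            # two targets in a class holding a single pool SNP
            enrichment.match_snps_by_bins(pool, np.array([0, 0]), seed=0)


class TestLdIndependenceFilter:
    def ld(self, rows):
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])

    def test_no_ld_keeps_everything(self):
        kept, info = enrichment.ld_independence_filter(
            ["a1", "a2"], ["b1"], self.ld([]), self.ld([])
        )
        assert kept == ["a1", "a2"]
        assert info["missing_pairs_panel_a"] == 2

    def test_high_r2_in_single_panel_removes(self):
        ld_a = self.ld([("a1", "b1", 0.9)])
        kept, _ = enrichment.ld_independence_filter(["a1", "a2"], ["b1"], ld_a, self.ld([]))
        assert kept == ["a2"]

    def test_hand_derived_five_snp_scan(self):
        snps_a = [f"a{i}" for i in range(1, 6)]
        ld_a = self.ld([("a1", "b1", 0.85), ("a2", "b1", 0.3), ("a3", "b2", 0.79)])
        ld_b = self.ld([("a2", "b2", 0.5), ("b1", "a4", 0.81), ("a5", "b2", 0.2)])
        kept, info = enrichment.ld_independence_filter(snps_a, ["b1", "b2"], ld_a, ld_b)
        assert kept == ["a2", "a3", "a5"]
        assert info["removed"] == 2

    def test_boundary_is_exclusive(self):
        ld_a = self.ld([("a1", "b1", 0.8)])
        kept, _ = enrichment.ld_independence_filter(["a1"], ["b1"], ld_a, self.ld([]))
        assert kept == []
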