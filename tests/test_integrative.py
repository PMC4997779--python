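import numpy as np
import pandas as pd
import pytest

from tfsilence import integrative as itg
from tfsilence.io_formats import (
    GeneCoordinates,
    MutationRecord,
    SegmentRecord,
    VariantClass,
)


def frame(values, rows, cols):
    return pd.DataFrame(np.asarray(values, dtype=float), index=rows,
                        columns=cols)


class TestZScores:
    def test_arithmetic(self):
        normal = frame([[9, 10, 11, 10]], ["g"], list("abcd"))
        tumour = frame([[10, 5]], ["g"], ["t1", "t2"])
        z = itg.compute_zscores(tumour, normal)
        sigma = normal.loc["g"].std(ddof=1)
        assert z.z.loc["g", "t1"] == pytest.approx(0.0)
        assert z.z.loc["g", "t2"] == pytest.approx(-5 / sigma)

    def test_zero_sigma_genes_dropped(self):
        normal = frame([[1, 1, 1], [1, 2, 3]], ["flat", "ok"], list("abc"))
        tumour = frame([[0], [0]], ["flat", "ok"], ["t"])
        z = itg.compute_zscores(tumour, normal)
        assert list(z.z.index) == ["ok"]

    def test_too_few_normals_rejected(self):
        normal = frame([[1, 2]], ["g"], ["a", "b"])
        tumour = frame([[1]], ["g"], ["t"])
        with pytest.raises(ValueError):
            itg.compute_zscores(tumour, normal)

    def test_null_tumours_tail_rate(self):
        """Tumours drawn from the normal distribution itself: the Z < -2
        call rate matches the Gaussian tail (~0.023)."""
        rng = np.random.default_rng(12)
        n_genes, n_norm, n_tum = 300, 500, 50
        genes = [f"g{i}" for i in range(n_genes)]
        normal = frame(rng.normal(7, 1, (n_genes, n_norm)), genes,
                       [f"n{j}" for j in range(n_norm)])
        tumour = frame(rng.normal(7, 1, (n_genes, n_tum)), genes,
                       [f"t{j}" for j in range(n_tum)])
        z = itg.compute_zscores(tumour, normal)
        rate = itg.call_underexpression(z.z).to_numpy().mean()
        assert rate == pytest.approx(0.0228, abs=0.005)


class TestThresholdStrictness:
    """Values exactly at a threshold never produce a call."""

    def test_z_exactly_minus_two_not_called(self):
        z = frame([[-2.0, -2.01, 0.0]], ["g"], ["a", "b", "c"])
        calls = itg.call_underexpression(z)
        assert calls.loc["g"].tolist() == [False, True, False]

    def test_segval_exactly_at_threshold_not_called(self):
        assert itg.call_cnv_loss(-0.35) is False
        assert itg.call_cnv_loss(-0.36) is True
        assert itg.call_cnv_loss(0.0) is False
        seg = frame([[-0.35, -0.351]], ["g"], ["a", "b"])
        assert itg.call_cnv_loss(seg).loc["g"].tolist() == [False, True]

    def test_delta_beta_exactly_at_thresholds_not_called(self):
        tumour = frame([[0.70, 0.75, 0.55, 0.50]], ["g"], list("abcd"))
        normal = frame([[0.40, 0.40, 0.40]], ["g"], ["n1", "n2", "n3"])
        strict, relaxed, delta = itg.call_hypermethylation(tumour, normal)
        # deltas: 0.30 (exactly at strict), 0.35, 0.15, 0.10 (exactly relaxed)
        assert strict.loc["g"].tolist() == [False, True, False, False]
        assert relaxed.loc["g"].tolist() == [True, True, True, False]
        np.testing.assert_allclose(delta.loc["g"], [0.30, 0.35, 0.15, 0.10])

    def test_missing_datum_never_calls(self):
        assert itg.call_cnv_loss(float("nan")) is False
        tumour = frame([[np.nan]], ["g"], ["a"])
        normal = frame([[0.2, 0.2, 0.2]], ["g"], ["n1", "n2", "n3"])
        strict, relaxed, _ = itg.call_hypermethylation(tumour, normal)
        assert not strict.loc["g", "a"] and not relaxed.loc["g", "a"]


class TestSegmentMapping:
    COORDS = [GeneCoordinates("g1", "chr1", 100, 200),
              GeneCoordinates("g2", "chr1", 950, 1150),
              GeneCoordinates("g3", "chr2", 0, 100)]

    def test_full_containment(self):
        segs = [SegmentRecord("S1", "chr1", 0, 500, -0.5)]
        out = itg.map_segments_to_genes(segs, self.COORDS)
        assert out.loc["g1", "S1"] == -0.5

    def test_max_overlap_wins(self):
        # g2 spans [950,1150): 50 bp in the first segment, 150 in the second
        segs = [SegmentRecord("S1", "chr1", 0, 1000, 0.1),
                SegmentRecord("S1", "chr1", 1000, 2000, -0.7)]
        out = itg.map_segments_to_genes(segs, self.COORDS)
        assert out.loc["g2", "S1"] == -0.7

    def test_tie_goes_to_smaller_start(self):
        segs = [SegmentRecord("S1", "chr1", 0, 1050, 0.1),
                SegmentRecord("S1", "chr1", 1050, 2000, -0.7)]
        out = itg.map_segments_to_genes(segs, self.COORDS)
        assert out.loc["g2", "S1"] == 0.1  # 100 bp each; earlier start wins

    def test_no_overlap_is_missing(self):
        segs = [SegmentRecord("S1", "chr1", 0, 500, 0.2)]
        out = itg.map_segments_to_genes(segs, self.COORDS)
        assert np.isnan(out.loc["g3", "S1"])

    def test_overlap_oracle_on_random_instances(self):
        """Brute-force per-base overlap count agrees with the mapper."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            coords = [GeneCoordinates(f"g{i}", "chr1",
                                      s := int(rng.integers(0, 900)),
                                      s + int(rng.integers(10, 100)))
                      for i in range(5)]
            starts = np.sort(rng.choice(1000, 4, replace=False))
            bounds = [0, *starts.tolist(), 1000]
            segs = [SegmentRecord("S1", "chr1", bounds[i], bounds[i + 1],
                                  float(rng.normal()))
                    for i in range(len(bounds) - 1)]
            out = itg.map_segments_to_genes(segs, coords)
            for c in coords:
                per_base = {}
                for s in segs:
                    ov = len(set(range(c.start, c.end))
                             & set(range(s.start, s.end)))
                    if ov:
                        per_base.setdefault(ov, []).append(s)
                best = min(per_base[max(per_base)], key=lambda s: s.start)
                assert out.loc[c.gene_id, "S1"] == best.segval


class TestMutationCalls:
    def test_multiple_hits_count_once(self):
        recs = [MutationRecord("S1", "TP53", VariantClass.Missense),
                MutationRecord("S1", "TP53", VariantClass.Missense),
                MutationRecord("S1", "TP53", VariantClass.Nonsense)]
        out = itg.call_inactivating_mutation(recs, ["TP53"], ["S1", "S2"])
        assert out.loc["TP53", "S1"] and not out.loc["TP53", "S2"]

    def test_other_class_not_inactivating(self):
        recs = [MutationRecord("S1", "TP53", VariantClass.Other)]
        out = itg.call_inactivating_mutation(recs, ["TP53"], ["S1"])
        assert not out.loc["TP53", "S1"]

    def test_no_records_all_false(self):
        out = itg.call_inactivating_mutation([], ["g1", "g2"], ["S1"])
        assert not out.to_numpy().any()


def toy_calls(n_under=4, loss_in=1, hyper_in=2):
    tumours = [f"t{j}" for j in range(6)]
    under = frame([[1] * n_under + [0] * (6 - n_under)], ["g"], tumours) > 0
    loss = frame([[1] * loss_in + [0] * (6 - loss_in)], ["g"], tumours) > 0
    hyper = frame([[0] * (n_under - hyper_in) + [1] * hyper_in + [0] * (6 - n_under)],
                  ["g"], tumours) > 0
    mut = frame([[0] * 6], ["g"], tumours) > 0
    delta = frame([[0.4 if h else 0.0 for h in hyper.loc["g"]]], ["g"], tumours)
    seg = frame([[-0.7 if l else 0.0 for l in loss.loc["g"]]], ["g"], tumours)
    return itg.AlterationCalls(underexpressed=under, cnv_loss=loss,
                               hypermeth=hyper, hypermeth_relaxed=hyper,
                               mutated=mut, delta_beta=delta, segval=seg)


class TestMechanismFrequencies:
    def test_fraction_arithmetic(self):
        freqs = itg.mechanism_frequencies(toy_calls())
        row = freqs.loc["g"]
        assert row["n_under"] == 4
        assert row["f_loss"] == pytest.approx(0.25)
        assert row["f_hyper"] == pytest.approx(0.5)
        assert row["f_mut"] == 0.0

    def test_no_alterations_is_neither(self):
        freqs = itg.mechanism_frequencies(toy_calls(loss_in=0, hyper_in=0))
        row = freqs.loc["g"]
        assert (row["f_loss"], row["f_hyper"], row["f_mut"]) == (0, 0, 0)
        assert row["mechanism_class"] == "Neither"

    def test_never_underexpressed_excluded(self):
        freqs = itg.mechanism_frequencies(toy_calls(n_under=0, loss_in=0,
                                                    hyper_in=0))
        assert "g" not in freqs.index

    @pytest.mark.parametrize("f_hyper,f_loss,expected", [
        (0.5, 0.05, "DNAmDominant"),
        (0.05, 0.5, "CNVDominant"),
        (0.4, 0.4, "Both"),
        (0.05, 0.05, "Neither"),
        (0.25, 0.15, "Neither"),  # falls in the cutoff gap
    ])
    def test_classification_cutoffs(self, f_hyper, f_loss, expected):
        n_h, n_l = int(f_hyper * 20), int(f_loss * 20)
        tumours = [f"t{j}" for j in range(20)]
        under = frame([[1] * 20], ["g"], tumours) > 0
        hyper = frame([[1] * n_h + [0] * (20 - n_h)], ["g"], tumours) > 0
        loss = frame([[0] * (20 - n_l) + [1] * n_l], ["g"], tumours) > 0
        mut = frame([[0] * 20], ["g"], tumours) > 0
        vals = frame([[0.0] * 20], ["g"], tumours)
        calls = itg.AlterationCalls(under, loss, hyper, hyper, mut, vals, vals)
        freqs = itg.mechanism_frequencies(calls)
        assert freqs.loc["g", "mechanism_class"] == expected


class TestChannelComparison:
    def test_planted_dnam_shift_detected(self, rng):
        genes = [f"g{i}" for i in range(120)]
        tfs = set(genes[:20])
        dnam = pd.Series(rng.normal(0, 1, 120), index=genes)
        dnam[list(tfs)] += 2.0
        seg = pd.Series(rng.normal(0, 0.1, 120), index=genes)
        mut = pd.Series(np.zeros(120), index=genes)
        out = itg.compare_silenced_vs_underexpressed(dnam, seg, mut, tfs,
                                                     set(genes))
        assert out["p_dnam"] < 0.01
        assert out["p_cnv"] > 0.05

    def test_null_channels_uniformish(self):
        ps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(100)]
            stat = pd.Series(rng.normal(size=100), index=genes)
            out = itg.compare_silenced_vs_underexpressed(
                stat, stat * 0 + rng.normal(size=100), stat * 0,
                set(genes[:15]), set(genes))
            ps.append(out["p_dnam"])
        assert all(p >= 0.001 for p in ps)
        assert np.mean(ps) > 0.2

    def test_subset_violation_rejected(self):
        s = pd.Series([1.0], index=["g"])
        with pytest.raises(ValueError):
            itg.compare_silenced_vs_underexpressed(s, s, s, {"g"}, set())


class TestMetaCombine:
    def test_all_ones(self):
        table = pd.DataFrame({"p_dnam": [1.0] * 6, "p_cnv": [1.0] * 6})
        out = itg.meta_combine(table)
        assert out["p_dnam"] == pytest.approx(1.0)

    def test_closed_form_pair(self):
        table = pd.DataFrame({"p_dnam": [0.5, 0.5]})
        assert itg.meta_combine(table)["p_dnam"] == pytest.approx(0.5966,
                                                                  abs=5e-5)

    def test_monotone_in_inputs(self):
        t1 = pd.DataFrame({"c": [0.5, 0.5, 0.5]})
        t2 = pd.DataFrame({"c": [0.5, 0.1, 0.5]})
        assert itg.meta_combine(t2)["c"] < itg.meta_combine(t1)["c"]

    def test_single_cancer_rejected(self):
        with pytest.raises(ValueError):
            itg.meta_combine(pd.DataFrame({"c": [0.5]}))


class TestExpectedCountsNull:
    @staticmethod
    def null_calls(rng, n_genes=200, n_tum=30):
        genes = [f"g{i}" for i in range(n_genes)]
        tumours = [f"t{j}" for j in range(n_tum)]
        under = frame(rng.random((n_genes, n_tum)) < 0.3, genes, tumours) > 0
        hyper = frame(rng.random((n_genes, n_tum)) < 0.1, genes, tumours) > 0
        vals = frame(np.zeros((n_genes, n_tum)), genes, tumours)
        return itg.AlterationCalls(under, under & False, hyper, hyper,
                                   under & False, vals + 0.05, vals), genes

    def test_null_draw_covered_by_interval(self):
        """A 'TF set' drawn from the null pool lands inside the 95%
        interval in most repeats."""
        rng = np.random.default_rng(21)
        calls, genes = self.null_calls(rng)
        pool = set(genes)
        inside = 0
        for rep in range(50):
            fake_tfs = set(rng.choice(genes, size=20, replace=False))
            out = itg.expected_counts_null(calls, pool, fake_tfs,
                                           n_draws=300, seed=rep)
            inside += out["ci_low"] <= out["observed"] <= out["ci_high"]
        assert inside >= 45

    def test_planted_enrichment_above_interval(self):
        rng = np.random.default_rng(22)
        calls, genes = self.null_calls(rng)
        # enrich the first 20 genes with extra joint events
        enriched = calls.hypermeth.copy()
        enriched.iloc[:20] = calls.underexpressed.iloc[:20]
        calls = itg.AlterationCalls(calls.underexpressed, calls.cnv_loss,
                                    enriched, enriched, calls.mutated,
                                    calls.delta_beta, calls.segval)
        out = itg.expected_counts_null(calls, set(genes), set(genes[:20]),
                                       n_draws=300, seed=0)
        assert out["observed"] > out["ci_high"]

    def test_degenerate_single_draw_flagged(self):
        rng = np.random.default_rng(23)
        calls, genes = self.null_calls(rng, n_genes=30, n_tum=5)
        out = itg.expected_counts_null(calls, set(genes), set(genes[:5]),
                                       n_draws=1, seed=0)
        assert out.get("degenerate") and out["ci_low"] == out["ci_high"]


def planted_freqs(n_dnam=10, n_cnv=10, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_dnam):
        rows.append((f"d{i}", 10, 0.02 * rng.random(), 0.6 + 0.3 * rng.random(),
                     0.7, 0.0, 10, 10, "DNAmDominant"))
    for i in range(n_cnv):
        rows.append((f"c{i}", 10, 0.6 + 0.3 * rng.random(), 0.02 * rng.random(),
                     0.05, 0.0, 10, 10, "CNVDominant"))
    return pd.DataFrame(rows, columns=["gene", "n_under", "f_loss", "f_hyper",
                                       "f_hyper_relaxed", "f_mut",
                                       "n_loss_data", "n_hyper_data",
                                       "mechanism_class"]).set_index("gene")


class TestTertileExclusivity:
    def test_planted_anticorrelation_significant(self):
        out = itg.tertile_exclusivity(planted_freqs())
        assert out["p_hyper_in_low_loss"] < 0.05
        assert out["p_loss_in_low_hyper"] < 0.05

    def test_equal_frequencies_no_evidence(self):
        freqs = planted_freqs()
        freqs["f_loss"] = 0.3
        freqs["f_hyper"] = 0.3
        out = itg.tertile_exclusivity(freqs)
        assert out["p_hyper_in_low_loss"] >= 0.5

    def test_independent_frequencies_null_p(self):
        ps = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            freqs = planted_freqs(rng=rng)
            freqs["f_loss"] = rng.random(len(freqs))
            freqs["f_hyper"] = rng.random(len(freqs))
            ps.append(itg.tertile_exclusivity(freqs)["p_hyper_in_low_loss"])
        assert np.mean(ps) > 0.2

    def test_too_few_tfs_rejected(self):
        with pytest.raises(ValueError):
            itg.tertile_exclusivity(planted_freqs(n_dnam=2, n_cnv=2))


class TestPerTFExclusivity:
    @staticmethod
    def exclusive_calls(n_tum=30, exclusive=True):
        tumours = [f"t{j}" for j in range(n_tum)]
        under = frame([[1] * n_tum], ["g"], tumours) > 0
        half = n_tum // 2
        loss_row = [1] * half + [0] * (n_tum - half)
        loss = frame([loss_row], ["g"], tumours) > 0
        delta_row = [0.0 if (l and exclusive) else 0.4 for l in loss_row]
        delta = frame([delta_row], ["g"], tumours)
        seg = frame([[-0.7 if l else 0.0 for l in loss_row]], ["g"], tumours)
        return itg.AlterationCalls(under, loss, delta > 0.3, delta > 0.1,
                                   loss & False, delta, seg)

    def test_planted_exclusive_tf_flagged(self):
        out = itg.per_tf_exclusivity(self.exclusive_calls())
        assert out.loc["g", "p"] < 0.05

    def test_cooccurring_alterations_not_flagged(self):
        out = itg.per_tf_exclusivity(self.exclusive_calls(exclusive=False))
        assert out.loc["g", "p"] >= 0.3

    def test_below_min_freq_excluded(self):
        calls = self.exclusive_calls()
        out = itg.per_tf_exclusivity(calls, min_freq=0.9)
        assert "g" not in out.index


class TestCrossCancerConcordance:
    def test_identical_vectors_r2_one(self):
        f = planted_freqs()
        table, _ = itg.cross_cancer_concordance({"A": f, "B": f.copy()})
        assert table.loc[0, "r2_dnam"] == pytest.approx(1.0)
        assert table.loc[0, "r2_cnv"] == pytest.approx(1.0)

    def test_shared_dnam_noisy_cnv(self):
        rng = np.random.default_rng(5)
        tables = {}
        base = planted_freqs(rng=rng)
        for name in "ABCD":
            f = base.copy()
            f["f_loss"] = rng.random(len(f))  # CNV not reproducible
            tables[name] = f
        table, p = itg.cross_cancer_concordance(tables)
        assert (table["r2_dnam"] > table["r2_cnv"]).all()
        assert p < 0.05

    def test_independent_frequencies_r2_near_zero(self):
        rng = np.random.default_rng(6)
        tables = {}
        for name in "AB":
            f = planted_freqs(rng=rng)
            f["f_hyper"] = rng.random(len(f))
            f["f_loss"] = rng.random(len(f))
            tables[name] = f
        table, _ = itg.cross_cancer_concordance(tables)
        assert table.loc[0, "r2_dnam"] < 0.3
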