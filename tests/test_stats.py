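"""Statistics: dispersion, normalization, DE calling, UMI collision model."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnakit import readproc
from srnakit.simulate import LibraryLayout, SimConfig, make_population, simulate_library
from srnakit.stats import (
    barcode_bias,
    bh_adjust,
    bias_improvement,
    chi_square_2x2,
    de_test,
    dispersion_table,
    normalize_counts,
    replicate_dispersion,
    size_factors,
    umi_correct,
    umi_expected_distinct,
    undercount_fraction,
)


class TestReplicateDispersion:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(100, 110, 0.01), (7, 7, 0.0), (50, 60, 0.04), (110, 100, 0.01)],
    )
    def test_squared_relative_difference(self, a, b, expected):
        assert replicate_dispersion(a, b) == pytest.approx(expected)

    def test_ten_percent_gives_hundredth_exactly(self):
        assert replicate_dispersion(100, 110) == pytest.approx(0.01, rel=1e-12)

    @given(
        a=st.floats(0.1, 1e6),
        b=st.floats(0.1, 1e6),
        c=st.floats(0.01, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance(self, a, b, c):
        assert replicate_dispersion(c * a, c * b) == pytest.approx(
            replicate_dispersion(a, b), rel=1e-6
        )

    def test_zero_against_positive_is_infinite(self):
        assert replicate_dispersion(0, 5) == math.inf

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            replicate_dispersion(0, 0)

    def test_three_replicates_average_pairs(self):
        # pairs (100,110), (100,120), (110,120): 0.01 + 0.04 + (10/110)^2
        expected = (0.01 + 0.04 + (10 / 110) ** 2) / 3
        assert replicate_dispersion(100, 110, 120) == pytest.approx(expected)

    def test_cv2_mode(self):
        vals = [100.0, 110.0]
        expected = np.var(vals, ddof=1) / np.mean(vals) ** 2
        assert replicate_dispersion(*vals, mode="cv2") == pytest.approx(expected)

    def test_table_skips_all_zero_features(self):
        df = pd.DataFrame({"r1": [0, 10], "r2": [0, 11]}, index=["f0", "f1"])
        recs = dispersion_table(df)
        assert [r.feature for r in recs] == ["f1"]


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert size_factors(df).tolist() == pytest.approx([1.0, 1.0])

    def test_median_of_ratios_hand_example(self):
        df = pd.DataFrame({"a": [100, 10, 40], "b": [200, 20, 80]})
        f = size_factors(df)
        assert f["a"] == pytest.approx(1 / math.sqrt(2))
        assert f["b"] == pytest.approx(math.sqrt(2))

    def test_scaling_equivariance_of_factor_ratios(self):
        # scaling one library by c shifts the geometric means too, so the
        # invariant quantity is the ratio of factors, which scales by c
        df = pd.DataFrame({"a": [100, 10, 40], "b": [200, 20, 80]})
        scaled = df.copy()
        scaled["b"] = scaled["b"] * 3
        f, g = size_factors(df), size_factors(scaled)
        assert g["b"] / g["a"] == pytest.approx(3 * f["b"] / f["a"])
        # and normalized counts are unchanged up to a global constant
        n1, n2 = normalize_counts(df), normalize_counts(scaled)
        assert (n2 / n1).stack().std() == pytest.approx(0.0, abs=1e-12)

    def test_no_all_positive_feature_errors(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(df)
        assert size_factors(df, pseudocount=1.0).notna().all()

    def test_normalize_divides_by_factors(self):
        df = pd.DataFrame({"a": [100, 10, 40], "b": [200, 20, 80]})
        norm = normalize_counts(df)
        assert norm["a"].tolist() == pytest.approx(norm["b"].tolist())


class TestBhAdjust:
    def test_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.33]).tolist() == pytest.approx([0.33])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]).tolist() == pytest.approx([0.2] * 3)

    def test_order_preserving(self):
        p = [0.001, 0.5, 0.04, 0.2]
        adj = bh_adjust(p)
        assert np.argsort(adj).tolist() == np.argsort(p).tolist()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestChiSquare:
    def test_balanced_table_zero_statistic(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_formula(self):
        a, b, c, d = 10, 20, 20, 10
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = chi_square_2x2([[a, b], [c, d]])
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(6.6667, abs=1e-3)

    def test_transposition_invariance(self):
        t = [[13, 7], [5, 25]]
        assert chi_square_2x2(t)[0] == pytest.approx(
            chi_square_2x2(np.transpose(t))[0]
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestUmiModel:
    def test_single_molecule(self):
        for K in (4, 256, 4**8):
            assert umi_expected_distinct(1, K) == pytest.approx(1.0)

    def test_closed_form_matches_monte_carlo(self):
        """E[distinct] = K(1-(1-1/K)^n) vs 1e5 simulated draws at n=64, K=256."""
        n, K, trials = 64, 256, 100_000
        rng = np.random.default_rng(12345)
        draws = rng.integers(0, K, size=(trials, n))
        distinct = np.array([len(np.unique(row)) for row in draws])
        mc = distinct.mean()
        analytic = umi_expected_distinct(n, K)
        assert analytic == pytest.approx(56.7246, abs=1e-3)
        assert abs(analytic - mc) / mc < 0.005

    def test_saturation_limit(self):
        assert umi_expected_distinct(10**6, 256) == pytest.approx(256.0)

    def test_correct_inverts_expected(self):
        assert umi_correct(56.7246, 256) == pytest.approx(64.0, rel=0.005)

    def test_small_count_limit(self):
        assert umi_correct(1.0, 4**8) == pytest.approx(1.0, abs=1 / (2 * 4**8) + 1e-9)

    def test_round_trip_within_half_percent(self):
        K = 4**8
        for n in [1, 10, 100, 1000, K // 10, K // 4, K // 2]:
            back = umi_correct(umi_expected_distinct(n, K), K)
            assert back == pytest.approx(n, rel=0.005)

    def test_saturated_observation_rejected(self):
        with pytest.raises(ValueError):
            umi_correct(256, 256)

    def test_undercount_band_at_moderate_saturation(self):
        """Copy/label ratios 0.2-0.6 undercount by roughly 9-25%."""
        ratios = np.linspace(0.2, 0.6, 9)
        under = [undercount_fraction(r) for r in ratios]
        assert all(0.09 <= u <= 0.25 for u in under)
        assert under == sorted(under)  # worsens with saturation


def _nb_matrix(rng, n_features, mu, alpha, n_rep=3, fold=None, n_effect=0):
    """NB counts for two conditions; the first n_effect features get a
    `fold`-fold higher mean in condition B."""
    mus = rng.lognormal(np.log(mu), 0.8, size=n_features)
    data = {}
    for cond, suffix in ((0, "a"), (1, "b")):
        for r in range(n_rep):
            m = mus.copy()
            if cond == 1 and n_effect:
                m[:n_effect] *= fold
            p = 1 / (1 + alpha * m)
            counts = rng.negative_binomial(1 / alpha, p)
            data[f"{suffix}{r}"] = counts
    df = pd.DataFrame(data, index=[f"f{i}" for i in range(n_features)])
    return df, [f"a{r}" for r in range(n_rep)], [f"b{r}" for r in range(n_rep)]


class TestDeTest:
    def test_identical_groups_no_calls(self):
        df = pd.DataFrame(
            {s: [100, 50, 20] for s in ("a0", "a1", "b0", "b1")},
            index=["f0", "f1", "f2"],
        )
        res = de_test(df, ["a0", "a1"], ["b0", "b1"])
        assert all(r.call == "ns" and r.log2fc == 0.0 for r in res)

    def test_twentyfold_feature_called_with_correct_sign(self):
        rng = np.random.default_rng(0)
        stable = rng.poisson(100, size=(40, 6)).astype(float)
        df = pd.DataFrame(
            np.vstack([stable, [[10, 10, 10, 200, 200, 200]]]),
            index=[f"s{i}" for i in range(40)] + ["hot"],
            columns=["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        res = {r.feature: r for r in de_test(df, ["a0", "a1", "a2"], ["b0", "b1", "b2"])}
        assert res["hot"].call == "up"
        assert res["hot"].log2fc > math.log2(5)

    def test_recovers_planted_eightfold_effects(self):
        """200 NB features, 20 with a true 8-fold effect, 3 replicates per
        group: >= 80% of effects called, ~no false calls among 180 nulls."""
        rng = np.random.default_rng(2024)
        df, cond_a, cond_b = _nb_matrix(
            rng, 200, mu=200, alpha=0.05, fold=8.0, n_effect=20
        )
        res = de_test(df, cond_a, cond_b)
        true_calls = sum(
            1 for r in res if r.feature in {f"f{i}" for i in range(20)} and r.call == "up"
        )
        false_calls = sum(
            1 for r in res if r.feature not in {f"f{i}" for i in range(20)} and r.call != "ns"
        )
        assert true_calls >= 16
        assert false_calls <= 2

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(7)
        df, cond_a, cond_b = _nb_matrix(rng, 300, mu=150, alpha=0.05)
        res = de_test(df, cond_a, cond_b)
        assert sum(1 for r in res if r.call != "ns") <= 3

    def test_calls_agree_with_independent_nb_implementation(self):
        """The moment/Wald test calls the same features as a full NB GLM
        fit (pydeseq2) under the fivefold + padj<0.01 thresholds."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from pydeseq2.dds import DeseqDataSet
            from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(11)
        df, cond_a, cond_b = _nb_matrix(
            rng, 200, mu=200, alpha=0.05, fold=8.0, n_effect=20
        )
        meta = pd.DataFrame(
            {"condition": ["a"] * 3 + ["b"] * 3}, index=cond_a + cond_b
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=df[cond_a + cond_b].T, metadata=meta,
                design="~condition", quiet=True,
            )
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "b", "a"], quiet=True)
            ds.summary()
        ref = ds.results_df
        ref_sig = set(
            ref[(ref.padj < 0.01) & (ref.log2FoldChange.abs() >= math.log2(5))].index
        )
        mine = {r.feature for r in de_test(df, cond_a, cond_b) if r.call != "ns"}
        union = ref_sig | mine
        assert union
        assert len(ref_sig & mine) / len(union) >= 0.8

    def test_requires_replicates(self):
        df = pd.DataFrame({"a0": [1], "b0": [2], "b1": [3]})
        with pytest.raises(ValueError):
            de_test(df, ["a0"], ["b0", "b1"])

    def test_unknown_sample_rejected(self):
        df = pd.DataFrame({"a0": [1], "a1": [1], "b0": [1], "b1": [1]})
        with pytest.raises(ValueError):
            de_test(df, ["a0", "zz"], ["b0", "b1"])


class TestBarcodeBias:
    def test_equal_counts_zero_bias(self):
        bias = barcode_bias({"f": 10.0}, {"f": 10.0})
        assert bias["f"] == 0.0

    def test_direct_formula(self):
        bias = barcode_bias({"f": 100.0}, {"f": 50.0})
        assert bias["f"] == pytest.approx(math.log2(100.5 / 50.5))

    def test_collapsing_reduces_interlibrary_bias(self):
        """Two libraries from one population with independent PCR bias:
        the collapsed flavor sits closer between libraries than raw."""
        config = SimConfig(seed=31, pcr_cycles=10, n_reads=8000,
                           dimer_fraction=0.0, seq_error_rate=0.0)
        pop = make_population(config, {"miRNA": 1.0}, 80)
        flavors = {"raw": {}, "collapsed": {}}
        for bc, seed in (("ACGT", 101), ("TGCA", 202)):
            cfg = SimConfig(seed=seed, pcr_cycles=10, n_reads=8000,
                            dimer_fraction=0.0, seq_error_rate=0.0)
            lib = simulate_library(pop, LibraryLayout(barcode=bc), cfg)
            processed = readproc.process_reads(lib.reads, bc, lib.layout.adapter3)
            res = readproc.collapse([r for r in processed if r.status == "ok"])
            total_raw = sum(res.raw_counts.values())
            total_col = sum(res.collapsed_counts.values())
            flavors["raw"][bc] = {k: v / total_raw * 1e4 for k, v in res.raw_counts.items()}
            flavors["collapsed"][bc] = {
                k: v / total_col * 1e4 for k, v in res.collapsed_counts.items()
            }
        bias_raw = barcode_bias(flavors["raw"]["ACGT"], flavors["raw"]["TGCA"])
        bias_col = barcode_bias(flavors["collapsed"]["ACGT"], flavors["collapsed"]["TGCA"])
        assert bias_col.median() < bias_raw.median()
        summary = bias_improvement(bias_raw, bias_col)
        assert summary["fraction_improved"] > 0.5
        assert summary["mean_reduction"] > 0.0
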