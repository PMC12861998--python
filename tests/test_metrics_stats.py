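import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gainsim import metrics_stats as ms
from gainsim import trait_model as tm


class TestAccuracy:
    def test_perfect_and_inverted_prediction(self):
        g = np.array([0.1, 1.2, -0.5, 2.0])
        assert ms.accuracy(g, g) == pytest.approx(1.0)
        assert ms.accuracy(g, -g) == pytest.approx(-1.0)

    def test_hand_pearson_example(self):
        assert ms.accuracy([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9819805, abs=1e-6)

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = ms.accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(out)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ms.accuracy([1, 2], [1, 2])


class TestResponse:
    def test_subtraction(self):
        assert ms.response(3.4, 1.0) == pytest.approx(2.4)
        assert ms.response(1.0, 1.0) == 0.0

    def test_annualized_formula(self):
        assert ms.annualized_response(4.0, 2.0, 50.0) == pytest.approx(2.0)
        assert ms.annualized_response(2.0, 2.0, 50.0) == 0.0
        # negative baseline: |Ḡ0| in the denominator, sign from the numerator
        assert ms.annualized_response(-1.0, -2.0, 50.0) == pytest.approx(1.0)

    def test_zero_baseline_flags_nan(self):
        with pytest.warns(UserWarning):
            out = ms.annualized_response(1.0, 0.0, 50.0)
        assert np.isnan(out)


class TestRelativize:
    def test_ratio_and_difference_modes(self):
        s = np.array([2.0, 3.0, 1.0])
        np.testing.assert_allclose(ms.relativize(s), [1.0, 1.5, 0.5])
        np.testing.assert_allclose(ms.relativize(s, mode="difference"), [0.0, 1.0, -1.0])

    def test_constant_series_maps_to_one(self):
        np.testing.assert_allclose(ms.relativize(np.full(4, 2.5)), np.ones(4))


class TestVarianceComponents:
    def test_monomorphic_population_has_zero_variance(self, small_founders, small_arch):
        from gainsim.genome_founders import HaplotypePopulation

        fixed = HaplotypePopulation(
            haplotypes=small_founders.haplotypes[np.zeros(10, dtype=int)],
            gmap=small_founders.gmap,
            ids=np.arange(10),
            family=np.full(10, -1),
            generation="F6",
        )
        va, vaa = ms.variance_components_true(fixed, small_arch)
        assert va == 0.0 and vaa == 0.0

    def test_founder_ratio_half(self, small_map, small_founders):
        arch = tm.sample_architecture(small_map, small_founders, 0.5, seed=31)
        va, vaa = ms.variance_components_true(small_founders, arch)
        assert vaa / va == pytest.approx(0.5, rel=0.01)
        assert va >= 0 and vaa >= 0


class TestComparisons:
    def test_identical_groups_null_case(self):
        g = np.linspace(-1, 1, 30)
        res = ms.compare_sizes({25: g, 50: g, 100: g, 200: g})
        assert res.welch.iloc[0]["p_unc"] > 0.99
        assert res.omega_squared == 0.0
        assert len(res.pairwise) == 6

    def test_welch_approaches_classic_f_under_equal_variance(self):
        rng = np.random.default_rng(0)
        groups = {}
        for i, s in enumerate([25, 50, 100, 200]):
            g = rng.normal(size=100)
            groups[s] = (g - g.mean()) / g.std(ddof=1) + i * 0.3  # unit sample var
        res = ms.compare_sizes(groups)
        f_classic = scipy.stats.f_oneway(*groups.values()).statistic
        assert res.welch.iloc[0]["F"] == pytest.approx(f_classic, rel=0.01)

    def test_two_group_games_howell_reduces_to_welch_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.8, 2.5, 25)
        res = ms.compare_sizes({25: a, 200: b})
        p_welch_t = scipy.stats.ttest_ind(a, b, equal_var=False).pvalue
        assert res.pairwise.iloc[0]["pval"] == pytest.approx(p_welch_t, rel=0.02)

    def test_omega_squared_increases_with_separation(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=50)
        oms = [
            ms.omega_squared([base, base + d, base + 2 * d])
            for d in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a <= b for a, b in zip(oms, oms[1:]))

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError):
            ms.compare_sizes({25: np.ones(2), 50: np.ones(5)})


def _toy_records():
    rows = []
    for rep in range(2):
        for cycle in range(3):
            rows.append(
                ms.CycleRecord(
                    replicate=rep,
                    cycle=cycle,
                    year=5 * cycle,
                    context="theoretical",
                    progeny_size=25,
                    epistasis_ratio=0.0,
                    mean_G=2.0 + 0.5 * cycle,
                    best_line_G=3.0 + 0.5 * cycle,
                    Va=0.5 - 0.1 * cycle,
                    Vaa=0.0,
                    accuracy=0.6,
                    parents_mean_G=2.5 + 0.5 * cycle,
                ).to_dict()
            )
    return pd.DataFrame(rows, columns=ms.RECORD_COLUMNS)


class TestRecordPipeline:
    def test_response_columns_from_baseline(self):
        out = ms.add_response_columns(_toy_records())
        run = out[(out["replicate"] == 0)].sort_values("cycle")
        # R_t = parents_mean(t) − population mean at cycle 0 (= 2.0)
        np.testing.assert_allclose(run["response"], [0.5, 1.0, 1.5])
        # %/yr at t years, relative to |Ḡ0|
        np.testing.assert_allclose(
            run["response_pct_yr"], [0.0, 100 / 5 * 1.0 / 2.0, 100 / 10 * 1.5 / 2.0]
        )
        np.testing.assert_allclose(run["mean_G_rel"], [1.0, 1.25, 1.5])

    def test_summary_shape(self):
        out = ms.summarize_records(_toy_records())
        assert len(out) == 3
        assert (out["n_replicates"] == 2).all()
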