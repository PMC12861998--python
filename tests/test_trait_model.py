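import numpy as np
import pytest

from gainsim import genome_founders as gf
from gainsim import trait_model as tm


def _manual_arch(n_loci=4, a=(1.0, 2.0), pair_effect=3.0):
    """Hand-built two-QTN architecture for exact bilinear-form checks."""
    return tm.TraitArchitecture(
        qtn_idx=np.array([0, 1]),
        additive_effects=np.array(a),
        pair_idx=np.array([[0, 1]]),
        pair_effects=np.array([pair_effect]),
        dosage_centering=np.zeros(2),
        epistatic_offset=0.0,
        intercept=5.0,
        error_variance=1e-12,
        epistasis_ratio=1.0,
        target_H2=0.63,
    )


def _pop_with_dosages(dosages, n_loci=4):
    """Population whose -1/0/1 dosage rows equal the given matrix."""
    dosages = np.asarray(dosages)
    n = dosages.shape[0]
    h = np.zeros((n, 2, n_loci), dtype=np.uint8)
    h[:, 0, : dosages.shape[1]] = (dosages >= 0).astype(np.uint8)
    h[:, 1, : dosages.shape[1]] = (dosages >= 1).astype(np.uint8)
    gmap = gf.GeneticMap(
        chrom=np.zeros(n_loci, dtype=np.int16),
        pos_cM=np.arange(n_loci, dtype=float),
        role=np.array([1, 1, 0, 0], dtype=np.int8),
        chr_lengths_cM=np.array([float(n_loci)]),
    )
    return gf.HaplotypePopulation(
        haplotypes=h,
        gmap=gmap,
        ids=np.arange(n),
        family=np.full(n, -1),
        generation="F2",
    )


class TestGeneticValue:
    def test_bilinear_form_hand_example(self):
        # dosages (1,1): G = 1·1 + 2·1 + 3·1·1 = 6
        pop = _pop_with_dosages([[1, 1]])
        real = tm.genetic_value(pop, _manual_arch())
        assert real.genetic_values[0] == pytest.approx(6.0)

    def test_zero_dosage_gives_zero(self):
        pop = _pop_with_dosages([[0, 0]])
        real = tm.genetic_value(pop, _manual_arch())
        assert real.genetic_values[0] == pytest.approx(0.0)

    def test_components_sum_exactly(self, small_founders, small_arch):
        real = tm.genetic_value(small_founders, small_arch)
        np.testing.assert_array_equal(
            real.genetic_values,
            real.additive_component + real.epistatic_component,
        )


class TestCalibration:
    def test_no_epistasis_means_no_pairs(self, small_map, small_founders):
        arch = tm.sample_architecture(small_map, small_founders, 0.0, seed=1)
        assert arch.pair_idx.size == 0
        real = tm.genetic_value(small_founders, arch)
        assert real.epistatic_component.var() == 0.0

    @pytest.mark.parametrize("ratio", [0.5, 1.0])
    def test_epistasis_ratio_recovered(self, small_map, small_founders, ratio):
        arch = tm.sample_architecture(small_map, small_founders, ratio, seed=2)
        real = tm.genetic_value(small_founders, arch)
        observed = real.epistatic_component.var() / real.additive_component.var()
        assert observed == pytest.approx(ratio, rel=0.01)

    def test_founder_standardization(self, small_founders, small_arch):
        real = tm.genetic_value(small_founders, small_arch)
        assert abs(real.genetic_values.mean()) < 1e-9
        assert real.genetic_values.var() == pytest.approx(1.0, abs=1e-9)

    def test_error_variance_matches_h2_target(self, small_arch):
        # H² = VG/(VG + σe²) with VG = 1 → σe² = (1 − H²)/H²
        assert small_arch.error_variance == pytest.approx((1 - 0.63) / 0.63, rel=1e-12)

    def test_ratio_stable_across_seeds(self, small_map, small_founders):
        for seed in (5, 6):
            arch = tm.sample_architecture(small_map, small_founders, 1.0, seed=seed)
            real = tm.genetic_value(small_founders, arch)
            assert real.genetic_values.var() == pytest.approx(1.0, abs=1e-9)
            ratio = real.epistatic_component.var() / real.additive_component.var()
            assert ratio == pytest.approx(1.0, rel=0.01)

    def test_epistasis_with_one_qtn_raises(self, small_founders):
        gmap = gf.build_map(
            n_chromosomes=1,
            chr_lengths_cM=[100.0],
            n_loci_total=40,
            n_qtn_per_chr=1,
            n_snp_per_chr=2,
            seed=3,
        )
        founders = gf.simulate_founders(gmap, 30, seed=4)
        with pytest.raises(gf.ConfigurationError):
            tm.sample_architecture(gmap, founders, 0.5, seed=5)


class TestPhenotype:
    def test_noiseless_limit(self):
        pop = _pop_with_dosages([[1, 1], [0, 1], [-1, 0]])
        arch = _manual_arch()  # error variance 1e-12
        real = tm.phenotype(pop, arch, seed=0)
        np.testing.assert_allclose(
            real.phenotypes, arch.intercept + real.genetic_values, atol=1e-5
        )

    def test_noise_variance_matches_sigma_e2(self, small_founders, small_arch):
        # one individual duplicated: Var(Y) across draws is σ_e²
        idx = np.zeros(100_000, dtype=int)
        pop = gf.HaplotypePopulation(
            haplotypes=small_founders.haplotypes[idx],
            gmap=small_founders.gmap,
            ids=np.arange(len(idx)),
            family=np.full(len(idx), -1),
            generation="founder",
        )
        real = tm.phenotype(pop, small_arch, seed=8)
        assert real.phenotypes.var() == pytest.approx(
            small_arch.error_variance, rel=0.02
        )

    def test_founder_heritability_near_target(self, small_founders, small_arch):
        real = tm.phenotype(small_founders, small_arch, seed=9)
        h2 = real.genetic_values.var() / real.phenotypes.var()
        assert 0.5 < h2 < 0.75  # n=60: wide sampling band

    def test_regression_of_y_on_g_has_unit_slope(self, small_founders, small_arch):
        real = tm.phenotype(small_founders, small_arch, seed=10)
        slope = np.polyfit(real.genetic_values, real.phenotypes, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.35)
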