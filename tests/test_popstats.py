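"""Diversity and differentiation statistics from dosages."""

import itertools

import numpy as np
import pytest

from restogen.formats import DosageMatrix
from restogen.popstats import (
    HET_WINDOW,
    expected_het,
    fis,
    fst_matrix,
    hudson_fst,
    observed_het,
    unit_allele_freqs,
    diversity_table,
)
from restogen.synthetic_data import SimConfig, simulate_source_frequencies, simulate_herds


def matrix_from(dosage, units):
    dosage = np.asarray(dosage, dtype=float)
    ids = [f"i{i}" for i in range(dosage.shape[0])]
    return DosageMatrix(ids, [f"l{j}" for j in range(dosage.shape[1])],
                        dict(zip(ids, units)), dosage)


def hudson_single_locus(p1, p2, n1, n2):
    """Independent single-locus implementation of Hudson's estimator."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num / den


class TestFrequenciesAndHet:
    def test_allele_freq_simple(self):
        m = matrix_from([[0], [1], [2]], ["U"] * 3)
        assert unit_allele_freqs(m).loc["U", "l0"] == 0.5

    def test_allele_freq_fixed(self):
        m = matrix_from([[2], [2]], ["U"] * 2)
        assert unit_allele_freqs(m).loc["U", "l0"] == 1.0

    def test_empty_unit_errors(self):
        m = matrix_from([[1]], ["U"])
        with pytest.raises(ValueError):
            unit_allele_freqs(m, units=["V"])

    def test_expected_het_half(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], (3, 1)).T  # p = 0.5 at all loci
        m = matrix_from(d, ["U"] * 4)
        assert expected_het(m, "U", min_n=4) == pytest.approx(0.5)

    def test_monomorphic_contributes_zero(self):
        d = np.column_stack([np.zeros(5), [0, 1, 1, 2, 0]])
        m = matrix_from(d, ["U"] * 5)
        p = 4 / 10
        assert expected_het(m, "U") == pytest.approx((0 + 2 * p * (1 - p)) / 2)

    def test_observed_het_window(self):
        d = np.array([[1.0], [0.9], [1.1], [0.85], [1.15]])
        m = matrix_from(d, ["U"] * 5)
        # inclusive endpoints: 1.0, 0.9 and 1.1 count; 0.85 and 1.15 do not
        assert observed_het(m, "U") == pytest.approx(3 / 5)

    def test_observed_het_zero_for_homozygotes(self):
        d = np.tile([0.0, 2.0], (5, 3))[:, :3]
        m = matrix_from(d, ["U"] * 5)
        assert observed_het(m, "U") == 0.0

    def test_min_individuals_enforced(self):
        m = matrix_from(np.ones((3, 2)), ["U"] * 3)
        with pytest.raises(ValueError, match=">= 5"):
            expected_het(m, "U")


class TestFis:
    @pytest.mark.parametrize("he,ho,expect", [
        (0.177, 0.154, 0.130),   # published unit 271 (prints 0.131)
        (0.2, 0.2, 0.0),
        (0.2, 0.0, 1.0),
    ])
    def test_values(self, he, ho, expect):
        assert fis(he, ho) == pytest.approx(expect, abs=5e-4)

    def test_undefined_when_he_zero(self):
        assert np.isnan(fis(0.0, 0.0))

    def test_identity_end_to_end(self):
        rng = np.random.default_rng(3)
        d = np.round(rng.uniform(0, 2, (8, 50)), 2)
        m = matrix_from(d, ["U"] * 8)
        rec = diversity_table(m, units=["U"])[0]
        assert abs(rec.f_is - (1 - rec.h_o / rec.h_e)) < 1e-9


class TestHudsonFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(0)
        geno = rng.binomial(2, 0.4, size=(400, 50)).astype(float)
        m = matrix_from(geno, ["A"] * 200 + ["B"] * 200)
        assert abs(hudson_fst(m, "A", "B")) < 0.01

    def test_fixed_difference_is_one(self):
        d = np.vstack([np.zeros((20, 5)), np.full((20, 5), 2.0)])
        m = matrix_from(d, ["A"] * 20 + ["B"] * 20)
        assert hudson_fst(m, "A", "B") == pytest.approx(1.0, abs=1e-9)

    def test_matches_single_locus_oracle(self):
        # 10 diploids per unit, one locus: p1 = 0.5, p2 = 0.25 (n = 20 copies)
        a = np.array([0, 0, 1, 1, 1, 1, 1, 1, 2, 2], dtype=float)
        b = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=float)
        m = matrix_from(np.concatenate([a, b])[:, None], ["A"] * 10 + ["B"] * 10)
        expect = hudson_single_locus(0.5, 0.25, 20, 20)
        assert hudson_fst(m, "A", "B") == pytest.approx(expect, abs=1e-12)

    def test_multi_locus_equals_manual_ratio_of_sums(self):
        rng = np.random.default_rng(7)
        geno = rng.binomial(2, rng.uniform(0.1, 0.9, 8), size=(20, 8)).astype(float)
        units = ["A"] * 10 + ["B"] * 10
        m = matrix_from(geno, units)
        p1 = geno[:10].mean(axis=0) / 2
        p2 = geno[10:].mean(axis=0) / 2
        nums, dens = [], []
        for j in range(8):
            den = p1[j] * (1 - p2[j]) + p2[j] * (1 - p1[j])
            if den > 0:
                nums.append((p1[j] - p2[j]) ** 2
                            - p1[j] * (1 - p1[j]) / 19 - p2[j] * (1 - p2[j]) / 19)
                dens.append(den)
        assert hudson_fst(m, "A", "B") == pytest.approx(sum(nums) / sum(dens), abs=1e-12)

    def test_estimator_unbiased_under_generative_dual(self):
        # Hudson F_ST on Balding–Nichols pairs recovers configured drift
        cfg = SimConfig(n_sources=2, F=0.07, n_loci=5000, sample_size=30, seed=13)
        _, freqs = simulate_source_frequencies(cfg)
        truth = simulate_herds(freqs, cfg)
        m = DosageMatrix(truth.individual_ids,
                         [f"l{j}" for j in range(cfg.n_loci)],
                         truth.unit_of, truth.genotypes.astype(float))
        assert abs(hudson_fst(m, "S1", "S2") - 0.07) < 0.015


class TestFstMatrix:
    def test_single_unit(self):
        m = matrix_from(np.random.default_rng(1).binomial(2, 0.5, (6, 10)).astype(float),
                        ["U"] * 6)
        pm = fst_matrix(m)
        assert pm.units == ["U"]
        assert pm.values.shape == (1, 1) and pm.values[0, 0] == 0

    def test_symmetry_and_order_invariance(self):
        cfg = SimConfig(n_sources=3, F=[0.05, 0.07, 0.09], n_loci=1500,
                        sample_size=12, seed=17)
        _, freqs = simulate_source_frequencies(cfg)
        truth = simulate_herds(freqs, cfg)
        m = DosageMatrix(truth.individual_ids,
                         [f"l{j}" for j in range(cfg.n_loci)],
                         truth.unit_of, truth.genotypes.astype(float))
        pm = fst_matrix(m, units=["S1", "S2", "S3"])
        pm_rev = fst_matrix(m, units=["S3", "S2", "S1"])
        np.testing.assert_allclose(pm.values, pm.values.T)
        assert np.diag(pm.values).sum() == 0
        for a, b in itertools.combinations(["S1", "S2", "S3"], 2):
            assert pm.value(a, b) == pm_rev.value(a, b)

    def test_pairwise_tracks_mean_drift(self):
        # between-herd F_ST approximates the mean of the two drift levels
        cfg = SimConfig(n_sources=2, F=[0.04, 0.1], n_loci=5000,
                        sample_size=30, seed=19)
        _, freqs = simulate_source_frequencies(cfg)
        truth = simulate_herds(freqs, cfg)
        m = DosageMatrix(truth.individual_ids,
                         [f"l{j}" for j in range(cfg.n_loci)],
                         truth.unit_of, truth.genotypes.astype(float))
        assert abs(hudson_fst(m, "S1", "S2") - 0.07) < 0.015
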