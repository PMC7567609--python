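"""Tests for energy matrices, logos, and MCMC inference."""

import itertools

import numpy as np
import pytest

from regfoot.matrix import (
    EnergyMatrix,
    estimate_matrix_ols,
    infer_matrix,
    matrix_pearson,
    matrix_to_logo,
    predict_energy,
    rank_mi_objective,
)
from regfoot.seqs import encode_many
from regfoot.synth import assign_barcodes, generate_variants, sample_reads, simulate_expression

from conftest import make_site_template, make_counts, variant_read_totals


class TestPredictEnergy:
    def test_wildtype_zero_gauge_scores_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 4))
        m = EnergyMatrix(vals).to_wildtype_zero("ACGTAC")
        assert predict_energy("ACGTAC", m) == pytest.approx(0.0, abs=1e-12)

    def test_all_64_sequences_match_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        m = EnergyMatrix(rng.normal(size=(3, 4)))
        for combo in itertools.product("ACGT", repeat=3):
            seq = "".join(combo)
            expected = sum(m.values[i, "ACGT".index(b)] for i, b in enumerate(seq))
            assert predict_energy(seq, m) == pytest.approx(expected, abs=1e-12)

    def test_single_substitution_linearity(self):
        rng = np.random.default_rng(2)
        m = EnergyMatrix(rng.normal(size=(4, 4)))
        base = predict_energy("ACGT", m)
        mutated = predict_energy("AGGT", m)
        assert mutated - base == pytest.approx(m.values[1, 2] - m.values[1, 1], abs=1e-12)

    def test_alphabet_violation(self):
        m = EnergyMatrix(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="invalid base"):
            predict_energy("ANT", m)


class TestGauge:
    def test_wildtype_zero_idempotent(self):
        rng = np.random.default_rng(3)
        m = EnergyMatrix(rng.normal(size=(5, 4))).to_wildtype_zero("ACGTA")
        again = m.to_wildtype_zero()
        assert np.allclose(m.values, again.values)

    def test_energy_differences_gauge_independent(self):
        rng = np.random.default_rng(4)
        m = EnergyMatrix(rng.normal(size=(4, 4)))
        diff_raw = predict_energy("ACGT", m) - predict_energy("TGCA", m)
        mc = m.to_mean_centered()
        wz = m.to_wildtype_zero("ACGT")
        assert predict_energy("ACGT", mc) - predict_energy("TGCA", mc) == pytest.approx(diff_raw)
        assert predict_energy("ACGT", wz) - predict_energy("TGCA", wz) == pytest.approx(diff_raw)


class TestMatrixPearson:
    def test_self_is_one(self):
        m = EnergyMatrix(np.random.default_rng(5).normal(size=(8, 4)))
        assert matrix_pearson(m, m) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        m = EnergyMatrix(np.random.default_rng(6).normal(size=(8, 4)))
        neg = EnergyMatrix(-m.values)
        assert matrix_pearson(m, neg) == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(7)
        a = EnergyMatrix(rng.normal(size=(6, 4)))
        b = EnergyMatrix(rng.normal(size=(6, 4)))
        xa = (a.values - a.values.mean()).ravel()
        xb = (b.values - b.values.mean()).ravel()
        expected = (xa @ xb) / np.sqrt((xa**2).sum() * (xb**2).sum())
        assert matrix_pearson(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        flat = EnergyMatrix(np.ones((4, 4)))
        other = EnergyMatrix(np.random.default_rng(8).normal(size=(4, 4)))
        with pytest.raises(ValueError, match="zero variance"):
            matrix_pearson(flat, other)


class TestLogo:
    def test_flat_column_uniform_zero_height(self):
        logo = matrix_to_logo(EnergyMatrix(np.zeros((3, 4))))
        assert np.allclose(logo.probs, 0.25)
        assert np.allclose(logo.heights, 0.0)

    def test_strong_preference_approaches_two_bits(self):
        vals = np.zeros((1, 4))
        vals[0, 1:] = 50.0  # all non-A bases heavily penalized
        logo = matrix_to_logo(EnergyMatrix(vals))
        assert logo.info_bits[0] == pytest.approx(2.0, abs=1e-10)
        assert logo.probs[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_probs_match_softmax_oracle(self):
        col = np.array([[0.3, -1.2, 0.8, 0.0]])
        logo = matrix_to_logo(EnergyMatrix(col), scale_factor=1.7)
        w = np.exp(-1.7 * col[0])
        assert np.allclose(logo.probs[0], w / w.sum(), atol=1e-12)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(9)
        logo = matrix_to_logo(EnergyMatrix(rng.normal(size=(10, 4))))
        assert np.allclose(logo.probs.sum(axis=1), 1.0)


class TestObjective:
    def test_affine_invariance(self):
        # MI depends only on the rank order of energies
        rng = np.random.default_rng(10)
        energies = rng.normal(size=500)
        dna = rng.integers(1, 50, size=500).astype(float)
        mrna = rng.integers(1, 50, size=500).astype(float)
        base = rank_mi_objective(energies, dna, mrna)
        scaled = rank_mi_objective(3.7 * energies + 11.0, dna, mrna)
        assert scaled == pytest.approx(base, abs=1e-14)

    def test_shuffling_sequences_invariant(self):
        rng = np.random.default_rng(11)
        energies = rng.normal(size=300)
        dna = rng.integers(1, 50, size=300).astype(float)
        mrna = rng.integers(1, 50, size=300).astype(float)
        base = rank_mi_objective(energies, dna, mrna)
        perm = rng.permutation(300)
        assert rank_mi_objective(energies[perm], dna[perm], mrna[perm]) == pytest.approx(
            base, abs=1e-14
        )


class TestInferMatrix:
    def test_recovery_smoke(self):
        # short chain on a strong site: inferred pattern correlates with truth
        template, true_m = make_site_template(seed=100)
        library, counts = make_counts(template, seed=0)
        dna, mrna = variant_read_totals(library, counts)
        start, end = template.planted_sites[0].interval
        seqs = [v[start:end] for v in library.variants]
        inferred, diag = infer_matrix(
            seqs, dna, mrna, wildtype=template.wildtype_seq[start:end],
            n_steps=4000, seed=0,
        )
        r = matrix_pearson(inferred.to_mean_centered(), true_m.to_mean_centered())
        assert r > 0.8
        assert 0.0 < diag["acceptance_rate"] < 1.0
        assert inferred.gauge == "wildtype-zero"

    def test_no_signal_indistinguishable_from_permuted_null(self):
        # expression independent of the region: best objective comparable to
        # permuted-label chains
        template, _ = make_site_template(seed=101)
        library, counts = make_counts(template, seed=1, n_variants=400, depth=20_000)
        dna, mrna = variant_read_totals(library, counts)
        # pick a neutral region far from the planted site (site is at 70:78)
        seqs = [v[10:18] for v in library.variants]
        wt = template.wildtype_seq[10:18]
        _, diag = infer_matrix(seqs, dna, mrna, wildtype=wt, n_steps=2000, seed=2)
        rng = np.random.default_rng(3)
        null_best = []
        for k in range(3):
            perm = rng.permutation(len(seqs))
            _, d = infer_matrix(
                [seqs[i] for i in perm], dna, mrna, wildtype=wt, n_steps=2000, seed=4 + k
            )
            null_best.append(d["best_objective"])
        assert diag["best_objective"] < 3 * max(null_best)

    def test_validation_errors(self):
        template, _ = make_site_template(seed=102)
        library, counts = make_counts(template, seed=2, n_variants=150, depth=5000)
        dna, mrna = variant_read_totals(library, counts)
        seqs = [v[70:78] for v in library.variants]
        wt = template.wildtype_seq[70:78]
        with pytest.raises(ValueError, match="too short"):
            infer_matrix([s[:3] for s in seqs], dna, mrna, wildtype=wt[:3], n_steps=100)
        with pytest.raises(ValueError, match="burn-in"):
            infer_matrix(seqs, dna, mrna, wildtype=wt, n_steps=1, burn_in_frac=1.0)
        with pytest.raises(ValueError, match="nonzero reads"):
            infer_matrix(seqs, np.zeros_like(dna), np.zeros_like(mrna), wildtype=wt)


class TestEstimateMatrixOls:
    def test_recovers_planted_pattern(self):
        template, true_m = make_site_template(seed=103)
        library, counts = make_counts(template, seed=3)
        dna, mrna = variant_read_totals(library, counts)
        start, end = template.planted_sites[0].interval
        seqs = [v[start:end] for v in library.variants]
        ols = estimate_matrix_ols(seqs, dna, mrna, template.wildtype_seq[start:end])
        # repressor under the activator sign convention: anti-correlated
        r = matrix_pearson(ols.to_mean_centered(), true_m.to_mean_centered())
        assert abs(r) > 0.85
        assert ols.gauge == "wildtype-zero"
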