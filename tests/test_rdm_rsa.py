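"""RDM construction, searchlight definition, RDM regression, group stats."""

import numpy as np
import pytest

from bmrsa.rdm import (ATTRIBUTES, N_PAIRS, RDM, neural_rdm, read_rdm_csv,
                       theoretical_rdms, write_rdm_csv)
from bmrsa.rsa import (SearchlightSpec, define_searchlights, fisher_z, group_rsa,
                       one_sample_t, regress_rdm, searchlight_rsa, RSAMap)
from bmrsa.simulate import STIMULUS_LABELS


class TestTheoreticalRDMs:
    def test_between_within_pair_counts(self, theo_rdms):
        for rdm in theo_rdms.values():
            v = rdm.vector()
            assert v.sum() == 16          # between-category pairs
            assert (v == 0).sum() == 12   # within-category pairs

    def test_pairwise_correlation_minus_one_sixth(self, theo_rdms):
        # oracle: direct enumeration over the 28 pairs
        vecs = [r.vector() for r in theo_rdms.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(vecs[i], vecs[j])[0, 1]
                assert r == pytest.approx(-1.0 / 6.0, abs=1e-12)

    def test_category_relabeling_leaves_rdm_unchanged(self):
        swapped = [(l.facing, {"female": "male", "male": "female"}[l.gender],
                    l.emotion) for l in STIMULUS_LABELS]
        a = theoretical_rdms(STIMULUS_LABELS)["gender"].values
        b = theoretical_rdms(swapped)["gender"].values
        np.testing.assert_array_equal(a, b)

    def test_unbalanced_labels_rejected(self):
        labels = [(f, "female", e) for f in ("left", "right")
                  for e in ("happy", "sad")] * 2
        with pytest.raises(ValueError):
            theoretical_rdms(labels)


class TestNeuralRDM:
    def test_identical_patterns_zero_dissimilarity(self):
        rng = np.random.default_rng(0)
        p = rng.random(30)
        patterns = np.vstack([p, p, rng.random((6, 30))])
        assert neural_rdm(patterns).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_pattern_dissimilarity_two(self):
        rng = np.random.default_rng(1)
        p = rng.random(30)
        patterns = np.vstack([p, -p, rng.random((6, 30))])
        assert neural_rdm(patterns).values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_centered_orthogonal_patterns_dissimilarity_one(self):
        # orthogonalize within the zero-sum subspace: patterns stay centered
        rng = np.random.default_rng(2)
        x = rng.random((8, 32))
        xc = x - x.mean(axis=1, keepdims=True)
        patterns = np.linalg.qr(xc.T)[0].T[:8]
        r = neural_rdm(patterns)
        np.testing.assert_allclose(r.vector(), 1.0, atol=1e-10)

    def test_constant_pattern_rejected(self):
        patterns = np.random.default_rng(3).random((8, 20))
        patterns[4] = 2.5
        with pytest.raises(ValueError, match="constant"):
            neural_rdm(patterns)

    def test_voxel_permutation_invariance(self):
        rng = np.random.default_rng(4)
        patterns = rng.random((8, 40))
        perm = rng.permutation(40)
        np.testing.assert_allclose(neural_rdm(patterns).values,
                                   neural_rdm(patterns[:, perm]).values,
                                   atol=1e-12)

    def test_rdm_csv_roundtrip(self, tmp_path, theo_rdms):
        path = tmp_path / "rdm.csv"
        write_rdm_csv(theo_rdms["facing"], path)
        back = read_rdm_csv(path, kind="theoretical")
        np.testing.assert_allclose(back.values, theo_rdms["facing"].values)


class TestSearchlights:
    def test_neighborhoods_have_k_members_including_center(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        sl = define_searchlights(mask, SearchlightSpec(k=20))
        assert sl.neighbors.shape == (216, 20)
        for i in range(0, 216, 37):
            assert i in sl.neighbors[i]

    def test_matches_brute_force_k_nearest_with_tie_breaking(self):
        rng = np.random.default_rng(5)
        mask = rng.random((10, 10, 10)) > 0.3
        k = 25
        sl = define_searchlights(mask, SearchlightSpec(k=k))
        coords = np.argwhere(mask)
        for i in rng.choice(len(coords), size=15, replace=False):
            d2 = np.sum((coords - coords[i]) ** 2, axis=1)
            order = np.lexsort((np.arange(len(coords)), d2))
            np.testing.assert_array_equal(np.sort(sl.neighbors[i]),
                                          np.sort(order[:k]))

    def test_k_larger_than_mask_rejected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2, :2, :2] = True
        with pytest.raises(ValueError, match="exceeds mask size"):
            define_searchlights(mask, SearchlightSpec(k=20))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k"):
            SearchlightSpec(k=1)


class TestRegressRDM:
    def _random_instance(self, rng):
        X = rng.standard_normal((4, N_PAIRS))
        y = rng.standard_normal(N_PAIRS)
        return y, X

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            y, X = self._random_instance(rng)
            beta = regress_rdm(y, X)
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            ys = (y - y.mean()) / y.std()
            oracle = np.linalg.solve(Xs @ Xs.T, Xs @ ys)
            np.testing.assert_allclose(beta, oracle, atol=1e-8)

    def test_recovers_indicator_coefficient_for_orthogonal_predictors(self):
        rng = np.random.default_rng(7)
        Q = np.linalg.qr(rng.standard_normal((N_PAIRS, 4)))[0].T
        Q = Q - Q.mean(axis=1, keepdims=True)  # orthogonalize then center
        Q = np.linalg.qr((Q - Q.mean(1, keepdims=True)).T)[0].T
        beta = regress_rdm(Q[2], Q)
        expected = np.zeros(4)
        expected[2] = 1.0
        np.testing.assert_allclose(beta, expected, atol=1e-8)

    def test_pure_noise_has_zero_mean_coefficients(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, N_PAIRS))
        betas = np.stack([regress_rdm(rng.standard_normal(N_PAIRS), X)
                          for _ in range(1000)])
        assert np.all(np.abs(betas.mean(axis=0)) < 0.02)

    def test_invariant_to_affine_rescaling_of_y(self):
        rng = np.random.default_rng(9)
        y, X = self._random_instance(rng)
        np.testing.assert_allclose(regress_rdm(y, X),
                                   regress_rdm(-3.0 * y + 7.0, X) * -1.0,
                                   atol=1e-10)

    def test_collinear_predictors_rejected_with_condition_number(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((4, N_PAIRS))
        X[3] = 2.0 * X[1] + 0.5
        with pytest.raises(ValueError, match="condition number"):
            regress_rdm(rng.standard_normal(N_PAIRS), X)

    def test_zero_variance_inputs_rejected(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((4, N_PAIRS))
        with pytest.raises(ValueError, match="zero-variance"):
            regress_rdm(np.ones(N_PAIRS), X)
        X[0] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            regress_rdm(rng.standard_normal(N_PAIRS), X)


class TestSearchlightRSA:
    def test_identical_subjects_identical_maps(self, small_glm, theo_rdms,
                                               v1_model_rdm, small_searchlights):
        model = dict(theo_rdms)
        model["v1"] = v1_model_rdm
        t = small_glm[0].tmaps
        a = searchlight_rsa(t, model, small_searchlights)
        b = searchlight_rsa(t, model, small_searchlights)
        np.testing.assert_array_equal(a.coefs, b.coefs)

    def test_planted_roi_coefficients_elevated(self, small_group, small_glm,
                                               theo_rdms, v1_model_rdm,
                                               small_searchlights):
        _, effects, group = small_group
        model = dict(theo_rdms)
        model["v1"] = v1_model_rdm
        maps = [searchlight_rsa(g.tmaps, model, small_searchlights)
                for g in small_glm]
        mean = np.mean([m.coefs for m in maps], axis=0)
        mask = group[0].mask
        for i, attr in enumerate(ATTRIBUTES):
            roi_v = effects.roi_masks[attr][mask]
            assert mean[roi_v, i].mean() > mean[~roi_v, i].mean() + 0.1


class TestGroupRSA:
    def test_fisher_transform_reference_values(self):
        assert fisher_z(np.array(0.0)) == 0.0
        assert fisher_z(np.array(0.5)) == pytest.approx(0.5493, abs=1e-4)

    def test_fisher_clipped_near_unity(self):
        assert np.isfinite(fisher_z(np.array(1.0)))

    def test_zero_variance_voxels_capped(self):
        maps = [RSAMap(coefs=np.full((5, 2), 0.3), predictor_names=("a", "b"))
                for _ in range(4)]
        out = group_rsa(maps)
        np.testing.assert_array_equal(out["t"], 100.0)
        assert np.all(out["p"] < 1e-4)

    def test_group_t_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(12)
        z = rng.standard_normal((10, 50))
        t, p = one_sample_t(z)
        ref_t, ref_p = stats.ttest_1samp(z, 0.0, alternative="greater")
        np.testing.assert_allclose(t, ref_t, atol=1e-10)
        np.testing.assert_allclose(p, ref_p, atol=1e-10)

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="2 subjects"):
            group_rsa(np.zeros((1, 5, 2)))
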