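"""Mixture + MRF inference: oracle equivalence, ICM behaviour, PPM rules."""

import numpy as np
import pytest

from phmri.mrf_ppm import (
    ACT,
    DEACT,
    NULL,
    SIGMA_FLOOR,
    MixtureFit,
    compute_ppm,
    icm_fit,
    init_mixture,
    neighbor_prior,
    threshold_ppm,
)


def gmm_hard_em_oracle(z, init_means, init_sds, init_weights, init_labels, max_sweeps=50):
    """Independent non-spatial hard-assignment GMM (classification EM).

    Same update rules as the spatial model with the coupling switched off:
    M-step from the initial assignment, then alternate argmax assignment and
    M-step until labels stop changing. Returns (labels, responsibilities).
    """
    from scipy import stats as sps

    means = np.array(init_means, dtype=float)
    sds = np.array(init_sds, dtype=float)
    weights = np.array(init_weights, dtype=float)
    active = np.ones(3, dtype=bool)
    labels = np.array(init_labels, dtype=int)

    def m_step():
        for k in range(3):
            if not active[k]:
                continue
            members = z[labels == k]
            if members.size == 0:
                active[k] = False
                weights[k] = 0.0
                continue
            means[k] = members.mean()
            sds[k] = max(members.std(), SIGMA_FLOOR)
            weights[k] = members.size / z.size
        weights[active] /= weights[active].sum()
        weights[~active] = 0.0

    def scores():
        s = np.full((z.size, 3), -np.inf)
        for k in range(3):
            if active[k]:
                s[:, k] = np.log(weights[k]) + sps.norm.logpdf(z, means[k], sds[k])
        return s

    m_step()
    for _ in range(max_sweeps):
        new = np.argmax(scores(), axis=1)
        changed = (new != labels).any()
        labels = new
        m_step()
        if not changed:
            break
    # identifiability guard: a class within the universal threshold
    # sqrt(2 ln V) of the null mean is the null tail, not a separate mode
    merged = False
    sep = np.sqrt(2.0 * np.log(z.size)) * sds[NULL]
    for k in (DEACT, ACT):
        if active[k] and abs(means[k] - means[NULL]) < sep:
            labels[labels == k] = NULL
            active[k] = False
            weights[k] = 0.0
            merged = True
    if merged:
        members = z[labels == NULL]
        means[NULL] = members.mean()
        sds[NULL] = max(members.std(), SIGMA_FLOOR)
        weights[NULL] = members.size / z.size
        weights[active] /= weights[active].sum()
    s = scores()
    s -= s.max(axis=1, keepdims=True)
    resp = np.exp(s)
    resp /= resp.sum(axis=1, keepdims=True)
    return labels, resp, means, sds, weights


def _manual_fit(mask, labels, means, sds, weights, beta, active=None):
    return MixtureFit(
        means=np.array(means, float),
        sds=np.array(sds, float),
        weights=np.array(weights, float),
        mrf_beta=beta,
        labels=labels,
        mask=mask,
        active=np.ones(3, bool) if active is None else np.array(active, bool),
    )


class TestInitMixture:
    def test_null_class_centred_on_standard_normal(self, rng):
        z = rng.normal(size=(25, 25, 16))
        fit = init_mixture(z, np.ones(z.shape, bool))
        assert abs(fit.means[NULL]) < 0.1
        assert fit.means[DEACT] < fit.means[NULL] < fit.means[ACT]

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            init_mixture(np.full((10, 10, 5), 2.0), np.ones((10, 10, 5), bool))

    def test_tiny_mask_rejected(self, rng):
        mask = np.zeros((10, 10, 5), bool)
        mask[:2, :2, :2] = True
        with pytest.raises(ValueError, match="50"):
            init_mixture(rng.normal(size=(10, 10, 5)), mask)

    def test_activation_tail_assigned_to_activated_class(self, rng):
        z = rng.normal(size=(20, 20, 10))
        z[:4, :4, :4] = 5.0 + 0.1 * rng.normal(size=(4, 4, 4))
        fit = init_mixture(z, np.ones(z.shape, bool))
        assert (fit.labels == ACT).sum() >= 64


class TestNeighborPrior:
    def test_beta_zero_reduces_to_global_mixing(self, rng):
        mask = np.ones((6, 6, 4), bool)
        labels = rng.integers(0, 3, size=mask.shape).astype(np.int8)
        fit = _manual_fit(mask, labels, [-3, 0, 3], [1, 1, 1], [0.2, 0.5, 0.3], beta=0.0)
        prior = neighbor_prior(fit)
        for k, w in enumerate([0.2, 0.5, 0.3]):
            np.testing.assert_allclose(prior[k][mask], w, atol=1e-12)

    def test_unanimous_neighbors_softmax_value(self):
        # all 6 neighbors activated, beta = 1, uniform mixing:
        # p_act = e^6 / (e^6 + 2)
        mask = np.ones((3, 3, 3), bool)
        labels = np.full((3, 3, 3), ACT, dtype=np.int8)
        fit = _manual_fit(mask, labels, [-3, 0, 3], [1, 1, 1], [1 / 3] * 3, beta=1.0)
        prior = neighbor_prior(fit)
        expected = np.exp(6) / (np.exp(6) + 2)
        assert prior[ACT][1, 1, 1] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.99507, abs=5e-5)

    def test_split_neighbors_tie(self):
        # centre voxel: 3 neighbors null, 3 activated -> those classes tie
        mask = np.ones((3, 3, 3), bool)
        labels = np.full((3, 3, 3), NULL, dtype=np.int8)
        labels[0, 1, 1] = labels[2, 1, 1] = labels[1, 0, 1] = ACT
        fit = _manual_fit(mask, labels, [-3, 0, 3], [1, 1, 1], [1 / 3] * 3, beta=1.7)
        prior = neighbor_prior(fit)
        assert prior[ACT][1, 1, 1] == pytest.approx(prior[NULL][1, 1, 1], abs=1e-12)


class TestIcmAgainstPlainGmm:
    def test_beta_zero_matches_independent_oracle(self, rng):
        """With the spatial coupling pinned at zero, labels and PPMs must
        equal the non-spatial hard-EM mixture to machine precision."""
        z = rng.normal(size=(15, 15, 8))
        z[2:6, 2:6, 2:5] += 5.0
        z[9:13, 9:13, 3:6] -= 5.0
        mask = np.ones(z.shape, bool)
        init = init_mixture(z, mask)
        init_labels = init.labels[mask].copy()
        fit = icm_fit(z, mask, init=init, mrf_beta=0.0)

        labels_o, resp_o, means_o, sds_o, weights_o = gmm_hard_em_oracle(
            z[mask], init.means.copy(), init.sds.copy(), init.weights.copy(), init_labels
        )
        np.testing.assert_array_equal(fit.labels[mask], labels_o)
        np.testing.assert_allclose(fit.means, means_o, atol=1e-12)
        np.testing.assert_allclose(fit.sds, sds_o, atol=1e-12)
        np.testing.assert_allclose(fit.weights, weights_o, atol=1e-12)
        np.testing.assert_allclose(fit.ppm_act[mask], resp_o[:, ACT], atol=1e-12)
        np.testing.assert_allclose(fit.ppm_deact[mask], resp_o[:, DEACT], atol=1e-12)

    def test_objective_nondecreasing_each_sweep(self, rng):
        z = rng.normal(size=(14, 14, 8))
        z[3:7, 3:7, 2:6] += 6.0
        fit = icm_fit(z, np.ones(z.shape, bool))
        for rec in fit.objective_history:
            assert rec["post_labels"] >= rec["pre_labels"] - 1e-9


class TestIcmRecovery:
    def test_planted_blobs_recovered(self, rng):
        z = rng.normal(size=(20, 20, 10))
        blob = np.zeros(z.shape, bool)
        blob[3:8, 3:8, 3:7] = True
        blob[13:17, 12:17, 4:8] = True
        z[blob] = 6.0 + rng.normal(scale=0.5, size=blob.sum())
        fit = icm_fit(z, np.ones(z.shape, bool))
        detected = fit.labels == ACT
        dice = 2 * (detected & blob).sum() / (detected.sum() + blob.sum())
        assert dice >= 0.9

    def test_pure_null_map_yields_almost_no_detections(self, rng):
        z = rng.normal(size=(20, 20, 10))
        mask = np.ones(z.shape, bool)
        with pytest.warns(RuntimeWarning):
            fit = icm_fit(z, mask)
        non_null = (fit.labels[mask] != NULL).mean()
        assert non_null < 0.005
        for k in (DEACT, ACT):
            assert (not fit.active[k]) or fit.weights[k] < 0.01 or (fit.labels[mask] == k).mean() < 0.005

    def test_negating_zmap_swaps_activation_and_deactivation(self, rng):
        z = rng.normal(size=(16, 16, 8))
        z[3:7, 3:7, 2:6] += 6.0
        mask = np.ones(z.shape, bool)
        fit_pos = icm_fit(z, mask)
        fit_neg = icm_fit(-z, mask)
        swap = {ACT: DEACT, NULL: NULL, DEACT: ACT, -1: -1}
        np.testing.assert_array_equal(
            fit_neg.labels, np.vectorize(swap.get)(fit_pos.labels)
        )
        np.testing.assert_allclose(fit_neg.ppm_deact, fit_pos.ppm_act, atol=1e-12)
        np.testing.assert_allclose(fit_neg.ppm_act, fit_pos.ppm_deact, atol=1e-12)

    def test_spatial_coupling_removes_isolated_detections(self, rng):
        """At beta = 2 the label field has fewer isolated single-voxel
        activations than at beta = 0, aggregated over replicates."""
        from scipy import ndimage

        def count_isolated(labels):
            act = labels == ACT
            lab, n = ndimage.label(act, structure=ndimage.generate_binary_structure(3, 1))
            sizes = ndimage.sum_labels(act, lab, index=range(1, n + 1))
            return int((np.asarray(sizes) == 1).sum())

        totals = {0.0: 0, 2.0: 0}
        for rep in range(20):
            rep_rng = np.random.default_rng(100 + rep)
            z = rep_rng.normal(size=(14, 14, 8))
            z[3:8, 3:8, 2:6] += 4.0
            mask = np.ones(z.shape, bool)
            for beta in totals:
                fit = icm_fit(z, mask, mrf_beta=beta)
                totals[beta] += count_isolated(fit.labels)
        assert totals[2.0] < totals[0.0]


class TestPpmRules:
    def test_equal_likelihood_tied_prior_gives_half(self):
        mask = np.ones((5, 5, 4), bool)
        labels = np.full(mask.shape, NULL, np.int8)
        fit = _manual_fit(
            mask, labels, [-1, 0, 1], [1, 1, 1], [0.5, 0.0, 0.5], beta=0.0,
            active=[True, False, True],
        )
        z = np.zeros(mask.shape)  # midway between the two surviving classes
        ppm_act, ppm_deact = compute_ppm(z, fit)
        np.testing.assert_allclose(ppm_act[mask], 0.5, atol=1e-12)
        np.testing.assert_allclose(ppm_deact[mask], 0.5, atol=1e-12)
        # the strict > 0.5 rule excludes exact halves
        assert not threshold_ppm(ppm_act).any()

    def test_dominant_voxel_near_certainty(self):
        mask = np.ones((3, 3, 3), bool)
        labels = np.full(mask.shape, ACT, np.int8)
        fit = _manual_fit(mask, labels, [-4, 0, 4], [1, 1, 0.1], [1 / 3] * 3, beta=1.0)
        z = np.full(mask.shape, 4.0)
        ppm_act, _ = compute_ppm(z, fit)
        assert ppm_act[1, 1, 1] > 0.99

    def test_threshold_is_strict_and_zero_threshold_keeps_support(self):
        ppm = np.array([[[0.0, 0.5, 0.5000001, 1.0]]])
        np.testing.assert_array_equal(threshold_ppm(ppm), [[[False, False, True, True]]])
        np.testing.assert_array_equal(threshold_ppm(ppm, 0.0), [[[False, True, True, True]]])
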