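"""Infusion EV construction, onset-uncertainty regressors, voxelwise GLM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phmri.infusion_glm import (
    assemble_design,
    build_infusion_ev,
    build_svd_onset_regressors,
    fit_voxelwise_glm,
    t_to_z,
)
from conftest import make_volume


class TestBuildInfusionEv:
    def test_piecewise_values(self):
        ev = build_infusion_ev(598, 2.5, time_origin_s=5.0)
        t = ev.times_s
        np.testing.assert_array_equal(ev.sampled_ev[t <= 300], 0.0)
        np.testing.assert_array_equal(ev.sampled_ev[t >= 780], 1.0)
        mid = (t > 300) & (t < 780)
        np.testing.assert_allclose(ev.sampled_ev[mid], (t[mid] - 300) / 480, rtol=1e-15)

    def test_breakpoints_exact(self):
        ev = build_infusion_ev(600, 2.5, time_origin_s=0.0)
        assert ev.sampled_ev[int(300 / 2.5)] == 0.0
        assert ev.sampled_ev[int(780 / 2.5)] == 1.0
        assert ev.sampled_ev[int(540 / 2.5)] == 0.5

    def test_dropped_volume_origin(self):
        # 2 dropped frames at TR 2.5 -> origin 5 s; frame 200 is t = 505 s
        ev = build_infusion_ev(598, 2.5, time_origin_s=5.0)
        assert ev.times_s[200] == pytest.approx(505.0)
        assert ev.sampled_ev[200] == pytest.approx((505 - 300) / 480)

    def test_scan_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_infusion_ev(10, 2.5)

    def test_monotone_within_unit_interval(self):
        ev = build_infusion_ev(598, 2.5, 5.0)
        assert np.all(np.diff(ev.sampled_ev) >= 0)
        assert ev.sampled_ev.min() == 0.0 and ev.sampled_ev.max() == 1.0


class TestSvdOnsetRegressors:
    def test_k_zero_empty(self):
        out = build_svd_onset_regressors(598, 2.5, 5.0, k=0)
        assert out.shape == (598, 0)

    @pytest.mark.parametrize("k", [1, 3])
    def test_orthonormal_and_orthogonal_to_ev(self, k):
        svd = build_svd_onset_regressors(598, 2.5, 5.0, k=k)
        ev = build_infusion_ev(598, 2.5, 5.0).sampled_ev
        np.testing.assert_allclose(svd.T @ svd, np.eye(k), atol=1e-10)
        assert np.max(np.abs(svd.T @ ev)) < 1e-10
        assert np.max(np.abs(svd.sum(axis=0))) < 1e-8  # orthogonal to intercept

    def test_first_component_dominates_residual_family(self):
        """Independent oracle: build the shifted-ramp family explicitly and
        check the top singular direction carries >= 80% of residual energy."""
        n, tr, t0 = 598, 2.5, 5.0
        times = t0 + tr * np.arange(n)
        shifts = np.arange(-60, 75, 15.0)
        family = np.column_stack(
            [np.clip((times - 300 - s) / 480.0, 0, 1) for s in shifts]
        )
        nominal = np.clip((times - 300) / 480.0, 0, 1)
        basis, _ = np.linalg.qr(np.column_stack([np.ones(n), nominal]))
        resid = family - basis @ (basis.T @ family)
        s = np.linalg.svd(resid, compute_uv=False)
        assert s[0] ** 2 / (s**2).sum() >= 0.80

    def test_k_exceeding_shifts_rejected(self):
        with pytest.raises(ValueError):
            build_svd_onset_regressors(598, 2.5, 5.0, onset_shifts_s=(-30.0, 30.0), k=2)


class TestAssembleDesign:
    def _ev(self, n=240):
        return build_infusion_ev(n, 2.5, 5.0)

    def test_duplicate_nuisance_reported(self, rng):
        tc = rng.normal(size=240)
        with pytest.raises(ValueError) as err:
            assemble_design(self._ev(), wm_tc=tc, csf_tc=tc)
        assert "wm" in str(err.value) and "csf" in str(err.value)

    def test_constant_nuisance_reported(self, rng):
        with pytest.raises(ValueError, match="wm"):
            assemble_design(self._ev(), wm_tc=np.full(240, 3.0), csf_tc=rng.normal(size=240))

    def test_valid_design_full_rank_and_named(self, rng):
        svd = build_svd_onset_regressors(240, 2.5, 5.0, k=2)
        d = assemble_design(self._ev(), svd, rng.normal(size=240), rng.normal(size=240))
        assert d.names == ["infusion_ev", "svd_1", "svd_2", "drift", "wm", "csf", "intercept"]
        assert np.linalg.matrix_rank(d.matrix) == len(d.names)
        assert d.column("drift").mean() == pytest.approx(0.0, abs=1e-12)


class TestTtoZ:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.integers(3, 500))
    def test_odd_and_bounded(self, t, dof):
        z = t_to_z(np.array([t, -t]), dof)
        assert z[0] == pytest.approx(-z[1], abs=1e-12)
        assert abs(z[0]) <= 8.0

    def test_monotone(self):
        t = np.linspace(-30, 30, 501)
        z = t_to_z(t, 12)
        assert np.all(np.diff(z) >= 0)

    def test_extreme_t_clipped_not_nan(self):
        z = t_to_z(np.array([1e6, -1e6]), 10)
        np.testing.assert_array_equal(z, [8.0, -8.0])


class TestFitVoxelwiseGlm:
    def _design(self, n=400, rng=None, k=2):
        ev = build_infusion_ev(n, 2.5, 5.0)
        svd = build_svd_onset_regressors(n, 2.5, 5.0, k=k)
        rng = rng or np.random.default_rng(0)
        return ev, assemble_design(ev, svd, rng.normal(size=n), rng.normal(size=n))

    def test_noiseless_amplitude_exact(self, rng):
        ev, design = self._design(rng=rng)
        y = 3.0 * design.column("infusion_ev") + 2.0
        vol = make_volume(np.tile(y, (2, 2, 1, 1)))
        mask = np.ones((2, 2, 1), dtype=bool)
        res = fit_voxelwise_glm(vol, design, mask)
        np.testing.assert_allclose(res.amplitude.data, 3.0, atol=1e-9)
        assert res.dof == vol.n_volumes - len(design.names)

    def test_amplitude_invariant_under_svd_augmentation(self, rng):
        """On data generated with the nominal EV, orthogonal onset regressors
        cannot change the fitted amplitude."""
        n = 400
        ev = build_infusion_ev(n, 2.5, 5.0)
        wm, csf = rng.normal(size=n), rng.normal(size=n)
        noise = rng.normal(size=n)
        y = 1.5 * ev.sampled_ev + 0.3 * noise + 5.0
        vol = make_volume(y.reshape(1, 1, 1, n))
        mask = np.ones((1, 1, 1), dtype=bool)
        amps = []
        for k in (0, 3):
            svd = build_svd_onset_regressors(n, 2.5, 5.0, k=k)
            design = assemble_design(ev, svd, wm, csf)
            amps.append(fit_voxelwise_glm(vol, design, mask).amplitude.data[0, 0, 0])
        # noise has a component in the svd span, so equality is not exact;
        # but on pure nominal-EV signal it is
        y0 = 1.5 * ev.sampled_ev + 5.0
        vol0 = make_volume(y0.reshape(1, 1, 1, n))
        a0 = []
        for k in (0, 3):
            svd = build_svd_onset_regressors(n, 2.5, 5.0, k=k)
            design = assemble_design(ev, svd, wm, csf)
            a0.append(fit_voxelwise_glm(vol0, design, mask).amplitude.data[0, 0, 0])
        assert a0[0] == pytest.approx(a0[1], abs=1e-10)
        assert a0[0] == pytest.approx(1.5, abs=1e-9)

    def test_perfect_fit_z_clipped(self, rng):
        ev, design = self._design(rng=rng)
        y = 2.0 * design.column("infusion_ev") + 1.0
        vol = make_volume(y.reshape(1, 1, 1, -1))
        mask = np.ones((1, 1, 1), dtype=bool)
        res = fit_voxelwise_glm(vol, design, mask)
        assert res.zstat.data[0, 0, 0] == 8.0

    def test_exactly_zero_series_warns(self, rng):
        ev, design = self._design(rng=rng)
        vol = make_volume(np.zeros((1, 1, 1, design.n_rows)))
        mask = np.ones((1, 1, 1), dtype=bool)
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            res = fit_voxelwise_glm(vol, design, mask)
        assert res.zstat.data[0, 0, 0] == 0.0

    def test_onset_jitter_bias_reduced_by_svd_regressors(self):
        """Deterministic check: with a +60 s true onset, the k=3 design
        recovers the amplitude with smaller error than the k=0 design."""
        n = 598
        times = 5.0 + 2.5 * np.arange(n)
        shifted = np.clip((times - 360) / 480.0, 0, 1)  # true onset +60 s
        ev = build_infusion_ev(n, 2.5, 5.0)
        rng = np.random.default_rng(1)
        wm, csf = rng.normal(size=n), rng.normal(size=n)
        vol = make_volume((1.0 * shifted).reshape(1, 1, 1, n))
        mask = np.ones((1, 1, 1), dtype=bool)
        err = {}
        for k in (0, 3):
            svd = build_svd_onset_regressors(n, 2.5, 5.0, k=k)
            design = assemble_design(ev, svd, wm, csf)
            amp = fit_voxelwise_glm(vol, design, mask).amplitude.data[0, 0, 0]
            err[k] = abs(amp - 1.0)
        assert err[3] < err[0]
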