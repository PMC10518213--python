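"""I-V construction, linear fits, conductance decomposition and the
difference/similarity analyses, against linear-algebra and Monte-Carlo
oracles."""
import numpy as np
import pytest

import synconduct as sc
from synconduct.conductance import (
    ConditioningWarning,
    IVSeries,
    build_iv_series,
    decompose_conductances,
    difference_conductance,
    fit_linear_iv,
    net_light_evoked,
    reconstruct_currents,
    timecourse_similarity,
)
from synconduct.synthetic import CellModel, DriveTraces, MgBlock, simulate_voltage_clamp

FS = 10_000.0
POTENTIALS = np.arange(-110.0, 51.0, 20.0)  # 9 holding potentials


def _vc_sweep(signal, v_hold, fs=FS):
    return sc.SweepRecord(
        "c", "voltage_clamp", fs, np.asarray(signal, dtype=float),
        holding_potential=v_hold, ljp_corrected=True,
    )


def _known_traces(n_bins=60):
    t = np.arange(n_bins) * 10.0
    g_exc = 0.5 + 0.4 * np.sin(t / 80.0)
    g_inh = 0.3 + 0.2 * np.cos(t / 100.0)
    g_nmda = 0.25 + 0.1 * np.sin(t / 60.0)
    return t, g_exc, g_inh, g_nmda


def _forward_iv(t, g_exc, g_inh, g_nmda, mg, potentials=POTENTIALS):
    I = (
        g_exc[:, None] * potentials[None, :]
        + g_inh[:, None] * (potentials[None, :] + 70.0)
        + g_nmda[:, None] * mg(potentials)[None, :] * potentials[None, :]
    )
    return IVSeries(
        time_grid_ms=t + 5.0,
        potentials_mv=potentials,
        currents_pa=I,
        n_sweeps_per_potential=np.ones(potentials.size, dtype=int),
    )


class TestNetLightEvoked:
    def test_constant_sweeps_give_zero_net(self):
        sweeps = [_vc_sweep(np.full(5000, -120.0), -60.0) for _ in range(3)]
        net = net_light_evoked(sweeps, (0.0, 0.3))
        np.testing.assert_allclose(net, 0.0)

    def test_known_conductance_step_recovered(self):
        """Forward-modeled G step: net trace equals G_step x (V - E)."""
        v = -60.0
        g = np.zeros(6000)
        g[3000:] = 1.5  # nS step after baseline window
        cell = CellModel(g_leak_ns=2.0)
        drive = DriveTraces(g, np.zeros_like(g), np.zeros_like(g), FS, {})
        sw = simulate_voltage_clamp(cell, drive, v)
        net = net_light_evoked([sw], (0.0, 0.3))
        np.testing.assert_allclose(net[3000:], 1.5 * v, rtol=1e-12)
        np.testing.assert_allclose(net[:3000], 0.0, atol=1e-12)

    def test_averaging_is_linear(self):
        rng = np.random.default_rng(0)
        a = _vc_sweep(rng.standard_normal(5000), -60.0)
        b = _vc_sweep(rng.standard_normal(5000), -60.0)
        both = net_light_evoked([a, b], (0.0, 0.3))
        each = 0.5 * (
            net_light_evoked([a], (0.0, 0.3)) + net_light_evoked([b], (0.0, 0.3))
        )
        np.testing.assert_allclose(both, each, atol=1e-12)

    def test_heterogeneous_holding_potentials_rejected(self):
        sweeps = [_vc_sweep(np.zeros(5000), -60.0), _vc_sweep(np.zeros(5000), -80.0)]
        with pytest.raises(ValueError):
            net_light_evoked(sweeps, (0.0, 0.3))


class TestBuildIvSeries:
    def test_nine_potentials_nine_points_per_bin(self):
        traces = {float(v): np.ones(1000) * v for v in POTENTIALS}
        iv = build_iv_series(traces, FS, 10.0)
        assert iv.currents_pa.shape == (10, 9)

    def test_identical_traces_identical_bins(self):
        tr = np.sin(np.arange(2000) / 100.0)
        iv = build_iv_series({-60.0: tr, 0.0: tr}, FS, 10.0)
        np.testing.assert_allclose(iv.currents_pa[:, 0], iv.currents_pa[:, 1])

    def test_linear_current_bin_mean_equals_midpoint(self):
        """Bin averaging of a linear-in-time current equals its value at
        the bin center (trapezoid identity)."""
        t = np.arange(1000) / FS
        tr = 100.0 * t
        iv = build_iv_series({-60.0: tr, 0.0: tr}, FS, 10.0)
        # midpoint of bin k is (k + 0.5) * 10 ms, minus half a sample
        expected = 100.0 * (iv.time_grid_ms * 1e-3 - 0.5 / FS)
        np.testing.assert_allclose(iv.currents_pa[:, 0], expected, rtol=1e-9)

    def test_fewer_than_two_potentials_rejected(self):
        with pytest.raises(ValueError):
            build_iv_series({-60.0: np.zeros(100)}, FS)


class TestFitLinearIv:
    def test_agonist_iv_parameters_recovered(self):
        """Points generated from 4.4 nS / +0.9 mV at -95..+65 mV in 20-mV
        steps refit to the generating values to 3 significant figures."""
        v = np.arange(-95.0, 66.0, 20.0)
        i = 4.4 * (v - 0.9)
        fit = fit_linear_iv(np.column_stack([v, i]))
        assert float(f"{fit.conductance_ns:.3g}") == pytest.approx(4.4)
        assert float(f"{fit.reversal_mv:.3g}") == pytest.approx(0.9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_relation_degenerate(self):
        fit = fit_linear_iv([(-60.0, 0.0), (0.0, 0.0)])
        assert fit.conductance_ns == 0.0
        assert np.isnan(fit.reversal_mv)
        assert fit.degenerate

    def test_identical_potentials_singular(self):
        with pytest.raises(ValueError):
            fit_linear_iv([(-60.0, 1.0), (-60.0, 2.0)])

    def test_slope_estimator_unbiased_under_noise(self):
        """1000 noisy refits (sigma = 5 pA): mean slope within 3 SE of
        the generating conductance."""
        rng = np.random.default_rng(2)
        v = np.arange(-95.0, 66.0, 20.0)
        slopes = []
        for _ in range(1000):
            i = 4.4 * (v - 0.9) + 5.0 * rng.standard_normal(v.size)
            slopes.append(fit_linear_iv(np.column_stack([v, i])).conductance_ns)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 4.4) < 3 * se


class TestDecomposeConductances:
    def test_zero_currents_zero_conductances(self):
        mg = MgBlock()
        iv = _forward_iv(*(lambda t: (t, 0 * t, 0 * t, 0 * t))(np.arange(10) * 10.0), mg)
        g = decompose_conductances(iv, mg_block=mg)
        np.testing.assert_allclose(g.g_exc_ns, 0.0, atol=1e-12)
        np.testing.assert_allclose(g.g_inh_ns, 0.0, atol=1e-12)
        np.testing.assert_allclose(g.g_nmda_ns, 0.0, atol=1e-12)

    def test_noise_free_exact_recovery(self):
        """decompose(forward(G)) is the identity to solver tolerance on a
        full-rank 9-potential design."""
        mg = MgBlock()
        t, ge, gi, gn = _known_traces()
        g = decompose_conductances(_forward_iv(t, ge, gi, gn, mg), mg_block=mg)
        np.testing.assert_allclose(g.g_exc_ns, ge, rtol=1e-10)
        np.testing.assert_allclose(g.g_inh_ns, gi, rtol=1e-10)
        np.testing.assert_allclose(g.g_nmda_ns, gn, rtol=1e-10)
        np.testing.assert_allclose(g.rmse_pa, 0.0, atol=1e-9)

    def test_scaling_equivariance(self):
        """Scaling all currents by c scales all conductances by c."""
        mg = MgBlock()
        t, ge, gi, gn = _known_traces(20)
        iv = _forward_iv(t, ge, gi, gn, mg)
        iv_scaled = IVSeries(
            iv.time_grid_ms, iv.potentials_mv, 3.0 * iv.currents_pa,
            iv.n_sweeps_per_potential,
        )
        g1 = decompose_conductances(iv, mg_block=mg)
        g2 = decompose_conductances(iv_scaled, mg_block=mg)
        np.testing.assert_allclose(g2.g_exc_ns, 3.0 * g1.g_exc_ns, rtol=1e-9)
        np.testing.assert_allclose(g2.g_nmda_ns, 3.0 * g1.g_nmda_ns, rtol=1e-9)

    def test_two_component_fit_matches_two_point_closed_form(self):
        """With NMDA off and two potentials, the per-bin solution equals
        the analytic two-equation solve for (G_exc, G_inh)."""
        ge_true, gi_true = 0.8, 0.3
        v = np.array([-90.0, -30.0])
        I = np.array([[ge_true * vv + gi_true * (vv + 70.0) for vv in v]])
        iv = IVSeries(np.array([5.0]), v, I, np.ones(2, dtype=int))
        g = decompose_conductances(iv, fit_nmda=False)
        # closed form: solve the 2x2 system directly
        A = np.array([[v[0], v[0] + 70.0], [v[1], v[1] + 70.0]])
        ge_cf, gi_cf = np.linalg.solve(A, I[0])
        assert g.g_exc_ns[0] == pytest.approx(ge_cf)
        assert g.g_inh_ns[0] == pytest.approx(gi_cf)
        assert ge_cf == pytest.approx(ge_true)

    def test_negative_conductances_permitted(self):
        """Suppression of baseline input fits as a negative conductance."""
        mg = MgBlock()
        t = np.arange(5) * 10.0
        ge = np.full(5, -0.4)  # below-baseline excitation (Off-phase)
        g = decompose_conductances(
            _forward_iv(t, ge, np.zeros(5), np.zeros(5), mg), mg_block=mg
        )
        np.testing.assert_allclose(g.g_exc_ns, -0.4, rtol=1e-9)

    def test_collinear_design_warns(self):
        """Potentials spanning only a depolarized range where B(V) ~ 1
        make the NMDA and linear columns nearly collinear."""
        mg = MgBlock()
        v = np.array([40.0, 45.0, 50.0])
        iv = IVSeries(
            np.array([5.0]), v, np.array([[1.0, 1.1, 1.2]]), np.ones(3, dtype=int)
        )
        with pytest.warns(ConditioningWarning):
            decompose_conductances(iv, mg_block=mg, condition_threshold=1e3)

    def test_too_few_potentials_rejected(self):
        iv = IVSeries(
            np.array([5.0]), np.array([-60.0, 0.0]), np.zeros((1, 2)),
            np.ones(2, dtype=int),
        )
        with pytest.raises(ValueError):
            decompose_conductances(iv, fit_nmda=True)

    def test_mg_block_recorded_in_trace(self):
        mg = MgBlock(mg_mM=1.2)
        t, ge, gi, gn = _known_traces(5)
        g = decompose_conductances(_forward_iv(t, ge, gi, gn, mg), mg_block=mg)
        assert g.mg_block_record["mg_mM"] == 1.2


class TestReconstructCurrents:
    def test_zero_conductances_zero_current(self):
        g = sc.ConductanceTrace(
            np.arange(3) * 10.0, np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3)
        )
        np.testing.assert_allclose(reconstruct_currents(g, -60.0), 0.0)

    def test_round_trip_at_supplied_potentials(self):
        mg = MgBlock()
        t, ge, gi, gn = _known_traces(30)
        iv = _forward_iv(t, ge, gi, gn, mg)
        g = decompose_conductances(iv, mg_block=mg)
        for j, v in enumerate(POTENTIALS):
            np.testing.assert_allclose(
                reconstruct_currents(g, v), iv.currents_pa[:, j], rtol=1e-8, atol=1e-9
            )

    def test_no_inhibitory_contribution_at_e_inh(self):
        g = sc.ConductanceTrace(
            np.arange(3) * 10.0, np.zeros(3), np.ones(3), np.zeros(3), np.zeros(3),
            nmda_fitted=False,
        )
        np.testing.assert_allclose(reconstruct_currents(g, -70.0), 0.0, atol=1e-12)

    def test_non_finite_rejected(self):
        g = sc.ConductanceTrace(
            np.arange(2) * 10.0, np.array([np.nan, 0.0]), np.zeros(2), np.zeros(2),
            np.zeros(2),
        )
        with pytest.raises(ValueError):
            reconstruct_currents(g, -60.0)


class TestDifferenceConductance:
    def _trace(self, ge, seed=0):
        n = len(ge)
        return sc.ConductanceTrace(
            np.arange(n) * 10.0, np.asarray(ge, dtype=float), np.zeros(n),
            np.zeros(n), np.zeros(n),
        )

    def test_identical_traces_zero_difference(self):
        a = self._trace([1.0, 2.0, 3.0])
        d = difference_conductance(a, a)
        np.testing.assert_array_equal(d.g_exc_ns, 0.0)

    def test_antisymmetry(self):
        a = self._trace([1.0, 2.0, 3.0])
        b = self._trace([0.5, 0.1, 2.0])
        d1 = difference_conductance(a, b)
        d2 = difference_conductance(b, a)
        np.testing.assert_allclose(d1.g_exc_ns, -d2.g_exc_ns)

    def test_difference_isolates_tonic_component(self):
        """Control minus a drug fit lacking the tonic component recovers
        the tonic component."""
        tonic = np.array([1.2, 1.3, 1.1, 1.25])
        transient = np.array([3.0, 1.0, 0.3, 0.1])
        ctrl = self._trace(tonic + transient)
        drug = self._trace(transient)
        d = difference_conductance(ctrl, drug)
        np.testing.assert_allclose(d.g_exc_ns, tonic)

    def test_grid_mismatch_rejected(self):
        a = self._trace([1.0, 2.0])
        b = sc.ConductanceTrace(
            np.array([0.0, 20.0]), np.zeros(2), np.zeros(2), np.zeros(2), np.zeros(2)
        )
        with pytest.raises(ValueError):
            difference_conductance(a, b)


class TestTimecourseSimilarity:
    def test_exact_proportionality_scale_four(self):
        b = np.sin(np.arange(50) / 5.0)
        scale, corr = timecourse_similarity(4.0 * b, b)
        assert scale == pytest.approx(4.0)
        assert corr == pytest.approx(1.0)

    def test_orthogonal_traces_zero_scale(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, 1.0, 1.0])
        scale, _ = timecourse_similarity(a, b)
        assert scale == pytest.approx(0.0)

    def test_noisy_proportionality_recovered(self):
        """g_a = 4 g_b + small noise: scale within 5% of 4 and
        correlation > 0.95."""
        rng = np.random.default_rng(3)
        b = np.sin(np.arange(200) / 20.0) + 1.0
        a = 4.0 * b + 0.2 * rng.standard_normal(b.size)
        scale, corr = timecourse_similarity(a, b)
        assert scale == pytest.approx(4.0, rel=0.05)
        assert corr > 0.95

    def test_zero_reference_flagged(self):
        scale, corr = timecourse_similarity(np.ones(5), np.zeros(5))
        assert np.isnan(scale)

    def test_scale_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        s1, _ = timecourse_similarity(a, b)
        s2, _ = timecourse_similarity(5.0 * a, 5.0 * b)
        assert s1 == pytest.approx(s2)
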