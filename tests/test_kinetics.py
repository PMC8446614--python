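"""Two-compartment exchange model: impulse response, forward model, pixel fit."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from perfquant.containers import ConcentrationCurve
from perfquant.kinetics import (
    FitOptions,
    KineticParameters,
    cxm2_impulse_response,
    fit_pixel,
    forward_tissue_curve,
    quantify_map,
)
from perfquant.synthetic_data import AifParams, generate_aif


def ode_impulse_response(p: KineticParameters, times: np.ndarray) -> np.ndarray:
    """Independent oracle: integrate the compartment ODEs directly."""
    fp, ps, vp, ve = p.Fp / 60, p.PS / 60, p.vp, p.ve
    A = np.array([[-(fp + ps) / vp, ps / vp], [ps / ve, -ps / ve]])
    x0 = np.array([fp / vp, 0.0])  # delta input deposited in plasma
    sol = solve_ivp(
        lambda t, x: A @ x, (0, times[-1]), x0, t_eval=times,
        rtol=1e-11, atol=1e-13, method="LSODA",
    )
    return (vp * sol.y[0] + ve * sol.y[1]) / fp


@pytest.fixture(scope="module")
def aif():
    times = np.arange(86) * 0.7
    curve = generate_aif(AifParams(amplitude=1.0, onset=5.0, shape=1.0, scale=2.5), times)
    # 7 pre-contrast frames precede the 5 s onset
    return ConcentrationCurve(
        times=curve.times, values=curve.values, baseline_frames=7, label="aif"
    )


class TestImpulseResponse:
    def test_normalized_and_monotone(self):
        t = np.linspace(0, 120, 500)
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = KineticParameters(
                Fp=rng.uniform(0.2, 4), PS=rng.uniform(0.05, 3),
                vp=rng.uniform(0.02, 0.2), ve=rng.uniform(0.05, 0.5),
            )
            r = cxm2_impulse_response(p, t)
            assert r[0] == pytest.approx(1.0)
            assert np.all(np.diff(r) <= 1e-12)
            assert r[-1] < 0.5  # decays towards zero for Fp > 0

    def test_ps_zero_is_monoexponential(self):
        p = KineticParameters(Fp=1.2, PS=0.0, vp=0.1, ve=0.2)
        t = np.linspace(0, 60, 200)
        expected = np.exp(-(1.2 / 60) * t / 0.1)
        np.testing.assert_allclose(cxm2_impulse_response(p, t), expected, atol=1e-14)

    def test_matches_ode_integration(self):
        """Biexponential closed form vs stiff ODE oracle, 100 random parameter sets."""
        t = np.linspace(0, 120, 241)
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            p = KineticParameters(
                Fp=rng.uniform(0.2, 4), PS=rng.uniform(0.05, 3),
                vp=rng.uniform(0.02, 0.2), ve=rng.uniform(0.05, 0.5),
            )
            err = np.max(np.abs(cxm2_impulse_response(p, t) - ode_impulse_response(p, t)))
            worst = max(worst, err)
        assert worst < 1e-6

    def test_area_equals_total_distribution_volume_over_flow(self):
        """Mean transit time identity: integral of R = (vp + ve)/Fp."""
        p = KineticParameters(Fp=1.0, PS=0.5, vp=0.1, ve=0.2)
        t = np.linspace(0, 5000, 200001)
        area = np.trapezoid(cxm2_impulse_response(p, t), t)
        assert area == pytest.approx((p.vp + p.ve) / (p.Fp / 60), rel=1e-3)

    def test_degenerate_volumes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            KineticParameters(Fp=1.0, PS=0.5, vp=0.0, ve=0.2)
        with pytest.raises(ValueError):
            KineticParameters(Fp=1.0, PS=0.5, vp=0.5, ve=0.6)  # vp+ve > 1


class TestForwardModel:
    def test_linearity(self, aif):
        p = KineticParameters(Fp=1.5, PS=0.8, vp=0.08, ve=0.2, t0=2.0)
        zero = aif.with_values(np.zeros(len(aif)))
        assert np.all(forward_tissue_curve(zero, p).values == 0)
        c1 = forward_tissue_curve(aif, p).values
        c2 = forward_tissue_curve(aif.with_values(2 * aif.values), p).values
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_boxcar_ps_zero_closed_form(self):
        """PS=0, unit boxcar input: C(t) = vp (1 - exp(-Fp t / vp)) on the plateau."""
        dt = 0.05
        times = np.arange(0, 30, dt)
        T = 20.0
        box = ConcentrationCurve(times=times, values=(times <= T).astype(float), label="aif")
        p = KineticParameters(Fp=1.2, PS=0.0, vp=0.1, ve=0.2, t0=0.0)
        got = forward_tissue_curve(box, p).values
        sel = (times > 1.0) & (times <= T)
        expected = p.vp * (1 - np.exp(-(p.Fp / 60) * times[sel] / p.vp))
        np.testing.assert_allclose(got[sel], expected, rtol=5e-3, atol=2e-4)

    def test_peak_monotone_in_flow(self, aif):
        peaks = [
            forward_tissue_curve(
                aif, KineticParameters(Fp=fp, PS=0.8, vp=0.08, ve=0.2, t0=1.0)
            ).values.max()
            for fp in np.linspace(0.2, 4.0, 12)
        ]
        assert np.all(np.diff(peaks) > 0)

    def test_zero_before_onset_plus_delay(self, aif):
        p = KineticParameters(Fp=1.5, PS=0.8, vp=0.08, ve=0.2, t0=3.0)
        c = forward_tissue_curve(aif, p).values
        assert np.all(c[aif.times < 5.0 + 3.0] == pytest.approx(0.0, abs=1e-12))

    def test_short_aif_rejected(self):
        short = ConcentrationCurve(times=np.arange(3.0), values=np.ones(3), label="aif")
        with pytest.raises(ValueError, match="too short"):
            forward_tissue_curve(short, KineticParameters(1, 1, 0.1, 0.2))


class TestFitPixel:
    def test_noiseless_recovery_within_1pct(self, aif):
        truth = KineticParameters(Fp=1.575, PS=0.8, vp=0.08, ve=0.2, t0=2.0)
        tissue = forward_tissue_curve(aif, truth)
        result = fit_pixel(aif, tissue)
        assert result.params.mbf == pytest.approx(1.5, rel=0.01)
        assert result.converged

    def test_zero_tissue_returns_floor_not_error(self, aif):
        tissue = aif.with_values(np.zeros(len(aif)), label="tissue")
        result = fit_pixel(aif, tissue)
        assert result.params.mbf <= 0.01
        assert not result.converged

    def test_unit_invariance(self, aif):
        truth = KineticParameters(Fp=2.0, PS=1.0, vp=0.1, ve=0.25, t0=1.0)
        tissue = forward_tissue_curve(aif, truth)
        rng = np.random.default_rng(3)
        noisy = tissue.values + rng.normal(0, tissue.values.max() / 30, len(aif))
        r1 = fit_pixel(aif, tissue.with_values(noisy))
        c = 37.5
        r2 = fit_pixel(
            aif.with_values(c * aif.values), tissue.with_values(c * noisy)
        )
        assert r2.params.mbf == pytest.approx(r1.params.mbf, rel=1e-3)

    def test_mismatched_grids_rejected(self, aif):
        other = ConcentrationCurve(
            times=aif.times + 0.1, values=aif.values, label="tissue"
        )
        with pytest.raises(ValueError, match="time grid"):
            fit_pixel(aif, other)

    def test_noisy_recovery_mare(self, aif):
        """SNR-20 replicates at stress-level flow: median error stays moderate."""
        truth = KineticParameters(Fp=2.625, PS=1.0, vp=0.1, ve=0.2, t0=1.5)
        tissue = forward_tissue_curve(aif, truth)
        peak = tissue.values.max()
        rng = np.random.default_rng(21)
        errs = []
        for _ in range(20):
            noisy = tissue.values + rng.normal(0, peak / 20, len(aif))
            r = fit_pixel(aif, tissue.with_values(noisy))
            errs.append(abs(r.params.mbf - 2.5) / 2.5)
        assert np.median(errs) < 0.10


class TestQuantifyMap:
    def test_single_pixel_mask(self, noiseless_phantom, prepared_inputs):
        _, _, aif = prepared_inputs
        ph = noiseless_phantom
        rr, cc, ss = np.nonzero(ph.myocardial_mask)
        mask = np.zeros_like(ph.myocardial_mask)
        mask[rr[0], cc[0], ss[0]] = True
        m = quantify_map(ph.series, aif, mask)
        assert np.isfinite(m.values[mask]).sum() == 1

    def test_pixel_independence(self, noiseless_phantom, prepared_inputs):
        """Disjoint masks quantified separately equal the joint quantification."""
        _, _, aif = prepared_inputs
        ph = noiseless_phantom
        rr, cc, ss = np.nonzero(ph.myocardial_mask)
        m1 = np.zeros_like(ph.myocardial_mask)
        m2 = np.zeros_like(ph.myocardial_mask)
        m1[rr[0], cc[0], ss[0]] = True
        m2[rr[50], cc[50], ss[50]] = True
        joint = quantify_map(ph.series, aif, m1 | m2)
        sep1 = quantify_map(ph.series, aif, m1)
        sep2 = quantify_map(ph.series, aif, m2)
        assert joint.values[m1] == sep1.values[m1]
        assert joint.values[m2] == sep2.values[m2]

    def test_empty_mask_rejected(self, noiseless_phantom, prepared_inputs):
        _, _, aif = prepared_inputs
        ph = noiseless_phantom
        with pytest.raises(ValueError, match="empty"):
            quantify_map(ph.series, aif, np.zeros_like(ph.myocardial_mask))
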