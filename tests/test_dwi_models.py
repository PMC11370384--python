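import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippodev.dwi_models import (NoddiParams, SandiParams, TensorParams,
                                 ball_signal, fa_md, noddi_signal,
                                 odi_from_kappa, kappa_from_odi, sandi_sphmean,
                                 sphere_gpd_sphmean, stick_sphmean,
                                 tensor_signal, watson_stick_signal)
from hippodev.protocol import make_protocol


class TestTensorSignal:
    def test_isotropic_tensor(self, protocol):
        d = 0.8
        sig = tensor_signal(TensorParams(d * np.eye(3), S0=2.0), protocol)
        assert np.allclose(sig, 2.0 * np.exp(-protocol.bvals * d))

    def test_b0_returns_s0(self, protocol):
        sig = tensor_signal(TensorParams(np.diag([1.7, 0.3, 0.3]), S0=5.0),
                            protocol)
        assert np.allclose(sig[protocol.bvals == 0], 5.0)

    def test_frobenius_product_by_hand(self):
        from hippodev.protocol import AcquisitionProtocol

        prot = AcquisitionProtocol(np.array([1.0]), np.array([[1.0, 0, 0]]))
        sig = tensor_signal(TensorParams(np.diag([1.7, 0.3, 0.3])), prot)
        assert sig[0] == pytest.approx(np.exp(-1.7), rel=1e-12)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            TensorParams(np.diag([-1.0, 0.3, 0.3]))

    def test_direction_average_matches_axisymmetric_closed_form(self):
        """Direction average over a dense sphere grid equals
        exp(-b d_perp) * sphmean(b, d_par - d_perp) for an axially
        symmetric tensor."""
        from hippodev.protocol import AcquisitionProtocol

        d_par, d_perp, b = 1.7, 0.4, 2.4
        t, w = np.polynomial.legendre.leggauss(48)
        phi = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        st_ = np.sqrt(1 - t**2)
        dirs = np.stack([
            (st_[:, None] * np.cos(phi)).ravel(),
            (st_[:, None] * np.sin(phi)).ravel(),
            np.broadcast_to(t[:, None], (48, 48)).ravel()], axis=1)
        weights = np.broadcast_to(w[:, None] / (2 * 48), (48, 48)).ravel()
        prot = AcquisitionProtocol(np.full(len(dirs), b), dirs)
        sig = tensor_signal(TensorParams(np.diag([d_perp, d_perp, d_par])), prot)
        closed = np.exp(-b * d_perp) * stick_sphmean(b, d_par - d_perp)
        assert float(sig @ weights) == pytest.approx(closed, abs=1e-4)


class TestEigenvalueMetrics:
    @pytest.mark.parametrize("evals,fa,md", [
        ((1, 1, 1), 0.0, 1.0),
        ((2.5, 0, 0), 1.0, 2.5 / 3),
        ((1.7, 0.3, 0.3), None, 0.7666667),
        ((0, 0, 0), 0.0, 0.0),
    ])
    def test_known_values(self, evals, fa, md):
        got_fa, got_md = fa_md(evals)
        assert got_md == pytest.approx(md, abs=1e-6)
        if fa is not None:
            assert got_fa == pytest.approx(fa, abs=1e-9)
        assert 0.0 <= got_fa <= 1.0


class TestOrientationDispersionIndex:
    def test_limits_and_midpoint(self):
        assert odi_from_kappa(0.0) == pytest.approx(1.0)
        assert odi_from_kappa(1.0) == pytest.approx(0.5)
        assert odi_from_kappa(1e6) < 1e-5

    def test_inverse(self):
        for odi in (0.1, 0.5, 0.9):
            assert odi_from_kappa(kappa_from_odi(odi)) == pytest.approx(odi)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            odi_from_kappa(-0.5)


def watson_stick_bruteforce(b, cosbeta, kappa, d=1.7, nt=4000, nph=256):
    """Independent dense-quadrature oracle for the Watson-stick signal."""
    t = np.linspace(-1, 1, nt)
    phi = np.linspace(0, 2 * np.pi, nph, endpoint=False)
    st_, sb = np.sqrt(1 - t**2), np.sqrt(1 - cosbeta**2)
    gn = cosbeta * t[:, None] + sb * st_[:, None] * np.cos(phi)[None, :]
    w = np.exp(kappa * t**2 - kappa)
    K = np.exp(-b * d * gn**2).mean(axis=1)
    return np.trapezoid(w * K, t) / np.trapezoid(w, t)


class TestWatsonStick:
    @pytest.mark.parametrize("kappa,tol", [(0.0, 1e-6), (1.0, 1e-6),
                                           (10.0, 1e-5), (100.0, 2e-4),
                                           (1000.0, 1e-3)])
    def test_against_bruteforce_oracle(self, kappa, tol):
        for b in (0.5, 6.0):
            for cb in (0.0, 0.5, 1.0):
                got = watson_stick_signal(np.array([b]), np.array([cb]), kappa)[0]
                want = watson_stick_bruteforce(b, cb, kappa)
                assert got == pytest.approx(want, abs=tol)

    def test_isotropic_dispersion_equals_spherical_mean(self):
        b = np.array([0.5, 2.4, 6.0])
        for cb in (0.0, 0.3, 0.9):
            sig = watson_stick_signal(b, np.full(3, cb), kappa=0.0)
            assert np.allclose(sig, stick_sphmean(b, 1.7), atol=1e-12)

    def test_high_concentration_approaches_single_stick(self):
        b, cb = 6.0, 0.7
        got = watson_stick_signal(np.array([b]), np.array([cb]), 1e3)[0]
        assert got == pytest.approx(np.exp(-b * 1.7 * cb**2), abs=1e-3)


class TestNoddiSignal:
    def test_pure_csf(self, protocol):
        p = NoddiParams(f_iso=1.0, f_in=0.5, kappa=2.0, mu=[0, 0, 1])
        sig = noddi_signal(p, protocol)
        assert np.allclose(sig, np.exp(-protocol.bvals * 3.0), atol=1e-12)

    def test_b0_is_one(self, protocol):
        p = NoddiParams(0.2, 0.6, 3.0, [1, 1, 0])
        assert np.allclose(noddi_signal(p, protocol)[protocol.bvals == 0], 1.0)

    def test_isotropic_watson_orientation_independent(self, protocol):
        p = NoddiParams(f_iso=0.0, f_in=1.0, kappa=0.0, mu=[0, 0, 1])
        sig = noddi_signal(p, protocol)
        expect = stick_sphmean(protocol.bvals, 1.7)
        assert np.allclose(sig, expect, atol=1e-10)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            NoddiParams(f_iso=-0.1, f_in=0.5, kappa=1.0, mu=[0, 0, 1])
        with pytest.raises(ValueError):
            NoddiParams(f_iso=0.1, f_in=1.5, kappa=1.0, mu=[0, 0, 1])


class TestStickSphericalMean:
    def test_no_attenuation_limit(self):
        assert stick_sphmean(0.0, 1.7) == pytest.approx(1.0)
        assert stick_sphmean(1.0, 0.0) == pytest.approx(1.0)

    def test_value_vs_numerical_average(self):
        # 1e6-orientation Monte-Carlo average of exp(-b D cos^2 theta)
        rng = np.random.default_rng(0)
        t = rng.uniform(-1, 1, 1_000_000)
        mc = np.exp(-6.0 * 1.7 * t**2).mean()
        assert stick_sphmean(6.0, 1.7) == pytest.approx(mc, abs=1e-3)
        assert stick_sphmean(6.0, 1.7) == pytest.approx(0.2775, abs=2e-4)

    def test_monotone_decreasing_in_b(self):
        b = np.linspace(0, 6, 61)
        sig = stick_sphmean(b, 1.7)
        assert np.all(np.diff(sig) < 0)


class TestBallSignal:
    @pytest.mark.parametrize("b,d,want", [
        (0.0, 3.0, 1.0),
        (1.2, 3.0, np.exp(-3.6)),
        (6.0, 3.0, np.exp(-18.0)),
    ])
    def test_known_values(self, b, d, want):
        assert ball_signal(b, d) == pytest.approx(want, rel=1e-12)


class TestSphereGPD:
    def test_vanishing_radius_limit(self):
        assert sphere_gpd_sphmean(6.0, 1e-3, 7, 24) == pytest.approx(1.0, abs=1e-9)

    def test_decreasing_in_radius(self):
        sig = [sphere_gpd_sphmean(6.0, r, 7, 24) for r in np.linspace(1, 12, 23)]
        assert np.all(np.diff(sig) < 0)

    def test_series_self_convergence(self):
        for r in (4.0, 8.0, 12.0):
            s20 = sphere_gpd_sphmean(6.0, r, 7, 24, n_roots=20)
            s50 = sphere_gpd_sphmean(6.0, r, 7, 24, n_roots=50)
            assert abs(s20 - s50) < 1e-8

    def test_timing_violation_rejected(self):
        with pytest.raises(ValueError):
            sphere_gpd_sphmean(6.0, 8.0, delta=24, big_delta=7)


class TestSandiSphericalMean:
    def test_b0_is_one(self, protocol):
        p = SandiParams(0.3, 0.5, 8.0, 1.7, 1.0)
        assert sandi_sphmean(p, protocol)[0] == pytest.approx(1.0)

    def test_pure_ball_degenerate_mixture(self, protocol):
        p = SandiParams(1.0, 0.5, 8.0, 1.7, 1.0)
        b = protocol.shells.b_shells
        assert np.allclose(sandi_sphmean(p, protocol), ball_signal(b, 1.0))

    def test_convex_combination_of_components(self, protocol):
        p = SandiParams(0.25, 0.6, 7.0, 2.0, 0.8)
        b = protocol.shells.b_shells
        expect = ((1 - 0.25) * (0.6 * stick_sphmean(b, 2.0)
                                + 0.4 * sphere_gpd_sphmean(b, 7.0, 7, 24))
                  + 0.25 * ball_signal(b, 0.8))
        assert np.allclose(sandi_sphmean(p, protocol), expect, atol=1e-12)

    def test_derived_fractions(self):
        p = SandiParams(0.3, 0.5, 8.0, 1.7, 1.0)
        assert p.f_neurite + p.f_soma + p.f_extracellular == pytest.approx(1.0)


@settings(max_examples=25, deadline=None)
@given(f_ec=st.floats(0, 1), f_in=st.floats(0, 1),
       r_s=st.floats(1, 12), d_in=st.floats(0.1, 3), d_ec=st.floats(0.1, 3))
def test_sandi_signal_in_unit_interval(f_ec, f_in, r_s, d_in, d_ec):
    """Normalised spherical-mean signals stay in (0, 1] for physical
    parameters, and the mixture is affine in each fraction."""
    prot = make_protocol(seed=0, shell_spec=[(0.0, 1), (0.5, 6), (1.2, 6),
                                             (2.4, 6), (4.0, 6), (6.0, 6)])
    p = SandiParams(f_ec, f_in, r_s, d_in, d_ec)
    sig = sandi_sphmean(p, prot)
    assert np.all(sig > 0) and np.all(sig <= 1 + 1e-12)
    # affine in f_ec: halfway mixture equals average of endpoints
    lo = sandi_sphmean(SandiParams(0.0, f_in, r_s, d_in, d_ec), prot)
    hi = sandi_sphmean(SandiParams(1.0, f_in, r_s, d_in, d_ec), prot)
    mid = sandi_sphmean(SandiParams(0.5, f_in, r_s, d_in, d_ec), prot)
    assert np.allclose(mid, 0.5 * (lo + hi), atol=1e-12)
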