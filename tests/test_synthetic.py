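"""Phantom generators: analytic curves, dimers, series, noise model."""

import numpy as np
import pytest

from oligosaxs import guinier_fit, oligomer_fraction
from oligosaxs.debye import debye_curve
from oligosaxs.guinier import kratky_transform
from oligosaxs.synthetic import (PhantomSpec, add_noise, ball_model,
                                 core_plus_tail_model, default_q_grid,
                                 dimer_curve, gaussian_chain_curve,
                                 mixture_series, sphere_curve)


class TestAnalyticCurves:
    def test_sphere_limits_and_first_zero(self):
        q = np.linspace(0.0, 0.4, 2000)
        sp = sphere_curve(30.0, 5.0, q)
        assert sp.I[0] == 5.0
        # first zero of the form factor at qR ~ 4.4934 (root of tan x = x)
        x = q * 30.0
        window = (x > 4.0) & (x < 5.0)
        x_min = x[window][np.argmin(sp.I[window])]
        assert x_min == pytest.approx(4.4934, abs=0.01)

    def test_sphere_guinier_moment(self):
        q = np.linspace(1e-3, 0.05, 100)
        rg = guinier_fit(sphere_curve(30.0, 1.0, q)).Rg
        assert rg == pytest.approx(np.sqrt(3.0 / 5.0) * 30.0, rel=5e-3)

    def test_gaussian_chain_limit_and_guinier(self):
        q = default_q_grid()
        gc = gaussian_chain_curve(25.0, 3.0, np.concatenate([[0.0], q]))
        assert gc.I[0] == pytest.approx(3.0)
        rg = guinier_fit(gaussian_chain_curve(25.0, 3.0,
                                              np.linspace(1e-3, 0.05, 80))).Rg
        assert rg == pytest.approx(25.0, rel=0.01)

    def test_chain_kratky_plateau_has_no_late_maximum(self):
        q = np.linspace(1e-3, 0.5, 300)
        k = kratky_transform(gaussian_chain_curve(25.0, 1.0, q))
        tail = k.I[q > 0.25]
        assert np.ptp(tail) < 0.12 * tail.mean()

    def test_analytic_matches_debye_of_point_sample(self):
        """Cross-module consistency: the closed-form sphere curve agrees
        with the Debye evaluation of a dense point realisation."""
        q = np.linspace(1e-3, 0.15, 80)
        ana = sphere_curve(30.0, 1.0, q)
        num = debye_curve(ball_model(30.0, 3000, seed=8), q)
        dev = np.abs(num.I / num.I[0] - ana.I / ana.I[0])
        assert dev.max() < 0.02


class TestDimer:
    def test_forward_scattering_quadruples(self):
        q = np.linspace(0.0, 0.3, 80)
        mono = ball_model(15.0, 100, seed=1)
        _, curve = dimer_curve(mono, 80.0, q_grid=q)
        W = mono.weights.sum()
        assert curve.I[0] == pytest.approx((2.0 * W) ** 2, rel=1e-9)

    def test_symmetric_under_c2(self):
        mono = ball_model(15.0, 100, seed=1)
        model, _ = dimer_curve(mono, 40.0)
        pos = model.positions
        # 180-degree rotation about z maps the set onto itself
        rotated = pos * np.array([-1.0, -1.0, 1.0])
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pos).query(rotated, k=1)
        assert d.max() < 1e-9

    def test_distant_copies_approach_doubled_monomer_at_high_q(self):
        q = np.linspace(0.2, 0.5, 60)
        mono = ball_model(12.0, 150, seed=2)
        mono_I = debye_curve(mono, q).I
        _, curve = dimer_curve(mono, 500.0, q_grid=q)
        np.testing.assert_allclose(curve.I, 2.0 * mono_I, rtol=0.02)

    def test_deterministic(self):
        mono = ball_model(15.0, 100, seed=1)
        a, ca = dimer_curve(mono, 40.0)
        b, cb = dimer_curve(mono, 40.0)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(ca.I, cb.I)


class TestCorePlusTail:
    def test_site_counts_and_determinism(self):
        m1 = core_plus_tail_model(n_core=285, n_tail=31, seed=3)
        m2 = core_plus_tail_model(n_core=285, n_tail=31, seed=3)
        assert len(m1) == 285 + 31
        np.testing.assert_array_equal(m1.positions, m2.positions)


class TestAddNoise:
    def test_zero_level_keeps_intensities_and_adds_sigma(self):
        sp = sphere_curve(20.0, 5.0, default_q_grid())
        out = add_noise(sp, 0.0, seed=1)
        np.testing.assert_array_equal(out.I, sp.I)
        assert out.sigma is not None and np.all(out.sigma > 0)

    def test_empirical_sd_matches_model(self):
        sp = sphere_curve(20.0, 5.0, default_q_grid())
        draws = np.array([add_noise(sp, 0.03, seed=s).I[50]
                          for s in range(10_000)])
        expected = 0.03 * sp.I[0] * np.sqrt(sp.I[50] / sp.I[0] + 0.01)
        assert draws.std() == pytest.approx(expected, rel=0.03)

    def test_seed_determinism(self):
        sp = sphere_curve(20.0, 5.0, default_q_grid())
        np.testing.assert_array_equal(add_noise(sp, 0.02, seed=9).I,
                                      add_noise(sp, 0.02, seed=9).I)


class TestMixtureSeries:
    def test_infinite_k_gives_pure_monomer(self):
        spec = PhantomSpec(K=np.inf, noise_level=0.0,
                           concentrations=(1.0, 2.0), seed=1)
        series = mixture_series(spec)
        assert all(p.meta["true_dimer_fraction"] == 0.0 for p in series)

    def test_fractions_increase_with_concentration(self):
        spec = PhantomSpec(K=5.0, noise_level=0.0, seed=1)
        series = mixture_series(spec)
        fr = [p.meta["true_dimer_fraction"] for p in series]
        assert all(b > a for a, b in zip(fr, fr[1:]))

    def test_printed_dimer_content_closes_the_loop(self):
        """A w = 0.324 phantom analysed through the I(0) mass route
        returns exactly 32.4% on noiseless data."""
        c = 2.0
        w = 0.324
        q0 = np.linspace(0.0, 0.4, 120)   # include q = 0 for exact I(0)
        spec = PhantomSpec(K=c * (1.0 - w) / w, noise_level=0.0,
                           concentrations=(c,), seed=5)
        prof = mixture_series(spec, q_grid=q0)[0]
        assert prof.meta["true_dimer_fraction"] == pytest.approx(w, rel=1e-12)
        # monomer reference: same spec at K = inf (all-monomer control)
        mono = mixture_series(PhantomSpec(K=np.inf, noise_level=0.0,
                                          concentrations=(c,), seed=5),
                              q_grid=q0)[0]
        m_ratio = prof.I[0] / mono.I[0]     # apparent mass in monomer units
        est = oligomer_fraction(m_ratio * 38_014, 38_014)
        assert est.dimer_percent == pytest.approx(32.4, abs=0.05)

    def test_metadata_records_spec_and_seed(self):
        spec = PhantomSpec(K=5.0, noise_level=0.01, seed=21,
                           concentrations=(1.0,))
        prof = mixture_series(spec)[0]
        assert prof.meta["spec"]["seed"] == 21
        assert "noise_seed" in prof.meta

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(dimer_fraction=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(radius=-1.0)
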