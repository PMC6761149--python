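"""Mixture decomposition and genetic-algorithm ensemble selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligosaxs import (EnsembleSelector, Mixture, ScatteringProfile,
                       fit_mixture, fit_to_profile, generate_pool,
                       oligomer_fraction, select_ensemble)
from oligosaxs.debye import debye_curve
from oligosaxs.exceptions import ConformerGenerationError
from oligosaxs.synthetic import add_noise, ball_model, dimer_curve


@pytest.fixture(scope="module")
def mono_dimer():
    q = np.linspace(5e-3, 0.4, 150)
    mono = ball_model(20.0, 300, seed=2)
    m_curve = debye_curve(mono, q)
    _, d_curve = dimer_curve(mono, 40.0, q_grid=q)
    return m_curve, d_curve


class TestFitMixture:
    def test_noiseless_decomposition_exact(self, mono_dimer):
        m, d = mono_dimer
        data = ScatteringProfile(q=m.q, I=0.6 * m.I + 0.4 * d.I)
        res = fit_mixture(data, [m, d])
        np.testing.assert_allclose(res.fractions, [0.6, 0.4], atol=1e-6)
        assert res.chi == pytest.approx(0.0, abs=1e-6)

    def test_single_component_fraction_one(self, mono_dimer):
        m, _ = mono_dimer
        res = fit_mixture(m, [m])
        assert res.fractions[0] == pytest.approx(1.0)

    def test_noisy_fraction_recovery_study(self, mono_dimer):
        m, d = mono_dimer
        data = ScatteringProfile(q=m.q, I=0.6 * m.I + 0.4 * d.I)
        errs = []
        for seed in range(50):
            noisy = add_noise(data, 0.01, seed=seed)
            res = fit_mixture(noisy, [m, d])
            errs.append(abs(res.fractions[1] - 0.4))
        assert np.mean(errs) <= 0.02

    def test_reduces_to_single_curve_fit(self, mono_dimer):
        m, _ = mono_dimer
        data = add_noise(m.replace(I=3.0 * m.I), 0.02, seed=9)
        chi_mix = fit_mixture(data, [m]).chi
        chi_fit = fit_to_profile(m, data).chi
        assert chi_mix == pytest.approx(chi_fit, rel=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(w=st.floats(min_value=0.0, max_value=1.0))
    def test_unbiased_on_simplex(self, mono_dimer, w):
        """Noiseless fraction recovery is exact for any simplex point."""
        m, d = mono_dimer
        data = ScatteringProfile(q=m.q, I=(1 - w) * m.I + w * d.I)
        res = fit_mixture(data, [m, d])
        assert res.fractions[1] == pytest.approx(w, abs=1e-6)
        assert abs(res.fractions.sum() - 1.0) <= 1e-9

    def test_i0_consistency_with_mass_route(self):
        """Apparent mass from the mixed curve's I(0) equals (1+w) M,
        closing the loop with the dimer-content statistic."""
        q = np.linspace(0.0, 0.4, 150)   # q = 0 included for exact I(0)
        mono = ball_model(20.0, 300, seed=2)
        m = debye_curve(mono, q)
        _, d = dimer_curve(mono, 40.0, q_grid=q)
        w = 0.42
        # per unit mass: dimer contributes half as many particles
        data = ScatteringProfile(q=q, I=(1 - w) * m.I + 0.5 * w * d.I)
        m_apparent = data.I[0] / m.I[0]     # in units of the monomer mass
        est = oligomer_fraction(m_apparent * 38_014, 38_014)
        assert est.dimer_fraction == pytest.approx(w, abs=1e-6)


class TestGeneratePool:
    def test_rigid_limit_copies_core(self):
        core = ball_model(10.0, 50, seed=1)
        pool = generate_pool(core, [], 4, seed=2)
        assert len(pool) == 4
        for m in pool:
            np.testing.assert_array_equal(m.positions, core.positions)

    def test_walk_geometry_audit(self):
        """All tail steps are exactly 3.8 A; no clash below 3.0 A."""
        core = ball_model(15.0, 100, seed=3)
        anchor_idx = int(np.argmax(core.positions[:, 0]))
        pool = generate_pool(core, [(anchor_idx, 31)], 20, seed=4)
        from scipy.spatial.distance import pdist, squareform
        for m in pool[:5]:
            tail = m.positions[100:]
            assert len(tail) == 31
            chain = np.vstack([core.positions[anchor_idx], tail])
            steps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
            np.testing.assert_allclose(steps, 3.8, atol=1e-9)
            D = squareform(pdist(m.positions))
            np.fill_diagonal(D, np.inf)
            # non-bonded pairs respect the hard-sphere cutoff
            for k in range(len(chain) - 1):
                a = 100 + k - 1 if k else anchor_idx
                D[a, 100 + k] = D[100 + k, a] = np.inf
            assert D[100:, :].min() >= 3.0 - 1e-9

    def test_same_seed_bit_identical(self):
        core = ball_model(10.0, 60, seed=5)
        p1 = generate_pool(core, [(0, 12)], 6, seed=77)
        p2 = generate_pool(core, [(0, 12)], 6, seed=77)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_impossible_walk_raises(self):
        # a dense cage around the anchor leaves no room to grow
        g = np.linspace(-4, 4, 5)
        cage = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        from oligosaxs import CoordinateModel
        model = CoordinateModel(positions=cage, weights=np.ones(len(cage)))
        with pytest.raises(ConformerGenerationError):
            generate_pool(model, [(62, 5)], 1, seed=0)


class TestSelectEnsemble:
    @pytest.fixture(scope="class")
    def pool(self):
        q = np.linspace(5e-3, 0.4, 120)
        core = ball_model(15.0, 100, seed=3)
        models = generate_pool(core, [(0, 20)], 30, seed=4)
        return [debye_curve(m, q) for m in models]

    def test_needle_in_pool_found_exactly(self, pool):
        res = select_ensemble(pool, pool[17], ensemble_size=1,
                              n_generations=30, n_rounds=2, seed=9)
        assert res.member_ids == (17,)
        assert res.chi == pytest.approx(0.0, abs=1e-9)

    def test_equal_pair_recovered(self, pool):
        data = ScatteringProfile(q=pool[3].q,
                                 I=0.5 * pool[3].I + 0.5 * pool[11].I)
        res = select_ensemble(pool, data, ensemble_size=2,
                              n_generations=60, n_rounds=2, seed=1)
        assert set(res.member_ids) == {3, 11}
        np.testing.assert_allclose(res.weights, [0.5, 0.5], atol=0.05)

    def test_ensemble_never_worse_than_best_single(self, pool):
        data = add_noise(ScatteringProfile(
            q=pool[0].q, I=0.4 * pool[2].I + 0.6 * pool[9].I), 0.02, seed=6)
        best_single = min(fit_to_profile(c, data).chi for c in pool)
        res = select_ensemble(pool, data, ensemble_size=3,
                              n_generations=40, n_rounds=2, seed=3)
        assert res.chi <= best_single + 1e-9

    def test_elitism_makes_chi_non_increasing(self, pool):
        data = ScatteringProfile(q=pool[0].q,
                                 I=0.5 * pool[5].I + 0.5 * pool[8].I)
        sel = EnsembleSelector(pool, data)
        res = sel.fit(ensemble_size=2, n_generations=40, n_rounds=1, seed=2)
        assert np.all(np.diff(res.chi_history) <= 1e-12)

    def test_oversized_ensemble_rejected(self, pool):
        with pytest.raises(ValueError):
            select_ensemble(pool, pool[0], ensemble_size=len(pool) + 1,
                            n_generations=5, seed=0)
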