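"""Bead-model reconstruction, NSD superposition and model averaging."""

import numpy as np
import pytest

from oligosaxs import (AnnealingSchedule, BeadModel, BeadReconstruction,
                       average_filter, nsd, rg_from_model)
from oligosaxs.debye import debye_curve
from oligosaxs.exceptions import DegenerateModelError
from oligosaxs.synthetic import add_noise, ball_model, sphere_curve

BR = 3.0
SPACING = BR / 0.62


def ellipsoid_phantom(ax=20.0, ay=14.0, az=26.0) -> BeadModel:
    occ = set()
    for i in range(-9, 10):
        for j in range(-9, 10):
            for k in range(-9, 10):
                x, y, z = i * SPACING, j * SPACING, k * SPACING
                if (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0:
                    occ.add((i, j, k))
    return BeadModel(occupied=frozenset(occ), spacing=SPACING, bead_radius=BR)


@pytest.fixture(scope="module")
def phantom_target():
    phantom = ellipsoid_phantom()
    q = np.linspace(5e-3, 0.35, 120)
    curve = debye_curve(phantom.to_coordinate_model(), q)
    return phantom, add_noise(curve, 0.02, seed=11)


SMALL = AnnealingSchedule(max_steps=60, patience=20)


class TestReconstruction:
    def test_round_trip_reaches_good_fit(self, phantom_target):
        phantom, target = phantom_target
        rec = BeadReconstruction(target, bead_radius=BR, search_radius=45.0,
                                 schedule=AnnealingSchedule(max_steps=150,
                                                            patience=30))
        res = rec.fit(seed=1)
        assert res.chi <= 1.5
        assert res.chi <= res.chi_initial
        assert res.model.is_connected()
        rg_true = rg_from_model(phantom.to_coordinate_model())
        rg_rec = rg_from_model(res.model.to_coordinate_model())
        assert rg_rec == pytest.approx(rg_true, rel=0.10)

    def test_best_energy_non_increasing_and_reproducible(self, phantom_target):
        _, target = phantom_target
        rec = BeadReconstruction(target, bead_radius=BR, search_radius=45.0,
                                 schedule=SMALL)
        a = rec.fit(seed=5)
        b = rec.fit(seed=5)
        assert a.model.occupied == b.model.occupied       # bit-reproducible
        assert a.energy <= a.energy_history[0]

    def test_sphere_target_rg_within_ten_percent(self):
        q = np.linspace(5e-3, 0.3, 100)
        target = add_noise(sphere_curve(25.0, 1.0, q), 0.02, seed=7)
        res = BeadReconstruction(target, bead_radius=BR, search_radius=45.0,
                                 schedule=AnnealingSchedule(max_steps=100,
                                                            patience=25)
                                 ).fit(seed=3)
        rg = rg_from_model(res.model.to_coordinate_model())
        assert rg == pytest.approx(np.sqrt(3.0 / 5.0) * 25.0, rel=0.10)

    def test_p2_symmetry_holds_in_result(self):
        from oligosaxs.synthetic import dimer_curve
        q = np.linspace(5e-3, 0.3, 100)
        mono = ball_model(14.0, 150, seed=2)
        _, curve = dimer_curve(mono, 32.0, q_grid=q)
        target = add_noise(curve, 0.02, seed=3)
        res = BeadReconstruction(target, bead_radius=BR, search_radius=50.0,
                                 symmetry="P2", schedule=SMALL).fit(seed=2)
        occ = res.model.occupied
        assert all((-i, -j, k) in occ for (i, j, k) in occ)
        assert res.model.is_connected()

    def test_monomer_fraction_requires_curve(self, phantom_target):
        _, target = phantom_target
        with pytest.raises(ValueError):
            BeadReconstruction(target, bead_radius=BR, search_radius=45.0,
                               monomer_fraction=0.58)

    def test_bead_radius_limit(self, phantom_target):
        _, target = phantom_target
        with pytest.raises(ValueError):
            BeadReconstruction(target, bead_radius=12.0, search_radius=45.0)

    def test_polydisperse_fit_runs(self, phantom_target):
        """Mixture-aware fitting with a fixed monomer fraction converges."""
        phantom, _ = phantom_target
        q = np.linspace(5e-3, 0.3, 100)
        mono_curve = sphere_curve(16.0, 1.0, q)
        dim = debye_curve(phantom.to_coordinate_model(), q)
        f = 0.58
        mixed = (f * mono_curve.I / np.trapezoid(mono_curve.I, q)
                 + (1 - f) * dim.I / np.trapezoid(dim.I, q))
        target = add_noise(mono_curve.replace(I=mixed), 0.02, seed=4)
        res = BeadReconstruction(target, bead_radius=BR, search_radius=45.0,
                                 monomer_fraction=f, monomer_curve=mono_curve,
                                 schedule=SMALL).fit(seed=6)
        assert res.chi <= res.chi_initial
        assert res.model.is_connected()


class TestNsd:
    def test_identity_is_zero(self):
        m = ellipsoid_phantom()
        assert nsd(m, m).nsd == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_rotated_copy_realigned(self):
        from scipy.spatial.transform import Rotation
        m = ellipsoid_phantom()
        R = Rotation.from_euler("xyz", [25, 40, 65], degrees=True).as_matrix()
        rotated = m.to_coordinate_model().transformed(rotation=R,
                                                      translation=[7, -3, 12])
        rep = nsd(m, rotated)
        assert rep.nsd <= 0.05

    def test_symmetry_under_swap(self):
        a = ellipsoid_phantom()
        b = ball_model(18.0, 150, seed=9)
        assert nsd(a, b).nsd == pytest.approx(nsd(b, a).nsd, abs=1e-6)
        assert nsd(a, b).nsd >= 0.0

    def test_offset_chains_closed_form(self):
        """Two parallel unit-spacing chains offset laterally by 1: every
        nearest-neighbour distance is 1, so NSD = sqrt(1/2 (1 + 1)) = 1
        (brute-force verified for small sets)."""
        n = 12
        A = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)])
        B = A + np.array([0.0, 1.0, 0.0])
        rep = nsd(A, B, alignment="none")
        # brute-force oracle
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
        t1 = d2.min(1).mean()   # d_B = 1
        t2 = d2.min(0).mean()   # d_A = 1
        expected = np.sqrt(0.5 * (t1 + t2))
        assert rep.nsd == pytest.approx(expected, rel=1e-12)
        assert rep.nsd == pytest.approx(1.0, rel=1e-12)

    def test_single_point_degenerate(self):
        with pytest.raises(DegenerateModelError):
            nsd(np.array([[0.0, 0.0, 0.0]]), np.zeros((3, 3)))


class TestAverageFilter:
    def test_idempotent_on_identical_models(self):
        m = ellipsoid_phantom()
        avg = average_filter([m, m, m])
        assert avg.occupied == m.occupied

    def test_threshold_semantics_on_disjoint_beads(self):
        a = BeadModel(occupied=frozenset({(0, 0, 0)}), spacing=SPACING,
                      bead_radius=BR)
        b = BeadModel(occupied=frozenset({(5, 0, 0)}), spacing=SPACING,
                      bead_radius=BR)
        both = average_filter([a, b], occupancy_cutoff=0.5)
        assert both.occupied == frozenset({(0, 0, 0), (5, 0, 0)})
        with pytest.warns(UserWarning):
            inter = average_filter([a, b], occupancy_cutoff=0.6)
        assert inter.occupied == frozenset()

    def test_average_of_noisy_reconstructions_not_worse(self, phantom_target):
        phantom, target = phantom_target
        recs = []
        for seed in (1, 2, 3):
            rec = BeadReconstruction(target, bead_radius=BR,
                                     search_radius=45.0,
                                     schedule=AnnealingSchedule(max_steps=40,
                                                                patience=15))
            recs.append(rec.fit(seed=seed).model)
        avg = average_filter(recs, occupancy_cutoff=0.5)
        singles = [nsd(phantom, m).nsd for m in recs]
        assert nsd(phantom, avg).nsd <= min(singles) + 0.1

    def test_mismatched_spacing_rejected(self):
        a = ellipsoid_phantom()
        b = BeadModel(occupied=a.occupied, spacing=SPACING * 2,
                      bead_radius=BR)
        with pytest.raises(ValueError):
            average_filter([a, b])
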