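"""Ab initio bead-shape reconstruction, NSD comparison and model averaging.

A low-resolution molecular envelope is represented as occupied beads on
a simple cubic lattice (bead radius = 0.62 * lattice spacing, slightly
overlapping spheres).  Starting from a compact connected ball, Metropolis
simulated annealing over single-bead occupancy flips minimises

    E = chi^2 + alpha_compact * looseness,

where chi^2 is the reduced chi-square of the bead model's Debye curve
against the data (with an optimal scale factor) and looseness is the
fraction of occupied beads with fewer than 6 occupied neighbours in the
26-neighbourhood.  Moves that disconnect the occupied set are rejected,
and under P2 symmetry every flip is applied simultaneously to the bead
and its 180-degree mate about the z axis, so the constraint holds at
every accepted step.  For polydisperse data a fixed monomer fraction
can be supplied together with a monomer form factor; the fitted curve
is then the area-normalised mixture

    I_fit = f * I_monomer / A_m + (1 - f) * I_beads / A_b.

Reconstructions are compared with the normalised spatial discrepancy
(NSD) after principal-axes superposition, and sets of reconstructions
are combined by occupancy-map averaging and filtering.
"""

from __future__ import annotations

import itertools
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DegenerateModelError, InitializationError
from .guinier import guinier_fit
from .profiles import CoordinateModel, ScatteringProfile

__all__ = [
    "BeadModel", "NsdReport", "AnnealingSchedule", "BeadReconstruction",
    "reconstruct", "nsd", "average_filter",
]

#: bead radius as a fraction of the lattice spacing (overlapping spheres)
BEAD_RADIUS_FACTOR = 0.62

_NEIGHBORS26 = [np.array(d) for d in itertools.product((-1, 0, 1), repeat=3)
                if d != (0, 0, 0)]
_NEIGHBORS26_T = [tuple(d) for d in itertools.product((-1, 0, 1), repeat=3)
                  if d != (0, 0, 0)]


@dataclass(frozen=True)
class BeadModel:
    """Occupied beads on a simple cubic lattice."""

    occupied: frozenset            # integer (i, j, k) lattice coordinates
    spacing: float                 # lattice constant, A
    bead_radius: float             # A
    lattice_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    symmetry: str = "P1"
    search_radius: float = np.inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupied", frozenset(
            tuple(int(v) for v in s) for s in self.occupied))
        object.__setattr__(self, "lattice_origin",
                           np.asarray(self.lattice_origin, dtype=float))

    def __len__(self) -> int:
        return len(self.occupied)

    def positions(self) -> np.ndarray:
        if not self.occupied:
            return np.zeros((0, 3))
        ijk = np.array(sorted(self.occupied), dtype=float)
        return self.lattice_origin + self.spacing * ijk

    def to_coordinate_model(self, label: str = "beads") -> CoordinateModel:
        pos = self.positions()
        return CoordinateModel(positions=pos, weights=np.ones(len(pos)),
                               label=label)

    def is_connected(self) -> bool:
        return _connected(set(self.occupied))

    def volume(self) -> float:
        """Occupied volume as n_beads * spacing^3 (space-filling cells)."""
        return len(self) * self.spacing ** 3

    def write_pdb(self, path) -> None:
        """Write one HETATM dummy atom per bead (for superposition tools)."""
        lines = []
        for n, p in enumerate(self.positions(), start=1):
            lines.append(
                f"HETATM{n:5d}  CA  DUM A{(n - 1) % 9999 + 1:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00 20.00           C"
            )
        lines.append("END")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class NsdReport:
    """Normalised spatial discrepancy between two point models."""

    nsd: float
    rotation: np.ndarray       # applied to the second model (about centroids)
    translation: np.ndarray

    def summary(self) -> str:
        return f"NSD = {self.nsd:.4f}"


@dataclass
class AnnealingSchedule:
    """Simulated-annealing control parameters.

    T0 is calibrated so roughly ``initial_acceptance`` of uphill moves
    are accepted at the start; the temperature then cools geometrically
    by ``cooling`` per block of ``flips_per_step`` attempted flips, and
    the run stops after ``patience`` blocks without best-energy
    improvement (or ``max_steps`` blocks).
    """

    cooling: float = 0.98
    flips_per_step: int = 1000
    patience: int = 50
    max_steps: int = 400
    initial_acceptance: float = 0.8
    n_q: int = 80               # data points used in the chi^2 (subsampled)
    hist_bin: float = 1.0       # pair-distance histogram bin, A


def _connected(occ: set) -> bool:
    if not occ:
        return False
    start = next(iter(occ))
    seen = {start}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        for d in _NEIGHBORS26_T:
            t = (s[0] + d[0], s[1] + d[1], s[2] + d[2])
            if t in occ and t not in seen:
                seen.add(t)
                queue.append(t)
    return len(seen) == len(occ)


def _locally_safe_removal(occ: set, s: tuple) -> bool:
    """Sufficient condition: the occupied 26-neighbours of ``s`` stay
    mutually connected inside the 3x3x3 neighbourhood without ``s``."""
    nbrs = [(s[0] + d[0], s[1] + d[1], s[2] + d[2]) for d in _NEIGHBORS26_T]
    occ_nbrs = [t for t in nbrs if t in occ]
    if not occ_nbrs:
        return False  # isolated bead: removing it empties a component
    region = set(occ_nbrs)
    start = occ_nbrs[0]
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for d in _NEIGHBORS26_T:
            t = (u[0] + d[0], u[1] + d[1], u[2] + d[2])
            if t in region and t not in seen:
                seen.add(t)
                queue.append(t)
    return len(seen) == len(region)


class BeadReconstruction:
    """Simulated-annealing bead reconstruction model for one curve.

    Parameters
    ----------
    data : ScatteringProfile
    bead_radius : float
        Bead radius in A; the lattice spacing is bead_radius / 0.62.
        Must be smaller than search_radius / 4.
    search_radius : float
        Radius of the spherical search volume, A.
    symmetry : {"P1", "P2"}
        P2 imposes 180-degree rotational symmetry about the z axis.
    monomer_fraction : float in [0, 1)
        Fixed fraction of a known monomer form factor in the fitted
        curve (polydispersity-aware fitting); requires ``monomer_curve``.
    """

    def __init__(self, data: ScatteringProfile, bead_radius: float,
                 search_radius: float, symmetry: str = "P1",
                 monomer_fraction: float = 0.0,
                 monomer_curve: ScatteringProfile | None = None,
                 schedule: AnnealingSchedule | None = None):
        if symmetry not in ("P1", "P2"):
            raise ValueError("symmetry must be 'P1' or 'P2'")
        if not bead_radius < search_radius / 4:
            raise ValueError("bead_radius must be < search_radius / 4")
        if not 0 <= monomer_fraction < 1:
            raise ValueError("monomer_fraction must be in [0, 1)")
        if monomer_fraction > 0 and monomer_curve is None:
            raise ValueError("monomer_curve required when monomer_fraction > 0")
        self.data = data
        self.bead_radius = float(bead_radius)
        self.spacing = float(bead_radius) / BEAD_RADIUS_FACTOR
        self.search_radius = float(search_radius)
        self.symmetry = symmetry
        self.monomer_fraction = float(monomer_fraction)
        self.monomer_curve = monomer_curve
        self.schedule = schedule or AnnealingSchedule()

    # -- state helpers ----------------------------------------------------

    def _subsampled_data(self):
        d = self.data
        n = len(d)
        nq = min(self.schedule.n_q, n)
        idx = np.unique(np.linspace(0, n - 1, nq).round().astype(int))
        q = d.q[idx]
        I = d.I[idx]
        if d.sigma is not None:
            sig = d.sigma[idx]
        else:
            sig = 0.02 * np.abs(I) + 1e-12 * max(np.max(np.abs(I)), 1.0)
        return q, I, sig

    def _mate(self, s: tuple) -> tuple:
        return (-s[0], -s[1], s[2])

    def fit(self, seed: int = 0, initial_radius: float | None = None):
        """Run the annealing and return a :class:`BeadReconstructionResult`."""
        rng = np.random.default_rng(seed)
        sch = self.schedule
        q, Iexp, sig = self._subsampled_data()

        # fixed monomer component, area-normalised
        mono = None
        if self.monomer_fraction > 0:
            mc = self.monomer_curve
            Im = mc.I if (len(mc) == len(q) and np.allclose(mc.q, q)) else \
                np.interp(q, mc.q, mc.I)
            mono = Im / np.trapezoid(Im, q)

        # histogram machinery
        hb = sch.hist_bin
        nbins = int(np.ceil(2.0 * self.search_radius / hb)) + 2
        centers = (np.arange(nbins) + 0.5) * hb
        S = np.sinc(np.outer(centers, q) / np.pi)   # (nbins, nq)

        # lattice and initial ball
        a = self.spacing
        nmax = int(np.floor(self.search_radius / a))
        lattice = set()
        for i in range(-nmax, nmax + 1):
            for j in range(-nmax, nmax + 1):
                for k in range(-nmax, nmax + 1):
                    if a * np.sqrt(i * i + j * j + k * k) <= self.search_radius:
                        lattice.add((i, j, k))
        r0 = initial_radius
        if r0 is None:
            try:
                rg = guinier_fit(self.data).Rg
                r0 = np.sqrt(5.0 / 3.0) * rg
            except Exception:
                r0 = self.search_radius / 2.0
        r0 = float(np.clip(r0, 2.5 * a, 0.9 * self.search_radius))
        occ = {s for s in lattice
               if a * np.linalg.norm(s) <= r0}
        if not occ or not _connected(occ):
            raise InitializationError("no feasible connected starting shape")

        # indexable coordinate store with swap-removal
        sites: list[tuple] = []
        index: dict = {}
        xyz = np.zeros((len(lattice), 3))
        H = np.zeros(nbins)
        ncnt: dict = {}
        n_loose = 0

        def _dist_bins(p: np.ndarray, n_used: int) -> np.ndarray:
            if n_used == 0:
                return np.empty(0, dtype=int)
            d = np.linalg.norm(xyz[:n_used] - p, axis=1)
            return np.minimum((d / hb).astype(int), nbins - 1)

        def _add(s: tuple) -> None:
            nonlocal n_loose
            p = a * np.asarray(s, dtype=float)
            b = _dist_bins(p, len(sites))
            np.add.at(H, b, 1.0)
            index[s] = len(sites)
            xyz[len(sites)] = p
            sites.append(s)
            occ_set.add(s)
            c = 0
            for d in _NEIGHBORS26_T:
                t = (s[0] + d[0], s[1] + d[1], s[2] + d[2])
                if t in occ_set:
                    c += 1
                    old = ncnt[t]
                    ncnt[t] = old + 1
                    if old == 5:      # crossed the looseness threshold
                        n_loose -= 1
            ncnt[s] = c
            if c < 6:
                n_loose += 1

        def _remove(s: tuple) -> None:
            nonlocal n_loose
            i = index.pop(s)
            last = sites.pop()
            if last != s:
                sites[i] = last
                xyz[i] = xyz[len(sites)]
                index[last] = i
            occ_set.discard(s)
            p = a * np.asarray(s, dtype=float)
            b = _dist_bins(p, len(sites))
            np.add.at(H, b, -1.0)
            if ncnt.pop(s) < 6:
                n_loose -= 1
            for d in _NEIGHBORS26_T:
                t = (s[0] + d[0], s[1] + d[1], s[2] + d[2])
                if t in occ_set:
                    old = ncnt[t]
                    ncnt[t] = old - 1
                    if old == 6:
                        n_loose += 1

        occ_set: set = set()
        for s in sorted(occ):
            _add(s)

        dof = max(len(q) - 1, 1)

        def _chi2() -> float:
            n = len(sites)
            if n == 0:
                return np.inf
            Ib = n + 2.0 * (H @ S)
            if mono is not None:
                area = np.trapezoid(Ib, q)
                if area <= 0:
                    return np.inf
                curve = (self.monomer_fraction * mono
                         + (1.0 - self.monomer_fraction) * Ib / area)
            else:
                curve = Ib
            num = float(np.sum(Iexp * curve / sig ** 2))
            den = float(np.sum(curve ** 2 / sig ** 2))
            c = num / den if den > 0 else 0.0
            r = (Iexp - c * curve) / sig
            return float((r ** 2).sum() / dof)

        def _energy(chi2: float) -> float:
            loose = n_loose / max(len(sites), 1)
            return chi2 + alpha * loose

        # calibrate the compactness weight on the initial configuration
        chi2_0 = _chi2()
        alpha = 10.0 * max(chi2_0, 1.0)

        # propose a flip; returns affected sites or None if infeasible
        def _propose() -> list[tuple] | None:
            if rng.random() < 0.5 and len(sites) > 2:
                s = sites[int(rng.integers(len(sites)))]
            else:
                base = sites[int(rng.integers(len(sites)))]
                d = _NEIGHBORS26_T[int(rng.integers(26))]
                s = (base[0] + d[0], base[1] + d[1], base[2] + d[2])
                if s in occ_set or s not in lattice:
                    return None
            group = [s]
            if self.symmetry == "P2":
                m = self._mate(s)
                if m != s:
                    group.append(m)
            return group

        def _apply(group: list[tuple]) -> bool:
            """Toggle the group; return False (and revert) if infeasible."""
            adding = group[0] not in occ_set
            done = []
            ok = True
            for s in group:
                if adding:
                    if s in occ_set or s not in lattice:
                        ok = False
                        break
                    has_support = any(
                        (s[0] + d[0], s[1] + d[1], s[2] + d[2]) in occ_set
                        for d in _NEIGHBORS26_T) or any(
                        g in occ_set for g in group if g != s)
                    if not has_support:
                        ok = False
                        break
                    _add(s)
                    done.append(s)
                else:
                    if s not in occ_set or len(sites) <= 2:
                        ok = False
                        break
                    if not _locally_safe_removal(occ_set, s):
                        occ_set.discard(s)
                        still = _connected(occ_set)
                        occ_set.add(s)
                        if not still:
                            ok = False
                            break
                    _remove(s)
                    done.append(s)
            if not ok:
                for s in reversed(done):
                    (_remove if adding else _add)(s)
                return False
            return True

        def _revert(group: list[tuple], was_adding: bool) -> None:
            for s in reversed(group):
                (_remove if was_adding else _add)(s)

        # T0 calibration from uphill trial moves
        chi2_cur = chi2_0
        e_cur = _energy(chi2_cur)
        uphill = []
        for _ in range(60):
            g = _propose()
            if g is None:
                continue
            adding = g[0] not in occ_set
            if _apply(g):
                de = _energy(_chi2()) - e_cur
                _revert(g, adding)
                if de > 0:
                    uphill.append(de)
        t = (float(np.median(uphill)) / -np.log(sch.initial_acceptance)
             if uphill else 1.0)

        best_occ = set(occ_set)
        best_e = e_cur
        best_chi2 = chi2_cur
        energy_history = [e_cur]
        stall = 0
        for _step in range(sch.max_steps):
            improved = False
            for _ in range(sch.flips_per_step):
                g = _propose()
                if g is None:
                    continue
                adding = g[0] not in occ_set
                if not _apply(g):
                    continue
                chi2_new = _chi2()
                e_new = _energy(chi2_new)
                de = e_new - e_cur
                if de <= 0 or rng.random() < np.exp(-de / max(t, 1e-12)):
                    e_cur, chi2_cur = e_new, chi2_new
                    if e_cur < best_e - 1e-12:
                        best_e, best_chi2 = e_cur, chi2_cur
                        best_occ = set(occ_set)
                        improved = True
                else:
                    _revert(g, adding)
            energy_history.append(e_cur)
            t *= sch.cooling
            stall = 0 if improved else stall + 1
            if stall >= sch.patience:
                break

        model = BeadModel(occupied=frozenset(best_occ), spacing=a,
                          bead_radius=self.bead_radius,
                          symmetry=self.symmetry,
                          search_radius=self.search_radius)
        return BeadReconstructionResult(
            model=model, chi=float(np.sqrt(best_chi2)),
            energy=best_e, alpha_compact=alpha, seed=seed,
            chi_initial=float(np.sqrt(chi2_0)),
            energy_history=np.asarray(energy_history),
        )


@dataclass(frozen=True)
class BeadReconstructionResult:
    """Outcome of a bead-model annealing run."""

    model: BeadModel
    chi: float
    energy: float
    alpha_compact: float
    seed: int
    chi_initial: float
    energy_history: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        return (f"beads = {len(self.model)}  chi = {self.chi:.4g}  "
                f"(initial {self.chi_initial:.4g}, seed {self.seed}, "
                f"{self.model.symmetry})")


def reconstruct(data: ScatteringProfile, bead_radius: float,
                search_radius: float, symmetry: str = "P1",
                monomer_fraction: float = 0.0,
                monomer_curve: ScatteringProfile | None = None,
                seed: int = 0,
                schedule: AnnealingSchedule | None = None) -> BeadModel:
    """Functional wrapper around :class:`BeadReconstruction`; returns the
    bead model only (use the class for diagnostics)."""
    rec = BeadReconstruction(data, bead_radius, search_radius,
                             symmetry=symmetry,
                             monomer_fraction=monomer_fraction,
                             monomer_curve=monomer_curve, schedule=schedule)
    return rec.fit(seed=seed).model


# ---------------------------------------------------------------------------
# NSD and averaging
# ---------------------------------------------------------------------------

def _as_positions(m) -> np.ndarray:
    if isinstance(m, BeadModel):
        return m.positions()
    if isinstance(m, CoordinateModel):
        return m.positions
    return np.atleast_2d(np.asarray(m, dtype=float))


def _nn_distance(X: np.ndarray) -> float:
    tree = cKDTree(X)
    d, _ = tree.query(X, k=2)
    return float(d[:, 1].mean())


def _nsd_value(A: np.ndarray, B: np.ndarray, dA: float, dB: float) -> float:
    ta, tb = cKDTree(A), cKDTree(B)
    d_ab, _ = tb.query(A, k=1)   # min over b for each a
    d_ba, _ = ta.query(B, k=1)
    term1 = (d_ab ** 2).sum() / (len(A) * dB ** 2)
    term2 = (d_ba ** 2).sum() / (len(B) * dA ** 2)
    return float(np.sqrt(0.5 * (term1 + term2)))


def _principal_axes(X: np.ndarray) -> np.ndarray:
    c = X.mean(0)
    cov = np.cov((X - c).T)
    w, V = np.linalg.eigh(cov)
    V = V[:, ::-1]          # descending eigenvalues
    if np.linalg.det(V) < 0:
        V[:, 2] *= -1
    return V


def nsd(a, b, alignment: str = "principal_axes") -> NsdReport:
    """Normalised spatial discrepancy between two point models.

    NSD(A, B) = sqrt( 1/2 [ (1/(N_A d_B^2)) sum_i min_j |a_i - b_j|^2
                          + (1/(N_B d_A^2)) sum_j min_i |b_j - a_i|^2 ] ),

    with d the mean nearest-neighbour distance within each set.  With
    ``alignment="principal_axes"`` both sets are centred, the second is
    rotated into the first's principal frame, and all four proper
    axis-sign combinations are tried; the minimum NSD and the applied
    transform are reported.
    """
    if alignment not in ("principal_axes", "none"):
        raise ValueError("alignment must be 'principal_axes' or 'none'")
    A = _as_positions(a)
    B = _as_positions(b)
    if len(A) < 2 or len(B) < 2:
        raise DegenerateModelError(
            "NSD needs >= 2 points per model (nearest-neighbour distance "
            "is undefined otherwise)")
    dA, dB = _nn_distance(A), _nn_distance(B)
    if alignment == "none":
        return NsdReport(nsd=_nsd_value(A, B, dA, dB),
                         rotation=np.eye(3), translation=np.zeros(3))
    ca, cb = A.mean(0), B.mean(0)
    Va, Vb = _principal_axes(A), _principal_axes(B)
    best = None
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = Va @ np.diag(signs) @ Vb.T
        B2 = (B - cb) @ R.T + ca
        val = _nsd_value(A, B2, dA, dB)
        if best is None or val < best[0]:
            best = (val, R)
    val, R = best
    return NsdReport(nsd=val, rotation=R, translation=ca - R @ cb)


def average_filter(models: list[BeadModel],
                   occupancy_cutoff: float = 0.5) -> BeadModel:
    """Average a set of reconstructions into a filtered consensus model.

    All models are aligned (principal axes, four proper sign choices)
    to the reference with the lowest mean pairwise NSD, their beads are
    snapped onto the reference lattice, and beads present in at least
    ``occupancy_cutoff`` of the models are retained.  Components tied
    for the largest 26-connected size are all kept.  Models with fewer
    than 2 beads skip alignment (NSD is degenerate there).
    """
    if len(models) < 2:
        raise ValueError("need at least two models to average")
    spacings = {round(m.spacing, 9) for m in models}
    if len(spacings) != 1:
        raise ValueError("models must share one lattice spacing")
    alignable = all(len(m) >= 2 for m in models)

    if alignable:
        n = len(models)
        pair = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                v = nsd(models[i], models[j]).nsd
                pair[i, j] = pair[j, i] = v
        ref_i = int(np.argmin(pair.sum(1) / (n - 1)))
    else:
        ref_i = 0
    ref = models[ref_i]
    a = ref.spacing

    counts: dict = {}
    for m in models:
        if m is ref or not alignable:
            pos = m.positions()
        else:
            rep = nsd(ref, m)
            pos = m.positions() @ rep.rotation.T + rep.translation
        ijk = np.round((pos - ref.lattice_origin) / a).astype(int)
        for s in {tuple(v) for v in ijk}:
            counts[s] = counts.get(s, 0) + 1

    thr = occupancy_cutoff * len(models)
    kept = {s for s, c in counts.items() if c >= thr - 1e-9}
    if not kept:
        warnings.warn("occupancy cutoff removed all beads", stacklevel=2)
        return BeadModel(occupied=frozenset(), spacing=a,
                         bead_radius=ref.bead_radius,
                         lattice_origin=ref.lattice_origin)
    comps = _components(kept)
    nmax = max(len(c) for c in comps)
    final = set().union(*(c for c in comps if len(c) == nmax))
    return BeadModel(occupied=frozenset(final), spacing=a,
                     bead_radius=ref.bead_radius,
                     lattice_origin=ref.lattice_origin,
                     search_radius=ref.search_radius)


def _components(occ: set) -> list[set]:
    left = set(occ)
    out = []
    while left:
        start = next(iter(left))
        seen = {start}
        queue = deque([start])
        while queue:
            s = queue.popleft()
            for d in _NEIGHBORS26_T:
                t = (s[0] + d[0], s[1] + d[1], s[2] + d[2])
                if t in left and t not in seen:
                    seen.add(t)
                    queue.append(t)
        out.append(seen)
        left -= seen
    return out
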