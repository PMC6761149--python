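"""Synthetic SAXS phantoms with known ground truth.

The generators emulate the experimental situation the package is built
for: a compact ~38 kDa monomer whose last ~31 residues form a flexible
protruding tail, a two-fold-symmetric dimer of that monomer, and
concentration-dependent monomer/dimer mixtures with counting-like
noise.  Analytic reference curves (homogeneous sphere, Gaussian chain)
are provided in closed form for oracle tests.

All generators record their parameters and seed in the output profile
metadata, and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .debye import debye_curve
from .ensemble import _grow_segment
from .profiles import CoordinateModel, ScatteringProfile

__all__ = [
    "PhantomSpec", "default_q_grid", "sphere_curve", "gaussian_chain_curve",
    "ball_model", "core_plus_tail_model", "dimer_model", "dimer_curve",
    "mixture_series", "add_noise",
]


def default_q_grid(qmin: float = 0.005, qmax: float = 0.5,
                   n: int = 120) -> np.ndarray:
    """The package's default measurement grid, 1/A."""
    return np.linspace(qmin, qmax, n)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic dataset.

    The defaults mirror the study conditions the package emulates: a
    285-residue globular core with a 31-residue flexible C-terminal
    tail as the monomer, its two-fold-symmetric dimer, a 0.5-7 mg/ml
    concentration series, ~2% counting noise, and a low-micromolar-like
    association constant K (mg/ml units) for the binding isotherm
    w(c) = c / (c + K).
    """

    kind: str = "monomer_dimer_series"
    radius: float = 22.0                  # sphere/core radius, A
    separation: float = 40.0              # dimer centre separation, A
    rg: float = 25.0                      # gaussian_chain Rg, A
    n_core: int = 285                     # residues in the globular core
    n_tail: int = 31                      # residues in the flexible tail
    dimer_fraction: float = 0.42
    concentrations: tuple = (0.5, 1.0, 2.0, 5.0, 7.0)
    K: float = 5.0                        # isotherm constant, mg/ml
    noise_level: float = 0.02             # fractional sigma at I(0)
    seed: int = 0

    def __post_init__(self):
        kinds = ("sphere", "dumbbell", "gaussian_chain", "core_plus_tail",
                 "monomer_dimer_series")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if min(self.radius, self.separation, self.rg) <= 0:
            raise ValueError("lengths must be > 0")
        if not 0 <= self.dimer_fraction <= 1:
            raise ValueError("dimer_fraction must be in [0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def sphere_curve(R: float, I0: float, q_grid: np.ndarray) -> ScatteringProfile:
    """Exact homogeneous-sphere curve I = I0 [3 (sin x - x cos x)/x^3]^2.

    x = qR; the q -> 0 limit is I0 and the form factor's first zero sits
    at x ~ 4.4934 (the first root of tan x = x).
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    q = np.asarray(q_grid, dtype=float)
    x = q * R
    amp = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[~small]
    amp[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    amp[small] = 1.0 - x[small] ** 2 / 10.0
    return ScatteringProfile(q=q, I=I0 * amp ** 2, label=f"sphere(R={R})",
                             meta={"kind": "sphere", "R": R, "I0": I0})


def gaussian_chain_curve(Rg: float, I0: float,
                         q_grid: np.ndarray) -> ScatteringProfile:
    """Debye Gaussian-chain curve I = I0 * 2 (e^-x - 1 + x)/x^2, x = q^2 Rg^2."""
    if Rg <= 0:
        raise ValueError("Rg must be > 0")
    q = np.asarray(q_grid, dtype=float)
    x = (q * Rg) ** 2
    I = np.empty_like(x)
    small = x < 1e-6
    xs = x[~small]
    I[~small] = 2.0 * (np.expm1(-xs) + xs) / xs ** 2
    I[small] = 1.0 - x[small] / 3.0
    return ScatteringProfile(q=q, I=I0 * I, label=f"gchain(Rg={Rg})",
                             meta={"kind": "gaussian_chain", "Rg": Rg, "I0": I0})


def ball_model(R: float, n_sites: int, seed: int,
               weight: float = 1.0) -> CoordinateModel:
    """Uniform random point sample inside a ball of radius R (A)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_sites, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = R * rng.random(n_sites) ** (1.0 / 3.0)
    return CoordinateModel(positions=v * r[:, None],
                           weights=np.full(n_sites, weight),
                           label=f"ball(R={R},n={n_sites})")


def core_plus_tail_model(n_core: int = 285, core_radius: float = 17.5,
                         n_tail: int = 31, seed: int = 0) -> CoordinateModel:
    """Monomer stand-in: globular core plus flexible C-terminal tail.

    The core is a uniform ball sample (one site per residue); the tail
    is a self-avoiding 3.8 A-step walk anchored at the core surface,
    emulating a protruding, partially ordered C-terminal extension.
    """
    rng = np.random.default_rng(seed)
    core = ball_model(core_radius, n_core, seed=int(rng.integers(2 ** 31)))
    anchor_idx = int(np.argmax(core.positions[:, 0]))
    anchor = core.positions[anchor_idx]
    tail = _grow_segment(anchor, n_tail, core.positions,
                         np.random.default_rng(int(rng.integers(2 ** 31))))
    pos = np.vstack([core.positions, tail])
    return CoordinateModel(positions=pos, weights=np.ones(len(pos)),
                           label=f"core_plus_tail(n={n_core}+{n_tail})")


def dimer_model(monomer: CoordinateModel, separation: float,
                axis=(0.0, 0.0, 1.0)) -> CoordinateModel:
    """Two-fold-symmetric dimer: the centred monomer and its 180-degree
    copy about ``axis``, centres ``separation`` A apart along a
    perpendicular direction (so the assembly has exact C2 symmetry)."""
    if separation <= 0:
        raise ValueError("separation must be > 0")
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    # any unit vector perpendicular to the symmetry axis
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ u) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = trial - (trial @ u) * u
    perp /= np.linalg.norm(perp)

    m = monomer.centered()
    # Rodrigues for a 180-degree rotation: R = 2 u u^T - I
    R = 2.0 * np.outer(u, u) - np.eye(3)
    copy1 = m.transformed(translation=0.5 * separation * perp)
    copy2 = m.transformed(rotation=R).transformed(
        translation=-0.5 * separation * perp)
    dimer = CoordinateModel.concatenate([copy1, copy2],
                                        label=f"dimer({monomer.label})")
    from scipy.spatial import cKDTree
    d, _ = cKDTree(copy2.positions).query(copy1.positions, k=1)
    if d.min() < 1.0:
        warnings.warn("dimer copies approach closer than 1 A", stacklevel=2)
    return dimer


def dimer_curve(monomer: CoordinateModel, separation: float,
                axis=(0.0, 0.0, 1.0), q_grid: np.ndarray | None = None
                ) -> tuple[CoordinateModel, ScatteringProfile]:
    """Build the C2 dimer of ``monomer`` and its Debye curve.

    At q = 0 the dimer intensity is (2 W)^2, four times the monomer's.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    model = dimer_model(monomer, separation, axis)
    curve = debye_curve(model, q_grid)
    return model, curve


def add_noise(curve: ScatteringProfile, noise_level: float,
              seed: int) -> ScatteringProfile:
    """Counting-like Gaussian noise with a 1%-of-scale variance floor.

    sigma(q) = noise_level * I(0) * sqrt(I(q)/I(0) + 0.01); intensities
    are perturbed by centred Gaussians of that width.  At
    ``noise_level = 0`` the intensities are untouched and the sigma
    column holds the floor values at a vanishing effective level.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    I0 = float(curve.I[0]) if curve.q[0] == 0 else float(np.max(curve.I))
    if I0 <= 0:
        I0 = max(float(np.max(np.abs(curve.I))), 1.0)
    level = noise_level if noise_level > 0 else 1e-8
    sigma = level * I0 * np.sqrt(np.clip(curve.I / I0, 0, None) + 0.01)
    rng = np.random.default_rng(seed)
    I = curve.I + (rng.normal(size=len(curve)) * sigma
                   if noise_level > 0 else 0.0)
    meta = dict(curve.meta)
    meta.update({"noise_level": noise_level, "noise_seed": seed})
    return curve.replace(I=I, sigma=sigma, meta=meta)


def mixture_series(spec: PhantomSpec,
                   q_grid: np.ndarray | None = None) -> list[ScatteringProfile]:
    """Concentration series of monomer/dimer mixtures with ground truth.

    Per concentration c the dimer weight fraction follows the binding
    isotherm w(c) = c/(c + K) and the per-unit-mass intensity is

        I = (1 - w) I_mono + (w/2) I_dimer,

    so the apparent mass from I(0) interpolates between M and 2M; the
    whole curve is then scaled by c and perturbed by ``add_noise``.
    The true fractions are recorded in the metadata of each profile.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "sphere":
        mono = ball_model(spec.radius, 300, seed=int(rng.integers(2 ** 31)))
    else:
        mono = core_plus_tail_model(n_core=spec.n_core, n_tail=spec.n_tail,
                                    seed=int(rng.integers(2 ** 31)))
    I_mono = debye_curve(mono, q_grid).I
    _, dim_curve = dimer_curve(mono, spec.separation, q_grid=q_grid)
    I_dimer = dim_curve.I

    out = []
    for c in spec.concentrations:
        w = c / (c + spec.K) if np.isfinite(spec.K) else 0.0
        I = c * ((1.0 - w) * I_mono + 0.5 * w * I_dimer)
        prof = ScatteringProfile(
            q=q_grid, I=I, concentration=c,
            label=f"mix(c={c})",
            meta={"spec": asdict(spec), "true_dimer_fraction": float(w),
                  "concentration": c, "seed": spec.seed},
        )
        out.append(add_noise(prof, spec.noise_level,
                             seed=int(rng.integers(2 ** 31))))
    return out
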