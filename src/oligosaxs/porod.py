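"""Porod invariant, Porod volume, and mass / oligomer-fraction estimates.

The Porod invariant Q = int q^2 I(q) dq links the scattered intensity to
the particle volume through Vp = 2 pi^2 I(0) / Q for a uniform-density
particle.  Multiplying Vp (A^3) by the average protein density expressed
as 0.588 Da/A^3 gives an apparent molecular mass.  Comparing an apparent
mass against the monomer mass from chemical composition, and assuming a
pure monomer/dimer mixture, the dimer weight fraction is

    w = clip(M_apparent / M_monomer - 1, 0, 1),

since a mixture of weight fraction w of dimers has apparent (weight-
averaged) mass (1-w)*M + 2*w*M = (1+w)*M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import IntegrationError
from .profiles import ScatteringProfile

__all__ = [
    "PorodResult", "MassEstimate",
    "porod_volume", "mass_from_porod", "oligomer_fraction", "mass_from_i0",
]

#: average protein density expressed in Da per cubic Angstrom
PROTEIN_DENSITY_DA_PER_A3 = 0.588


@dataclass(frozen=True)
class PorodResult:
    """Porod invariant and derived volume."""

    Q_invariant: float          # int q^2 I dq, units I * A^-3
    Vp: float                   # Porod volume, A^3
    q_range_used: tuple[float, float]
    tail_extrapolated: bool

    def summary(self) -> str:
        return (
            "Porod analysis\n"
            "--------------\n"
            f"Q invariant : {self.Q_invariant:.6g} I*A^-3\n"
            f"Vp          : {self.Vp:,.0f} A^3\n"
            f"q range     : [{self.q_range_used[0]:.5f}, {self.q_range_used[1]:.5f}] 1/A"
            f"{' + q^-4 tail' if self.tail_extrapolated else ''}"
        )


@dataclass(frozen=True)
class MassEstimate:
    """Apparent mass and implied monomer/dimer composition."""

    M: float                 # apparent molecular mass, Da
    M_monomer_ref: float     # theoretical monomer mass, Da
    dimer_fraction: float    # weight fraction of dimer, [0, 1]
    source: str              # 'porod_volume' or 'forward_scattering'

    @property
    def dimer_percent(self) -> float:
        """Dimer content in percent, one decimal (reporting convention)."""
        return round(100.0 * self.dimer_fraction, 1)

    def summary(self) -> str:
        return (
            f"apparent M = {self.M:,.0f} Da (from {self.source}); "
            f"monomer M = {self.M_monomer_ref:,.0f} Da; "
            f"dimer content = {self.dimer_percent:.1f}%"
        )


def porod_volume(profile: ScatteringProfile, I0: float,
                 tail_power_law: bool = True) -> PorodResult:
    """Porod volume Vp = 2 pi^2 I0 / Q from the invariant Q = int q^2 I dq.

    Q is computed by trapezoidal integration on the measured grid.  With
    ``tail_power_law`` the integral is extended analytically beyond qmax
    assuming Porod's law I(q) = I(qmax) (qmax/q)^4, whose contribution is
    exactly I(qmax) * qmax^3.  A warning is issued when q^4 I is not
    approximately flat at the high-q end (Porod regime not reached).
    """
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    q, I = profile.q, profile.I
    Q = float(np.trapezoid(q ** 2 * I, q))
    # close the integral at the low-q end assuming I ~ I0 there
    Q += float(I0 * q[0] ** 3 / 3.0)
    if tail_power_law:
        # Porod's law I = K / q^4 gives int_{qmax}^inf q^2 I dq = K / qmax;
        # K is estimated as the average of q^4 I over the trailing tenth of
        # the grid (robust to single-point noise at the weakest intensities)
        ntail = max(len(q) // 10, 1)
        K = float(np.mean(q[-ntail:] ** 4 * I[-ntail:]))
        Q += K / q[-1]
    if Q <= 0:
        raise IntegrationError("Porod invariant integrated to a non-positive value")

    # Porod-regime check: q^4 I over the last 20% of the grid
    ntail = max(len(q) // 5, 3)
    p4 = q[-ntail:] ** 4 * I[-ntail:]
    mean_p4 = p4.mean()
    if mean_p4 <= 0 or np.ptp(p4) > 2.0 * abs(mean_p4):
        warnings.warn(
            "q^4*I(q) is not approximately constant at the high-q end; "
            "the Porod regime may not be reached and Vp may be biased",
            stacklevel=2,
        )
    Vp = float(2.0 * np.pi ** 2 * I0 / Q)
    return PorodResult(Q_invariant=Q, Vp=Vp,
                       q_range_used=(float(q[0]), float(q[-1])),
                       tail_extrapolated=tail_power_law)


def mass_from_porod(Vp: float,
                    density_factor: float = PROTEIN_DENSITY_DA_PER_A3) -> int:
    """Apparent molecular mass in Da from a Porod volume in A^3.

    Uses the average protein density expressed as 0.588 Da/A^3; the
    result is rounded to the nearest Dalton.
    """
    if Vp < 0:
        raise ValueError("Vp must be >= 0")
    return int(round(density_factor * Vp))


def oligomer_fraction(M_apparent: float, M_monomer: float,
                      source: str = "porod_volume") -> MassEstimate:
    """Dimer weight fraction implied by an apparent mass.

    Assumes only monomers and dimers contribute, so the weight-averaged
    mass is (1 + w) * M_monomer and w = M_apparent/M_monomer - 1,
    clipped to the physical interval [0, 1].
    """
    if M_monomer <= 0:
        raise ValueError("M_monomer must be > 0")
    if M_apparent < 0:
        raise ValueError("M_apparent must be >= 0")
    w = float(np.clip(M_apparent / M_monomer - 1.0, 0.0, 1.0))
    return MassEstimate(M=float(M_apparent), M_monomer_ref=float(M_monomer),
                        dimer_fraction=w, source=source)


def mass_from_i0(I0: float, concentration: float, k_cal: float) -> float:
    """Apparent mass from absolute forward scattering, M = k_cal * I0 / c.

    Requires the instrument/contrast calibration constant ``k_cal``
    (Da * mg/ml per intensity unit); on an absolute scale it collects
    the contrast and Avogadro factors of the standard expression
    I(0)/c = M * (delta-rho * v)^2 / N_A.
    """
    if concentration <= 0 or k_cal <= 0:
        raise ValueError("concentration and k_cal must be > 0")
    return float(k_cal * I0 / concentration)
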