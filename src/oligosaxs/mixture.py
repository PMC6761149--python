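"""Decomposition of a measured curve into non-negative component
fractions (monomer/dimer form-factor fitting).

For a dilute mixture of k non-interacting species the measured curve is
a non-negative combination of the component form factors:

    I(q) = c * sum_k f_k I_k(q)  (+ b),   f_k >= 0,  sum f_k = 1.

The amplitudes are found by sigma-weighted bounded least squares (the
additive constant, when enabled, is unbounded) and renormalised to
fractions with the overall scale factored out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .debye import FitResult, fit_to_profile
from .exceptions import GridError
from .profiles import ScatteringProfile

__all__ = ["MixtureResult", "Mixture", "fit_mixture"]


@dataclass(frozen=True)
class MixtureResult:
    """Non-negative volume-fraction decomposition of a curve."""

    fractions: np.ndarray     # per component, >= 0, sum to 1
    scale_c: float
    constant_b: float
    chi: float
    n_points: int
    assumed_sigma: bool = False

    def summary(self) -> str:
        fr = ", ".join(f"{f:.3f}" for f in self.fractions)
        return (f"fractions = [{fr}]  chi = {self.chi:.4g}  "
                f"(c = {self.scale_c:.6g}, b = {self.constant_b:.6g})")


class Mixture:
    """Mixture model: data as a non-negative combination of components.

    Parameters
    ----------
    data : ScatteringProfile
    components : list of ScatteringProfile
        Component form factors, interpolated onto the data grid when
        necessary.
    """

    def __init__(self, data: ScatteringProfile,
                 components: list[ScatteringProfile]):
        if not components:
            raise ValueError("need at least one component")
        self.data = data
        self.components = components

    def fit(self, subtract_constant: bool = False) -> MixtureResult:
        data = self.data
        comps = []
        for c in self.components:
            if len(c) == len(data) and np.allclose(c.q, data.q):
                comps.append(c.I)
            else:
                if c.q[0] > data.q[0] + 1e-12 or c.q[-1] < data.q[-1] - 1e-12:
                    raise GridError(
                        f"component {c.label!r} does not cover the data grid")
                comps.append(c.interpolated(data.q).I)
        C = np.column_stack(comps)
        if np.all(np.abs(C) < 1e-300):
            raise GridError("degenerate design: all components are zero")

        assumed = data.sigma is None
        sig = np.ones_like(data.I) if assumed else data.sigma
        k = C.shape[1]
        cols = [C / sig[:, None]]
        if subtract_constant:
            cols.append((1.0 / sig)[:, None])
        A = np.hstack(cols)
        b = data.I / sig
        lb = np.r_[np.zeros(k), -np.inf] if subtract_constant else np.zeros(k)
        ub = np.full(A.shape[1], np.inf)
        sol = scipy.optimize.lsq_linear(A, b, bounds=(lb, ub), method="bvls",
                                        tol=1e-14)
        amp = sol.x[:k]
        const = float(sol.x[k]) if subtract_constant else 0.0
        total = float(amp.sum())
        if total <= 0:
            fractions = np.full(k, 1.0 / k)
            total = 0.0
        else:
            fractions = amp / total
        resid = b - A @ sol.x
        p = k + (1 if subtract_constant else 0)
        dof = max(len(b) - p, 1)
        chi = float(np.sqrt((resid ** 2).sum() / dof))
        return MixtureResult(fractions=fractions, scale_c=total,
                             constant_b=const, chi=chi, n_points=len(b),
                             assumed_sigma=assumed)

    def single_component_fit(self, index: int,
                             subtract_constant: bool = False) -> FitResult:
        """Scale fit of one component alone (for nesting comparisons)."""
        return fit_to_profile(self.components[index], self.data,
                              subtract_constant)


def fit_mixture(data: ScatteringProfile, components: list[ScatteringProfile],
                subtract_constant: bool = False) -> MixtureResult:
    """Functional wrapper around :class:`Mixture`."""
    return Mixture(data, components).fit(subtract_constant=subtract_constant)
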