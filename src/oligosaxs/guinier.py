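"""Guinier analysis and the Kratky transform.

At low momentum transfer every compact particle scatters as

    I(q) = I(0) * exp(-q^2 Rg^2 / 3),

so ln I is linear in q^2 with slope -Rg^2/3.  The approximation holds
for q*Rg below about 1.3 for globular particles.  :class:`Guinier` fits
this law over an automatically selected low-q window; the selection rule
scans all contiguous windows of at least ``min_points`` points, keeps
those that are self-consistent (qmax*Rg <= qRg_limit and
qmin*Rg <= 0.65, negative slope), and picks the longest, breaking ties
by weighted R^2.  Points suspected of aggregation effects can be skipped
with ``skip_low_q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NoGuinierRegionError
from .profiles import ScatteringProfile

__all__ = ["Guinier", "GuinierResult", "guinier_fit", "kratky_transform"]

#: upper self-consistency bound on qmin*Rg for the fitted window
_QMIN_RG_LIMIT = 0.65


@dataclass(frozen=True)
class GuinierResult:
    """Result of a Guinier fit."""

    Rg: float            # radius of gyration, A
    I0: float            # extrapolated forward scattering, profile units
    Rg_err: float
    I0_err: float
    q_window: tuple[float, float]   # [qmin, qmax] actually fitted, 1/A
    n_points: int
    fit_r2: float
    qRg_limit: float

    @property
    def qmax_rg(self) -> float:
        return self.q_window[1] * self.Rg

    def summary(self) -> str:
        lines = [
            "Guinier fit",
            "-----------",
            f"Rg        : {self.Rg:10.3f} +/- {self.Rg_err:.3f} A",
            f"I(0)      : {self.I0:10.6g} +/- {self.I0_err:.3g}",
            f"q window  : [{self.q_window[0]:.5f}, {self.q_window[1]:.5f}] 1/A"
            f"  ({self.n_points} pts)",
            f"qmax*Rg   : {self.qmax_rg:10.3f}  (limit {self.qRg_limit})",
            f"R^2       : {self.fit_r2:10.5f}",
        ]
        return "\n".join(lines)


class Guinier:
    """Guinier model for a scattering profile.

    Parameters
    ----------
    profile : ScatteringProfile
        Curve to analyse.  Points with I <= 0 are excluded from window
        candidates.

    Examples
    --------
    >>> res = Guinier(profile).fit()
    >>> res.Rg, res.I0
    """

    def __init__(self, profile: ScatteringProfile):
        self.profile = profile

    def fit(self, qRg_limit: float = 1.3, skip_low_q: int = 0,
            min_points: int = 5) -> GuinierResult:
        p = self.profile
        if skip_low_q < 0:
            raise ValueError("skip_low_q must be >= 0")
        q = p.q[skip_low_q:]
        I = p.I[skip_low_q:]
        sig = None if p.sigma is None else p.sigma[skip_low_q:]

        pos = I > 0
        # restrict to the leading positive run: the Guinier window must be
        # contiguous from the low-q side of the usable data
        if not pos.any():
            raise NoGuinierRegionError("no positive intensities")
        q, I = q[pos], I[pos]
        if sig is not None:
            sig = sig[pos]

        x = q ** 2
        y = np.log(I)
        # weights for ln I: sigma_lnI = sigma / I
        w = np.ones_like(y) if sig is None else (I / sig) ** 2

        n = len(x)
        # prefix sums for O(1) weighted fits on any window
        W = np.concatenate([[0.0], np.cumsum(w)])
        Sx = np.concatenate([[0.0], np.cumsum(w * x)])
        Sy = np.concatenate([[0.0], np.cumsum(w * y)])
        Sxx = np.concatenate([[0.0], np.cumsum(w * x * x)])
        Sxy = np.concatenate([[0.0], np.cumsum(w * x * y)])
        Syy = np.concatenate([[0.0], np.cumsum(w * y * y)])

        best = None  # (length, r2, -i, i, j, slope, intercept)
        # Anchor the search to the low-q decay: beyond a fifty-fold intensity
        # drop the Guinier law is long invalid (qRg > 3), and oscillatory
        # tails would otherwise admit spuriously long flat windows.
        below = np.flatnonzero(I < I[0] / 50.0)
        nmax = min(n, int(below[0]) if below.size else n, 1000)
        if nmax < min_points:
            nmax = min(n, 1000)
        for i in range(0, nmax - min_points + 1):
            j = np.arange(i + min_points, nmax + 1)  # window is [i, j)
            Wij = W[j] - W[i]
            sx = Sx[j] - Sx[i]
            sy = Sy[j] - Sy[i]
            sxx = Sxx[j] - Sxx[i]
            sxy = Sxy[j] - Sxy[i]
            syy = Syy[j] - Syy[i]
            det = Wij * sxx - sx * sx
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = np.where(det > 0, (Wij * sxy - sx * sy) / det, np.nan)
                rg = np.sqrt(np.clip(-3.0 * slope, 0, None))
                ok = ((det > 0) & (slope < 0)
                      & (q[j - 1] * rg <= qRg_limit)
                      & (q[i] * rg <= _QMIN_RG_LIMIT))
            if not ok.any():
                continue
            jj = j[ok][-1]  # longest admissible window for this start
            Wij = W[jj] - W[i]
            sx, sy = Sx[jj] - Sx[i], Sy[jj] - Sy[i]
            sxx, sxy = Sxx[jj] - Sxx[i], Sxy[jj] - Sxy[i]
            syy = Syy[jj] - Syy[i]
            det = Wij * sxx - sx * sx
            sl = (Wij * sxy - sx * sy) / det
            intercept = (sy - sl * sx) / Wij
            ss_tot = syy - sy * sy / Wij
            ss_res = max(syy - intercept * sy - sl * sxy, 0.0)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            cand = (jj - i, r2, -i, i, jj, sl, intercept)
            if best is None or cand[:3] > best[:3]:
                best = cand
        if best is None:
            raise NoGuinierRegionError(
                "no admissible Guinier window (negative slope with "
                f"qmax*Rg <= {qRg_limit}) was found"
            )
        _, r2, _, i, j, slope, intercept = best
        npts = j - i
        xi, yi, wi = x[i:j], y[i:j], w[i:j]

        # Refine on the selected window with a second-order term in q^2:
        # ln I = a + b q^2 + c q^4.  The linear law truncated at qRg ~ 1.3
        # carries a small systematic curvature (for a sphere, ~ -x^4/350);
        # reporting Rg from the q^2 coefficient of the quadratic removes
        # that truncation bias while staying exact for pure exponentials.
        A = np.column_stack([np.ones_like(xi), xi, xi * xi])
        Aw = A * np.sqrt(wi)[:, None]
        try:
            coef, *_ = np.linalg.lstsq(Aw, yi * np.sqrt(wi), rcond=None)
            cov = np.linalg.inv(Aw.T @ Aw)
            use_quad = coef[1] < 0
        except np.linalg.LinAlgError:
            use_quad = False
        if use_quad:
            intercept, slope = float(coef[0]), float(coef[1])
            resid = yi - A @ coef
            dof = max(npts - 3, 1)
            var_scale = float((wi * resid ** 2).sum() / dof)
            if sig is not None:
                var_scale = max(var_scale, 1.0)
            var_slope = var_scale * cov[1, 1]
            var_icept = var_scale * cov[0, 0]
        else:
            resid = yi - (intercept + slope * xi)
            dof = max(npts - 2, 1)
            var_scale = float((wi * resid ** 2).sum() / dof)
            if sig is not None:
                var_scale = max(var_scale, 1.0)
            Wij = W[j] - W[i]
            sx = Sx[j] - Sx[i]
            sxx = Sxx[j] - Sxx[i]
            det = Wij * sxx - sx * sx
            var_slope = var_scale * Wij / det
            var_icept = var_scale * sxx / det
        rg = float(np.sqrt(-3.0 * slope))
        rg_err = float(1.5 * np.sqrt(max(var_slope, 0.0)) / rg) if rg > 0 else np.nan
        i0 = float(np.exp(intercept))
        return GuinierResult(
            Rg=rg, I0=i0,
            Rg_err=rg_err, I0_err=float(i0 * np.sqrt(var_icept)),
            q_window=(float(q[i]), float(q[j - 1])),
            n_points=npts, fit_r2=float(r2), qRg_limit=qRg_limit,
        )

    def plot(self, result: GuinierResult | None = None, ax=None):
        """Guinier plot (ln I vs q^2) with the fitted window highlighted."""
        import matplotlib.pyplot as plt

        if result is None:
            result = self.fit()
        if ax is None:
            _, ax = plt.subplots()
        p = self.profile
        m = p.I > 0
        ax.plot(p.q[m] ** 2, np.log(p.I[m]), ".", ms=3, label="data")
        qf = np.linspace(*result.q_window, 50)
        ax.plot(qf ** 2, np.log(result.I0) - qf ** 2 * result.Rg ** 2 / 3.0,
                "-", label=f"fit Rg={result.Rg:.1f} A")
        ax.set_xlabel(r"$q^2$ ($\mathrm{\AA}^{-2}$)")
        ax.set_ylabel(r"$\ln I(q)$")
        ax.legend()
        return ax


def guinier_fit(profile: ScatteringProfile, qRg_limit: float = 1.3,
                skip_low_q: int = 0, min_points: int = 5) -> GuinierResult:
    """Functional wrapper around :class:`Guinier`."""
    return Guinier(profile).fit(qRg_limit=qRg_limit, skip_low_q=skip_low_q,
                                min_points=min_points)


def kratky_transform(profile: ScatteringProfile) -> ScatteringProfile:
    """Return the Kratky-transformed curve (q, I*q^2).

    Bell-shaped with an interior maximum for globular particles;
    plateaus at high q for disordered (Gaussian-chain-like) scatterers.
    """
    f = profile.q ** 2
    return profile.replace(
        I=profile.I * f,
        sigma=None if profile.sigma is None else np.where(f > 0, profile.sigma * f,
                                                          np.finfo(float).tiny),
        label=f"kratky({profile.label})",
    )
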