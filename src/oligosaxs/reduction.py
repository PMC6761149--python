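"""Concentration-series reduction: scaling, infinite-dilution extrapolation
and merging of low/high concentration q-ranges.

In a dilution series the normalised intensity I(q)/c depends linearly on
concentration to first order in the structure factor, so the ideal
single-particle curve is the intercept of a per-q linear regression of
I/c against c.  Low-concentration data is preferred at low q (weaker
inter-particle interference) and high-concentration data at high q
(better counting statistics); ``merge_ranges`` stitches the two after a
least-squares scale match over an overlap window.
"""

from __future__ import annotations

import numpy as np

from .exceptions import GridError, MergeError
from .profiles import ScatteringProfile

__all__ = ["scale_and_extrapolate", "merge_ranges"]


def _common_grid(profiles: list[ScatteringProfile]) -> np.ndarray:
    qmin = max(p.q[0] for p in profiles)
    qmax = min(p.q[-1] for p in profiles)
    if qmax <= qmin:
        raise GridError("profiles share no overlapping q range")
    base = profiles[0].q
    grid = base[(base >= qmin) & (base <= qmax)]
    if len(grid) < 5:
        raise GridError("overlapping q range holds fewer than 5 points")
    return grid


def scale_and_extrapolate(profiles: list[ScatteringProfile]) -> ScatteringProfile:
    """Divide each curve by its concentration and extrapolate to c = 0.

    With one profile the result is simply I/c.  With two or more, a
    per-q ordinary linear regression of I/c against c is evaluated at
    c = 0; regression standard errors propagate into sigma where at
    least three concentrations are available, otherwise sigma is
    propagated from the member uncertainties.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles:
        if p.concentration is None:
            raise ValueError(f"profile {p.label!r} has no concentration")

    if len(profiles) == 1:
        p = profiles[0]
        c = p.concentration
        return p.replace(I=p.I / c,
                         sigma=None if p.sigma is None else p.sigma / c,
                         concentration=None,
                         label=f"{p.label}/c")

    grid = _common_grid(profiles)
    conc = np.array([p.concentration for p in profiles])
    Y = np.vstack([p.interpolated(grid).I / p.concentration for p in profiles])
    S = None
    if all(p.sigma is not None for p in profiles):
        S = np.vstack([p.interpolated(grid).sigma / p.concentration for p in profiles])

    if np.ptp(conc) == 0:
        # All at one concentration: no slope identifiable, average.
        I0 = Y.mean(axis=0)
        sig = None if S is None else np.sqrt((S ** 2).sum(0)) / len(profiles)
        return ScatteringProfile(q=grid, I=I0, sigma=sig, label="extrapolated")

    # per-q regression I/c = a + b*c, intercept a is the c->0 curve
    n = len(conc)
    cbar = conc.mean()
    sxx = ((conc - cbar) ** 2).sum()
    b = ((conc - cbar)[:, None] * (Y - Y.mean(0))).sum(0) / sxx
    a = Y.mean(0) - b * cbar
    if n > 2:
        resid = Y - (a[None, :] + np.outer(conc, b))
        s2 = (resid ** 2).sum(0) / (n - 2)
        sig = np.sqrt(s2 * (1.0 / n + cbar ** 2 / sxx))
        sig = np.where(sig > 0, sig, np.nan)
        if np.any(~np.isfinite(sig)) or np.any(sig <= 0):
            sig = None
    elif S is not None:
        # exact two-point line: intercept is a linear combination
        w1 = conc[1] / (conc[1] - conc[0])
        w2 = -conc[0] / (conc[1] - conc[0])
        sig = np.sqrt((w1 * S[0]) ** 2 + (w2 * S[1]) ** 2)
    else:
        sig = None
    return ScatteringProfile(q=grid, I=a, sigma=sig, label="extrapolated")


def merge_ranges(low_q: ScatteringProfile, high_q: ScatteringProfile,
                 overlap: tuple[float, float]) -> ScatteringProfile:
    """Merge a low-q and a high-q curve with a scale match over ``overlap``.

    The high-q curve is scaled by the least-squares factor that matches
    it to the low-q curve over the overlap window; the output takes the
    low-q points below the overlap midpoint and the scaled high-q points
    above it.
    """
    qlo, qhi = overlap
    if qhi <= qlo:
        raise MergeError("overlap interval is empty")
    in_low = (low_q.q >= qlo) & (low_q.q <= qhi)
    in_high = (high_q.q >= qlo) & (high_q.q <= qhi)
    if in_low.sum() < 2 or in_high.sum() < 2:
        raise MergeError("overlap not contained in both profiles")

    q_ov = low_q.q[in_low]
    I_low = low_q.I[in_low]
    I_high = np.interp(q_ov, high_q.q, high_q.I)
    denom = (I_high ** 2).sum()
    if denom == 0:
        raise MergeError("high-q curve vanishes over the overlap")
    k = (I_low * I_high).sum() / denom

    mid = 0.5 * (qlo + qhi)
    keep_low = low_q.q <= mid
    keep_high = high_q.q > mid
    q = np.concatenate([low_q.q[keep_low], high_q.q[keep_high]])
    I = np.concatenate([low_q.I[keep_low], k * high_q.I[keep_high]])
    sigma = None
    if low_q.sigma is not None and high_q.sigma is not None:
        sigma = np.concatenate([low_q.sigma[keep_low], k * high_q.sigma[keep_high]])
    order = np.argsort(q)
    q, I = q[order], I[order]
    if sigma is not None:
        sigma = sigma[order]
    keep = np.concatenate([[True], np.diff(q) > 0])
    return ScatteringProfile(q=q[keep], I=I[keep],
                             sigma=None if sigma is None else sigma[keep],
                             label=f"merged({low_q.label}|{high_q.label})",
                             meta={"merge_scale": float(k)})
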