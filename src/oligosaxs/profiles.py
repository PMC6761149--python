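"""Scattering profiles and coordinate models: containers and file I/O.

The two in-memory containers used throughout the package live here:

* :class:`ScatteringProfile` — a measured or simulated SAXS curve
  ``I(q)`` with optional per-point uncertainties, always stored with the
  momentum transfer ``q`` in inverse Angstrom.
* :class:`CoordinateModel` — a set of point scatterers (atoms or residue
  centroids) with positions in Angstrom and per-site scattering weights.

File formats are the field's plain-text de facto standards: 2/3-column
ASCII ``.dat`` files for curves and PDB for coordinates (read through
gemmi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    EmptyStructureError,
    GridError,
    MalformedProfileError,
    ProfileOrderingError,
)

__all__ = [
    "ScatteringProfile",
    "CoordinateModel",
    "read_profile",
    "write_profile",
    "read_structure",
]

#: Minimum number of points for a usable scattering curve.
MIN_PROFILE_POINTS = 5

# Electron counts used as per-atom scattering weights in atomic mode.
_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "SE": 34,
              "FE": 26, "ZN": 30, "MG": 12, "CA": 20, "MN": 25, "CL": 17,
              "NA": 11, "K": 19}

# Displaced solvent volumes (A^3) per atom, Fraser-style values for the
# common protein elements; used as optional excluded-volume weights.
_DISPLACED_VOLUME = {"H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13,
                     "S": 19.86, "P": 5.73, "SE": 28.73, "FE": 7.99,
                     "ZN": 9.85, "MG": 9.0}

_DEFAULT_WEIGHT = 6.0  # carbon-like fallback for unknown elements


@dataclass(frozen=True)
class ScatteringProfile:
    """One-dimensional scattering curve I(q).

    Parameters
    ----------
    q : array
        Momentum transfer grid, inverse Angstrom, strictly increasing,
        all values >= 0.
    I : array
        Intensity, arbitrary units (or absolute cm^-1), finite.
    sigma : array, optional
        Per-point standard errors, same units and length as ``I``,
        strictly positive.
    concentration : float, optional
        Protein concentration in mg/ml for concentration-series work.
    label : str
        Free-text identifier carried through the pipeline.
    meta : dict
        Provenance metadata (generator spec, seeds, ...).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    concentration: float | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if q.ndim != 1 or I.shape != q.shape:
            raise MalformedProfileError("q and I must be 1-D arrays of equal length")
        if len(q) < MIN_PROFILE_POINTS:
            raise MalformedProfileError(
                f"profile needs >= {MIN_PROFILE_POINTS} points, got {len(q)}"
            )
        if np.any(q < 0) or not np.all(np.isfinite(q)):
            raise MalformedProfileError("q must be finite and non-negative")
        if np.any(np.diff(q) <= 0):
            raise ProfileOrderingError("q must be strictly increasing")
        if not np.all(np.isfinite(I)):
            raise MalformedProfileError("I must be finite everywhere")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise MalformedProfileError("sigma must match q in length")
            if np.any(~np.isfinite(s)) or np.any(s <= 0):
                raise MalformedProfileError("sigma must be finite and > 0")
        if self.concentration is not None and self.concentration <= 0:
            raise MalformedProfileError("concentration must be > 0 when given")

    def __len__(self) -> int:
        return len(self.q)

    def replace(self, **kw) -> "ScatteringProfile":
        return replace(self, **kw)

    def restricted(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringProfile":
        """Sub-profile on q in [qmin, qmax]."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if m.sum() < MIN_PROFILE_POINTS:
            raise GridError("restriction leaves fewer than 5 points")
        return self.replace(q=self.q[m], I=self.I[m],
                            sigma=None if self.sigma is None else self.sigma[m])

    def interpolated(self, q_new: np.ndarray) -> "ScatteringProfile":
        """Linear interpolation onto ``q_new`` (must lie inside this grid)."""
        q_new = np.asarray(q_new, dtype=float)
        if q_new.min() < self.q[0] - 1e-12 or q_new.max() > self.q[-1] + 1e-12:
            raise GridError("target grid extends outside the measured q range")
        I = np.interp(q_new, self.q, self.I)
        s = None if self.sigma is None else np.interp(q_new, self.q, self.sigma)
        return self.replace(q=q_new, I=I, sigma=s)


@dataclass(frozen=True)
class CoordinateModel:
    """Point-scatterer model: positions (A), weights, optional volumes (A^3)."""

    positions: np.ndarray
    weights: np.ndarray
    volumes: np.ndarray | None = None
    site_labels: tuple = ()
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if pos.shape[0] < 1:
            raise EmptyStructureError("model must have at least one site")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if w.shape[0] != pos.shape[0] or np.any(w <= 0):
            raise ValueError("weights must be positive, one per site")
        if self.volumes is not None:
            v = np.atleast_1d(np.asarray(self.volumes, dtype=float))
            object.__setattr__(self, "volumes", v)
            if v.shape[0] != pos.shape[0] or np.any(v <= 0):
                raise ValueError("volumes must be positive, one per site")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None) -> "CoordinateModel":
        """Rigidly transform the model: x -> R x + t."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return replace(self, positions=pos)

    @property
    def centroid(self) -> np.ndarray:
        w = self.weights
        return (self.positions * w[:, None]).sum(0) / w.sum()

    def centered(self) -> "CoordinateModel":
        return self.transformed(translation=-self.centroid)

    @staticmethod
    def concatenate(models: Sequence["CoordinateModel"], label: str = "") -> "CoordinateModel":
        return CoordinateModel(
            positions=np.vstack([m.positions for m in models]),
            weights=np.concatenate([m.weights for m in models]),
            volumes=(np.concatenate([m.volumes for m in models])
                     if all(m.volumes is not None for m in models) else None),
            site_labels=tuple(l for m in models for l in m.site_labels),
            label=label,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_float_row(line: str) -> list[float] | None:
    toks = line.split()
    if not toks:
        return None
    try:
        return [float(t) for t in toks]
    except ValueError:
        return None


def read_profile(path: str | Path,
                 q_unit: str = "inverse_angstrom") -> ScatteringProfile:
    """Read a 2/3-column ASCII scattering curve (ATSAS-style ``.dat``).

    Any line whose first whitespace token does not parse as a float is
    treated as a header or comment and skipped.  With
    ``q_unit="inverse_nanometer"`` the q column is divided by 10 to give
    inverse Angstrom.
    """
    if q_unit not in ("inverse_angstrom", "inverse_nanometer"):
        raise ValueError(f"unknown q_unit {q_unit!r}")
    path = Path(path)
    rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        toks = line.split()
        if not toks:
            continue
        try:
            float(toks[0])
        except ValueError:
            continue  # header/comment line
        row = _parse_float_row(line)
        if row is None or len(row) < 2:
            continue
        rows.append(row[:3])
    if len(rows) < MIN_PROFILE_POINTS:
        raise MalformedProfileError(
            f"{path}: fewer than {MIN_PROFILE_POINTS} valid data rows"
        )
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0]
    if q_unit == "inverse_nanometer":
        q = q / 10.0
    sigma = arr[:, 2] if ncol >= 3 else None
    return ScatteringProfile(q=q, I=arr[:, 1], sigma=sigma, label=path.stem)


def write_profile(profile: ScatteringProfile, path: str | Path) -> Path:
    """Write a profile as 3-column (or 2-column when sigma is absent) ASCII.

    Round-trips through :func:`read_profile` to the written precision
    (6 significant digits).
    """
    path = Path(path)
    lines = [f"# {profile.label}" if profile.label else "# oligosaxs profile",
             "# q(1/A)  I  sigma" if profile.sigma is not None else "# q(1/A)  I"]
    for i in range(len(profile)):
        if profile.sigma is not None:
            lines.append(f"{profile.q[i]:.6e} {profile.I[i]:.6e} {profile.sigma[i]:.6e}")
        else:
            lines.append(f"{profile.q[i]:.6e} {profile.I[i]:.6e}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_structure(path: str | Path, mode: str = "residue_centroid") -> CoordinateModel:
    """Read a PDB file into a :class:`CoordinateModel`.

    ``mode="atomic"`` gives one site per non-hydrogen atom with the
    element's electron count as weight; ``mode="residue_centroid"`` gives
    one site per residue at the mean heavy-atom position with uniform
    weight 1.0 (a uniform-contrast coarse grain adequate at SAXS
    resolution).  Only altloc ' ' or 'A' atoms are used.
    """
    import gemmi

    if mode not in ("atomic", "residue_centroid"):
        raise ValueError(f"unknown mode {mode!r}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in structure")
    model = st[0]

    positions, weights, volumes, labels = [], [], [], []
    any_volume_known = True
    for chain in model:
        for res in chain:
            res_pos = []
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                elem = atom.element.name.upper()
                if elem in ("H", "D"):
                    continue
                res_pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                if mode == "atomic":
                    if elem not in _ELECTRONS:
                        warnings.warn(f"unknown element {elem!r}; using default weight")
                        weights.append(_DEFAULT_WEIGHT)
                        any_volume_known = False
                    else:
                        weights.append(float(_ELECTRONS[elem]))
                    volumes.append(_DISPLACED_VOLUME.get(elem, np.nan))
                    labels.append(f"{chain.name}/{res.seqid.num}{res.name}/{atom.name}")
            if mode == "residue_centroid" and res_pos:
                positions.append(np.mean(res_pos, axis=0))
                weights.append(1.0)
                labels.append(f"{chain.name}/{res.seqid.num}{res.name}")
            elif mode == "atomic":
                positions.extend(res_pos)
    if not positions:
        raise EmptyStructureError(f"{path}: no usable ATOM/HETATM records")
    vol = None
    if mode == "atomic" and any_volume_known and not np.any(np.isnan(volumes)):
        vol = np.asarray(volumes, dtype=float)
    return CoordinateModel(positions=np.asarray(positions, dtype=float),
                           weights=np.asarray(weights, dtype=float),
                           volumes=vol, site_labels=tuple(labels),
                           label=Path(path).stem)
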