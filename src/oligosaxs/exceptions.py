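"""Exception hierarchy for the oligosaxs toolchain.

All errors derive from :class:`OligoSaxsError` so callers can catch the
package's failures with a single except clause; input-shaped problems
additionally derive from ``ValueError`` to behave well in generic code.
"""


class OligoSaxsError(Exception):
    """Base class for all oligosaxs errors."""


class MalformedProfileError(OligoSaxsError, ValueError):
    """A scattering profile file or array set violates the profile contract."""


class ProfileOrderingError(MalformedProfileError):
    """Momentum-transfer grid is not strictly increasing."""


class EmptyStructureError(OligoSaxsError, ValueError):
    """A coordinate file contains no usable ATOM/HETATM records."""


class GridError(OligoSaxsError, ValueError):
    """Two curves share no usable q overlap, or grids are incompatible."""


class MergeError(GridError):
    """The requested merge overlap is empty or outside both profiles."""


class NoGuinierRegionError(OligoSaxsError, RuntimeError):
    """No admissible low-q window with a negative ln I vs q^2 slope exists."""


class IntegrationError(OligoSaxsError, RuntimeError):
    """A scattering invariant integrated to a non-positive value."""


class SolverError(OligoSaxsError, RuntimeError):
    """A linear inverse problem could not be solved; try raising alpha."""


class DegenerateModelError(OligoSaxsError, ValueError):
    """A point model is too small for the requested comparison."""


class ConformerGenerationError(OligoSaxsError, RuntimeError):
    """A self-avoiding segment walk failed after the bounded retry budget."""


class InitializationError(OligoSaxsError, RuntimeError):
    """Simulated annealing could not build a feasible starting shape."""
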