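"""Exception hierarchy for writhesim.

Simulation errors carry enough state (step index, offending bead/bond, last
valid frame) to write a diagnostic snapshot instead of failing silently.
"""

from __future__ import annotations


class WrithesimError(Exception):
    """Base class for all writhesim errors."""


class TopologyError(WrithesimError, ValueError):
    """Invalid polymer topology request (e.g. too few beads)."""


class GeometryError(WrithesimError, ValueError):
    """A construction does not fit the confining geometry.

    ``dimension`` names the offending quantity (e.g. ``"diameter"``).
    """

    def __init__(self, message: str, dimension: str | None = None):
        super().__init__(message)
        self.dimension = dimension


class ConfigError(WrithesimError, ValueError):
    """Malformed or inconsistent run configuration."""


class SimulationError(WrithesimError, RuntimeError):
    """Dynamics aborted; carries the step index and last valid frame."""

    def __init__(self, message: str, step: int | None = None,
                 index: int | None = None, frame=None):
        super().__init__(message)
        self.step = step          # integration step at failure
        self.index = index        # offending bead or bond index
        self.frame = frame        # last valid positions, if available


class BondOverstretchError(SimulationError):
    """A FENE bond reached its divergence length r0."""


class OverlapError(SimulationError):
    """Two beads at (numerically) zero separation."""


class EscapedBeadError(SimulationError):
    """A bead crossed the cylindrical wall or a piston plane."""


class NumericalBlowupError(SimulationError):
    """Non-finite coordinates or energy detected."""


class AnalysisError(WrithesimError, ValueError):
    """Invalid input to an analysis routine."""


class CurveTooShortError(AnalysisError):
    """Fewer vertices than the writhe double sum requires."""


class DegenerateSegmentError(AnalysisError):
    """Coincident consecutive vertices in a discrete curve."""


class UndefinedACFError(AnalysisError):
    """Autocorrelation of a constant (zero-variance) series."""


class RebinRequiredError(AnalysisError):
    """Histograms with incompatible binning cannot be pooled."""


class NotApplicableError(AnalysisError):
    """Estimator undefined for this topology (e.g. ring end-to-end vector)."""


class FileFormatError(WrithesimError, ValueError):
    """Malformed trajectory or topology file; names the failing frame."""

    def __init__(self, message: str, last_complete_frame: int | None = None):
        super().__init__(message)
        self.last_complete_frame = last_complete_frame
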