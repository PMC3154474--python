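"""Exception hierarchy."""


class PtggError(Exception):
    """Base class for package errors."""


class PdbParseError(PtggError):
    """Unparseable PDB content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TopologyError(PtggError):
    """Inconsistent duplex topology or mismatched models."""


class SelectionError(PtggError):
    """Atom selection matched nothing."""


class FrameFitError(PtggError):
    """Base reference frame could not be fitted."""


class OrientationError(PtggError):
    """Frames are anti-aligned where alignment is required."""


class GenerationError(PtggError):
    """Synthetic generator could not realize the requested geometry."""


class ChemistryError(PtggError):
    """Chemically invalid request (e.g. platinating a pyrimidine)."""


class ConvergenceError(PtggError):
    """Iterative procedure failed to converge."""
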