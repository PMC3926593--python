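"""Exception hierarchy shared by the measurement pipeline."""


class CropHeightError(Exception):
    """Base class for all errors raised by this package."""


class SeparationError(CropHeightError, ValueError):
    """Marker and background training samples overlap; no threshold exists."""


class DetectionError(CropHeightError, RuntimeError):
    """No marker candidate could be found in a binary mask."""


class CalibrationError(CropHeightError, ValueError):
    """A detected marker length is inconsistent with the reference geometry."""


class CorrectionError(CropHeightError, ValueError):
    """A series cannot be gap-corrected (e.g. every record is flagged)."""
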