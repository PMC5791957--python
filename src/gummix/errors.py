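"""Exception hierarchy for the gummix pipeline.

Every stage raises a typed error so that batch drivers can report
per-specimen failures without aborting a whole run.
"""


class GummixError(Exception):
    """Base class for all gummix errors."""


class ParameterError(GummixError, ValueError):
    """Invalid parameter or configuration value."""


class InputError(GummixError, ValueError):
    """Malformed or empty input data (images, tables)."""


class SegmentationError(GummixError):
    """The ROI/background segmentation could not produce a usable mask."""


class FeatureError(GummixError):
    """Feature extraction failed (empty ROI, all hues undefined, ...)."""


class RegistryError(GummixError, KeyError):
    """Unknown feature model or channel code."""


class SelectionError(GummixError):
    """Feature relevancy scoring failed (empty class, degenerate input)."""


class TrainingError(GummixError):
    """No network converged while training a cascade stage."""


class CalibrationError(GummixError):
    """Calibration failed, e.g. a stroke class has no suitable stage."""


class MEPATError(GummixError):
    """Base class for portable-record (MEPAT) errors."""


class MEPATValidationError(MEPATError):
    """Record violates structural invariants (missing blocks, bad counts)."""


class MEPATSchemaError(MEPATError):
    """File does not validate against the shipped XML schema."""


class MEPATParseError(MEPATError):
    """File is structurally valid XML but carries uninterpretable content
    (truncated weight matrices, unknown feature codes, bad numbers)."""


class DiagnosisError(GummixError):
    """Single-specimen diagnosis failed (bad T, feature mismatch)."""
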