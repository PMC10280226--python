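"""Exception hierarchy for the ppgcopd pipeline.

Every stage raises a subclass of :class:`PpgError`, so callers can catch one
base class at pipeline level while tests assert on the precise failure mode.
"""


class PpgError(Exception):
    """Base class for all ppgcopd errors."""


# --- record I/O ---------------------------------------------------------


class PpgIoError(PpgError):
    """File could not be read or written."""


class ChannelNotFound(PpgIoError):
    """Requested channel is absent from the file."""


class IrregularSampling(PpgIoError):
    """CSV time column is not a uniform grid (tolerance 1% of median dt)."""


class CorruptSignal(PpgIoError):
    """Non-finite samples encountered on read."""


class DuplicateSubject(PpgError):
    """Two cohort records share a subject_id."""


class LabelParseError(PpgError):
    """Label token is neither COPD nor HEALTHY (case-insensitive)."""


# --- signal processing --------------------------------------------------


class NyquistViolation(PpgError):
    """Sampling rate too low for the requested passband."""


class TooShort(PpgError):
    """Signal or epoch shorter than the operation requires."""


class DegenerateEpoch(PpgError):
    """Constant (zero-variance) epoch where a variance-based feature is undefined."""


# --- features / selection -----------------------------------------------


class ManifestMismatch(PpgError):
    """Epoch set refers to a subject absent from the cohort."""


class SingleClassError(PpgError):
    """Operation needs both classes but only one is present."""


class BadLevel(PpgError):
    """Selection level outside 1..10."""


class BadValue(PpgError):
    """Numeric argument outside its documented domain."""


# --- classification / evaluation ----------------------------------------


class SchemaError(PpgError):
    """Feature columns or label vectors do not line up."""


class UndefinedMetric(PpgError):
    """Metric undefined for the given confusion counts (e.g. one-class truth)."""


class ConfigError(PpgError):
    """Run configuration invalid or inconsistent."""
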