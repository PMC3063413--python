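"""Exception hierarchy.

Every error raised by fastkit derives from :class:`FastkitError` so callers
can catch the whole family; most also derive from the matching builtin so
idiomatic ``except KeyError`` style code keeps working.
"""


class FastkitError(Exception):
    """Base class for all fastkit errors."""


class ChannelNotFoundError(FastkitError, KeyError):
    """A requested channel name does not exist in the recording."""


class WindowBoundsError(FastkitError, IndexError):
    """A requested sample window falls outside the recording."""


class ParameterError(FastkitError, ValueError):
    """An operation parameter is invalid."""


class ConfigurationError(FastkitError, ValueError):
    """A montage / ROI / method configuration is unusable."""


class CompatibilityError(FastkitError, ValueError):
    """Two recordings cannot be combined (channels / rates differ)."""


class OverlapError(FastkitError, ValueError):
    """Appended recordings overlap in real-world clock time."""


class IntegrityError(FastkitError, OSError):
    """Header and binary payload disagree (e.g. truncated file)."""


class MarkerNotFoundError(FastkitError, LookupError):
    """An event label used to delimit an interval was not found."""


class DetectionError(FastkitError, RuntimeError):
    """A detector found no plausible result (e.g. no heartbeats)."""


class StageNotFoundError(FastkitError, LookupError):
    """A requested sleep stage has no scored windows."""
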