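"""Exception types shared across the package."""


class PhotocifError(ValueError):
    """Base class for validation and analysis errors."""


class SchemaError(PhotocifError):
    """A file or config block does not match the expected schema."""


class DegenerateBaselineError(PhotocifError):
    """Baseline window has (near-)zero standard deviation."""


class EmptyPeriEventError(PhotocifError):
    """No event survived peri-event windowing."""
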