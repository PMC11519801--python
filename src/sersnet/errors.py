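"""Exception hierarchy shared across the package."""


class SersnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SersnetError, ValueError):
    """A configuration record violates its invariants."""


class FormatError(SersnetError, ValueError):
    """A file or in-memory dataset violates the documented format."""


class IntegrityError(SersnetError, ValueError):
    """Metadata is internally inconsistent (e.g. one cell, two labels)."""


class InsufficientDataError(SersnetError, ValueError):
    """Too few observations for the requested statistic."""


class ShapeError(SersnetError, ValueError):
    """Array/layer shape mismatch."""


class DesignError(SersnetError, ValueError):
    """The experimental design cannot be executed (missing arm, empty subset)."""


class SizingError(DesignError):
    """A split fraction yields an empty mandatory subset."""


class RangeError(SersnetError, ValueError):
    """A requested spectral window lies outside the wavenumber axis."""


class DegenerateRatioError(SersnetError, ValueError):
    """A band-ratio denominator is zero or negative for some cell."""


class StateError(SersnetError, RuntimeError):
    """An operation was called on an object in the wrong state (e.g. untrained model)."""
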