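"""Exception hierarchy shared across the package."""


class GingiredError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GingiredError):
    """An input file is readable but not in an accepted format."""


class ManifestError(GingiredError):
    """An ROI manifest row failed validation."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if field is not None:
            loc.append(f"field {field!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


class BoundsError(GingiredError):
    """An ROI rectangle falls outside the photo."""


class ParameterError(GingiredError):
    """A numeric parameter is outside its valid domain."""


class AllHaloError(GingiredError):
    """Every pixel of an ROI was flagged as halo artifact; no mean is defined."""


class RatioUndefinedError(GingiredError):
    """Mean green intensity is zero; the R/G ratio is undefined."""


class ScoreValidationError(GingiredError):
    """A gingival-index score record failed validation."""


class InsufficientDataError(GingiredError):
    """Too few observations for the requested statistic."""
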