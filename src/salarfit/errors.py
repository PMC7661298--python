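"""Exception types raised across the package."""


class SalarfitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SalarfitError, ValueError):
    """A parameter or configuration value is out of its valid range."""


class SchemaError(SalarfitError, ValueError):
    """An input table is missing required columns or violates its schema."""


class OrphanParentError(SalarfitError, ValueError):
    """A parentage link names a parent absent from the fish table."""

    def __init__(self, orphans):
        self.orphans = sorted(orphans)
        super().__init__(
            f"{len(self.orphans)} parent id(s) in the parentage table are not in "
            f"the fish table: {self.orphans[:10]}"
            + (" ..." if len(self.orphans) > 10 else "")
        )


class UndefinedRRSError(SalarfitError, ValueError):
    """RRS is undefined because the wild (reference) corrected mean is <= 0."""


class DegenerateDesignError(SalarfitError, ValueError):
    """A regression design is degenerate (e.g. constant predictor)."""


class InsufficientDataError(SalarfitError, ValueError):
    """Not enough usable observations for the requested fit."""
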