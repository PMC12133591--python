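"""Exception hierarchy.

Everything raised deliberately by surfacer derives from :class:`SurfacerError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class SurfacerError(Exception):
    """Base class for all errors raised by surfacer."""


class ParameterError(SurfacerError):
    """A configuration value is outside its documented range; names the field."""


class FormatError(SurfacerError):
    """A table cell or header token could not be parsed."""


class SchemaError(SurfacerError):
    """A table is missing a mandatory column or violates a structural rule."""


class ValidationError(SurfacerError):
    """A parsed table violates a cross-field invariant."""


class DegenerateDesignError(SurfacerError):
    """The run design admits no non-trivial relabeling of conditions."""


class UndefinedScoreError(SurfacerError):
    """A specificity score is undefined for the given expression vector."""
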