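"""Exception hierarchy.

All package-raised errors derive from :class:`VarprioError` so callers (and
the CLI) can catch one base class and map it to a non-zero exit status.
"""


class VarprioError(Exception):
    """Base class for all errors raised by varprio."""


class ParseError(VarprioError):
    """A file (VCF, TSV, PED, PPF, VPOL) could not be parsed."""


class ValidationError(VarprioError):
    """Parsed content violates an invariant (duplicate IDs, bad interval, ...)."""


class ConfigurationError(VarprioError):
    """Inputs are individually valid but inconsistent with the requested run."""
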