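"""Typed exceptions shared across the toolkit."""


class SpdcError(Exception):
    """Base class for all spdchg errors."""


class ConfigError(SpdcError, ValueError):
    """Invalid simulation or model configuration."""


class FormatError(SpdcError, ValueError):
    """Unparseable or unsupported input file."""


class DuplicateIDError(SpdcError, ValueError):
    """Duplicate line or marker identifiers."""


class QCError(SpdcError, ValueError):
    """Quality control removed everything, or inputs fail QC preconditions."""


class PlanError(SpdcError, ValueError):
    """Infeasible or invalid crossing plan."""


class ModelError(SpdcError, ValueError):
    """Mis-specified model inputs (dimensions, untrained model, ...)."""
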