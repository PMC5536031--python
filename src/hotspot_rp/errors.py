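"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration problems (bad parameter
combinations) exit 2; data/format problems (unparseable or inconsistent
input files) exit 3.
"""


class HotspotRPError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HotspotRPError):
    """A file does not follow the expected external format."""


class ParseError(FormatError):
    """A specific record or line could not be parsed; message names it."""


class DataError(HotspotRPError):
    """Inputs are individually well-formed but mutually inconsistent."""


class DimensionError(HotspotRPError, ValueError):
    """Array widths/lengths do not line up."""


class ConfigError(HotspotRPError, ValueError):
    """Invalid parameter value or combination."""


class DegenerateInputError(HotspotRPError, ValueError):
    """Input lacks the variation the operation requires (e.g. one class)."""
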