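"""Exception hierarchy shared by all spikequant modules."""


class SpikequantError(Exception):
    """Base class for every error raised by spikequant."""


class ValidationError(SpikequantError, ValueError):
    """Invalid input: bad sequence alphabet, malformed table, bad config."""


class DesignError(SpikequantError, RuntimeError):
    """Panel or fixture design could not satisfy its constraints."""


class FitError(SpikequantError, RuntimeError):
    """The internal-standard regression could not be fitted."""


class QuantError(SpikequantError, RuntimeError):
    """Read-to-copy-number conversion failed."""
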