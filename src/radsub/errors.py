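"""Exception hierarchy.

ConfigurationError: a parameter or table handed to the pipeline is unusable
(duplicate barcodes, non-positive lengths, unknown system labels, ...).
ValidationError: data content violates a contract (non-DNA motif characters,
mixed-length tag input, mismatched id sets, ...).
"""


class RadsubError(Exception):
    """Base class for all radsub errors."""


class ConfigurationError(RadsubError, ValueError):
    """Invalid configuration or parameter table."""


class ValidationError(RadsubError, ValueError):
    """Input data violates an operation's contract."""
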