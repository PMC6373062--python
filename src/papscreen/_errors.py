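"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: ConfigError -> 2, DataError -> 3, ContractError -> 4.
"""


class PapscreenError(Exception):
    """Base class for all papscreen errors."""


class ConfigError(PapscreenError, ValueError):
    """Invalid configuration (bad clip limit, filter-bank mismatch, ...)."""


class DataError(PapscreenError, ValueError):
    """Malformed input data (non-finite features, bad CSV header, ...)."""


class ContractError(PapscreenError, ValueError):
    """A documented precondition of an operation was violated."""
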