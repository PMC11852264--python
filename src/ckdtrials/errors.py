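"""Exception hierarchy: configuration, data and contract errors are distinguished
so the CLI can map them onto distinct exit codes."""


class CKDTrialsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CKDTrialsError):
    """Invalid run or generator configuration."""


class DataError(CKDTrialsError):
    """Malformed or inconsistent input data."""


class ContractError(CKDTrialsError):
    """An operation was called outside its contract (programming error)."""


class DomainError(CKDTrialsError, ValueError):
    """A numeric argument outside the mathematical domain of a function."""


class ImputationError(CKDTrialsError):
    """Imputation cannot proceed (e.g. a fully missing variable)."""
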