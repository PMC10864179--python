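"""Exception hierarchy shared across the package."""


class MsaForgeError(Exception):
    """Base class for all package-specific errors."""


class MsaFormatError(MsaForgeError):
    """Malformed alignment input (ragged rows, empty stream, gapped query)."""


class UndefinedStatisticError(MsaForgeError):
    """A statistic is undefined for the given input (e.g. coverage of a
    query-only MSA, or an MAE over zero eligible pairs)."""


class StoichiometryError(MsaForgeError):
    """Malformed complex stoichiometry string."""


class BackendError(MsaForgeError):
    """A pluggable search backend failed; orchestration records a diagnostic
    and returns the partial result accumulated so far."""
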