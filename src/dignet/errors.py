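"""Exception taxonomy shared across the package."""


class DignetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DignetError, ValueError):
    """A generator or statistic was asked for an impossible parameterization."""


class SchemaError(DignetError, ValueError):
    """An input table is missing required columns or is malformed."""


class ParseError(DignetError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class LookupMissError(DignetError, KeyError):
    """A drug, ADR term, gene or cell type is absent from the relevant universe."""


class ConfigurationError(DignetError, ValueError):
    """An invalid configuration value (e.g. a cyclic synonym map)."""


class GroupingError(DignetError, ValueError):
    """Group definitions are empty, overlapping, or otherwise unusable."""


class DegenerateInputError(DignetError, ValueError):
    """The statistic is undefined on this input (all-zero table, constant vector...)."""


class InsufficientDataError(DignetError, ValueError):
    """Too few observations to compute the requested quantity."""


class SizeError(DignetError, ValueError):
    """Input exceeds a configured size cap for an exact algorithm."""


class PipelineHalt(DignetError, RuntimeError):
    """A pipeline stage produced an empty result; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
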