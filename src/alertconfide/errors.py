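"""Exception hierarchy for alertconfide."""


class AlertConfideError(Exception):
    """Base class for all package errors."""


class RegistryError(AlertConfideError):
    """A packaged or user-supplied registry file is missing or malformed."""


class ProfileError(AlertConfideError):
    """A confidence profile is incomplete or inconsistent."""


class NoApplicableCriteriaError(ProfileError):
    """Every criterion in a profile is marked not-applicable, so no score exists."""


class ConfigurationError(AlertConfideError):
    """A weighting scheme or threshold configuration cannot be used as given."""


class UnknownUseCaseError(AlertConfideError):
    """Requested use-case id is not among the packaged requirement profiles."""


class PatternError(AlertConfideError):
    """A SMARTS pattern failed to compile; the offending pattern is in args."""


class EmptyInventoryError(AlertConfideError):
    """No parseable molecules remain after quarantine."""


class UndefinedStatisticError(AlertConfideError):
    """A requested classification statistic has a zero denominator."""


class GenerationError(AlertConfideError):
    """The synthetic-inventory generator could not satisfy its postconditions."""
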