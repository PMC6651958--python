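"""Exception hierarchy shared across the package."""


class SmokesimError(Exception):
    """Base class for all package-specific errors."""


class ContractViolationError(SmokesimError, ValueError):
    """A transition-probability contract was violated.

    Raised when a combination of rates and death probabilities would produce
    a negative diagonal entry (i.e. the competing flows out of a state exceed
    probability one), or when a state vector contains negative or non-finite
    counts.
    """


class UndefinedRateError(SmokesimError, ZeroDivisionError):
    """A rate estimator was asked to divide by a zero denominator.

    The caller decides whether to impute, pool strata, or abort; the
    estimators never impute silently.
    """


class ConfigurationError(SmokesimError, ValueError):
    """A configuration file, rate table, or input schedule is incomplete."""


class FixtureIntegrityError(SmokesimError, IOError):
    """A packaged data file does not match its recorded checksum."""
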