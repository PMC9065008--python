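"""Exception hierarchy for fossilbd."""


class FossilbdError(Exception):
    """Base class for all package errors."""


class FormatError(FossilbdError):
    """A file or table does not conform to the declared dialect/schema."""


class ConfigError(FossilbdError):
    """An invalid rule, option, or configuration value."""


class DomainError(FossilbdError):
    """A parameter outside its mathematical domain (e.g. a non-positive rate)."""


class ConsistencyError(FossilbdError):
    """Internally inconsistent data (e.g. an occurrence outside its lifespan)."""


class SimulationExplosionError(FossilbdError):
    """A forward birth-death simulation exceeded its diversity cap."""
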