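"""Exception hierarchy.

Every error raised by this package derives from :class:`CaresError`, so callers
(and the CLI) can distinguish policy failures from programming errors.  Denied
access is *always* an exception (:class:`AuthorisationError`), never an empty
result: the hub fails closed.
"""

from __future__ import annotations


class CaresError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(CaresError, ValueError):
    """A caller-supplied parameter is out of range or inconsistent."""


class ConfigurationError(CaresError):
    """Missing or inconsistent configuration (secrets, task wiring, escrow)."""


class SchemaError(CaresError):
    """A collection schema is invalid or violated."""


class ConflictError(CaresError):
    """An attempt to register something that already exists."""


class NotFoundError(CaresError, LookupError):
    """An entity (user, collection, task, record id) is not known.

    Distinct from :class:`AuthorisationError`: an unknown entity is a lookup
    failure, not a policy decision.
    """


class AuthorisationError(CaresError, PermissionError):
    """A governance or role check denied the operation."""


class AuthenticationError(CaresError):
    """Credential verification failed (message never reveals which part)."""


class KeyfileError(CaresError):
    """A linkage key file is malformed beyond row-level repair."""


class TaskError(CaresError):
    """An extraction task is internally inconsistent (e.g. a transform step
    references a field that does not exist at that point in the pipeline)."""


class StandardisationError(CaresError):
    """A value cannot be coerced to its declared output type/format."""


class ComparisonError(CaresError):
    """Parallel-run comparison inputs are unusable (e.g. duplicate keys)."""


class InvalidRecordError(CaresError, ValueError):
    """An operational record violates its invariant (e.g. negative interval)."""
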