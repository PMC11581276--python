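"""Exception hierarchy.

All exceptions derive from :class:`PpsimError` so callers can catch the
package's failures with a single ``except``.  Where a standard-library
exception is the idiomatic choice (bad argument values, out-of-range
inputs) the class also subclasses ``ValueError``.
"""


class PpsimError(Exception):
    """Base class for all errors raised by ppsim."""


class DomainError(PpsimError, ValueError):
    """A time falls outside an intensity's domain, or an interval is invalid."""


class RangeError(PpsimError, ValueError):
    """A cumulative-intensity value falls outside [0, Lambda(b)]."""


class SpecError(PpsimError, ValueError):
    """An intensity specification is internally inconsistent."""


class DominationError(PpsimError, ValueError):
    """A majorizer fails to dominate its target intensity."""


class DispatchError(PpsimError, ValueError):
    """The draw() dispatcher received an ambiguous or empty argument bundle."""


class AttributionError(PpsimError, ValueError):
    """Superposition attribution impossible (all component rates zero)."""


class ConfigError(PpsimError, ValueError):
    """A run configuration failed schema validation."""
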