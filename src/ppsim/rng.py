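"""Reproducible random-number streams.

The sampling functions in this package accept either a
:class:`numpy.random.Generator` or an :class:`RngStream`.  ``RngStream``
adds two facilities used in discrete-event simulation studies:

* named sub-streams derived from a single seed, for common-random-number
  designs (the same ``(seed, stream_id)`` pair always reproduces the same
  variates, and distinct ``stream_id`` values give independent streams);
* antithetic partners, whose uniform layer returns ``1 - u`` for every
  uniform ``u`` of the base stream.

Exponential variates are generated from the uniform layer so that
antithetic coupling propagates to inter-arrival times; Poisson counts
delegate to the underlying generator (no antithetic coupling).
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["RngStream", "resolve_rng"]


def _derive_seed_sequence(seed: int, stream_id: str | None) -> np.random.SeedSequence:
    if stream_id is None:
        return np.random.SeedSequence(seed)
    # Stable across platforms/sessions: hash the label, not Python's hash().
    digest = hashlib.sha256(str(stream_id).encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.SeedSequence(seed, spawn_key=(key,))


class RngStream:
    """A seeded, optionally antithetic, sub-streamable random source.

    Parameters
    ----------
    seed:
        Non-negative integer master seed.
    stream_id:
        Optional label identifying a sub-stream of ``seed``.
    antithetic:
        When true, every uniform draw ``u`` is replaced by ``1 - u``.
    """

    def __init__(self, seed: int, stream_id: str | None = None, *,
                 antithetic: bool = False) -> None:
        if not (isinstance(seed, (int, np.integer)) and seed >= 0):
            raise ValueError("seed must be a non-negative integer")
        self.seed = int(seed)
        self.stream_id = stream_id
        self.antithetic = bool(antithetic)
        self._gen = np.random.default_rng(_derive_seed_sequence(self.seed, stream_id))

    # -- uniform layer ---------------------------------------------------
    def random(self, size=None):
        u = self._gen.random(size)
        return 1.0 - u if self.antithetic else u

    def uniform(self, low=0.0, high=1.0, size=None):
        return low + (high - low) * self.random(size)

    # -- derived variates ------------------------------------------------
    def exponential(self, scale=1.0, size=None):
        u = self.random(size)
        # u in [0, 1): -log1p(-u) is exact near zero and never -log(0).
        return -scale * np.log1p(-u)

    def poisson(self, lam, size=None):
        return self._gen.poisson(lam, size)

    def integers(self, low, high=None, size=None):
        return self._gen.integers(low, high, size=size)

    # -- stream management ----------------------------------------------
    def substream(self, stream_id: str) -> "RngStream":
        """A fresh independent stream derived from the same master seed."""
        return RngStream(self.seed, stream_id, antithetic=self.antithetic)

    def antithetic_partner(self) -> "RngStream":
        """The stream whose uniforms are the reflections ``1 - u`` of this one."""
        return RngStream(self.seed, self.stream_id, antithetic=not self.antithetic)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RngStream(seed={self.seed}, stream_id={self.stream_id!r}, "
                f"antithetic={self.antithetic})")


def resolve_rng(rng=None):
    """Coerce ``rng`` to an object exposing the Generator drawing API.

    ``None`` gives a fresh nondeterministic generator; an integer is taken
    as a seed; ``RngStream`` and ``numpy.random.Generator`` pass through.
    """
    if rng is None:
        return np.random.default_rng()
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    if isinstance(rng, (RngStream, np.random.Generator)):
        return rng
    raise TypeError(f"cannot interpret {type(rng).__name__} as a random source")
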