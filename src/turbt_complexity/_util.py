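"""Shared numeric helpers: half-up rounding and named random substreams."""

from __future__ import annotations

import hashlib

import numpy as np

#: small slack so that products such as 1.10 * 3 = 3.3000000000000003 round
#: the way their exact decimal values would
_EPS = 1e-9


def round_half_up(x):
    """Round to the nearest integer, with halves rounded up (toward 5)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5 + _EPS)


def round_to_multiple(x: float, granularity: float) -> float:
    """Round ``x`` to the nearest multiple of ``granularity``; ties round up."""
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    return granularity * float(np.floor(x / granularity + 0.5 + _EPS))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a reproducible RNG keyed by a master seed and a stage name.

    Each pipeline stage draws from its own stream so stages can be re-run
    in isolation without disturbing one another.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
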