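"""Small shared helpers: seeding, circular orientation arithmetic, logging."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("oriem")

#: Orientation grid used throughout: 9 values evenly spaced on [0, 180).
ORIENTATION_GRID = np.arange(0, 180, 20)


def child_seed(master_seed: int, *key: int) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed.

    Every stochastic stage draws its seed through this function so that a
    single master seed fixes the whole run while stages stay independent.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_for(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, *key))


def circ_dist_deg(a, b, period: float = 180.0):
    """Signed circular distance a-b on an orientation space of the given period.

    Returned values lie in (-period/2, period/2].
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    d = np.where(d > period / 2, d - period, d)
    # map exactly -period/2 to +period/2 so the interval is half-open
    d = np.where(d <= -period / 2, d + period, d)
    return d
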