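"""Deterministic child-seed derivation.

One master seed governs a run. Every consumer of randomness (each surrogate,
each Louvain restart, each synthetic draw) receives a child seed derived from
the master seed and an integer path, so ensembles are reproducible
element-wise: surrogate k of a run is the same graph no matter how many
surrogates are requested.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "child_rng"]

_SEED_CAP = 2**31


def child_seed(master: int, *path: int) -> int:
    """Derive a child seed from ``master`` and an integer path.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so children with
    different paths are statistically independent. The result is always in
    ``[0, 2**31)`` and is a pure function of its arguments.
    """
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(p) for p in path))
    return int(ss.generate_state(1, np.uint64)[0] % _SEED_CAP)


def child_rng(master: int, *path: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *path))
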