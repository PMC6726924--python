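"""Named, independent random streams derived from one user-facing seed.

Every stochastic stage of the pipeline (measurement noise, initial conditions,
reference-point sampling, permutation surrogates) draws from its own stream so
that changing e.g. the number of surrogates cannot perturb the simulated
dynamics.  Streams are spawned from ``SeedSequence(seed)`` keyed by a stable
hash of the stream name.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream"]


def _name_key(name: str) -> int:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def stream(seed: int, name: str) -> np.random.Generator:
    """Return an independent Generator for (seed, name).

    Deterministic: the same pair always yields a bit-identical stream,
    regardless of how many other streams were created.
    """
    ss = np.random.SeedSequence([int(seed) & 0xFFFFFFFFFFFFFFFF, _name_key(name)])
    return np.random.default_rng(ss)
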