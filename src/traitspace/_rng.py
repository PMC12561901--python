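"""Seed derivation.

All randomness in the package flows from one top-level integer seed.  Each
stage derives its own independent stream by hashing a stage label into a
``SeedSequence`` spawn key, so partial re-runs (e.g. re-running only the
group tests) see the same stream as a full run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def _stage_key(stage: str) -> int:
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def stage_rng(seed: int, stage: str = "") -> np.random.Generator:
    """Return a Generator for ``stage`` derived deterministically from ``seed``."""
    if stage:
        return np.random.default_rng(np.random.SeedSequence([int(seed), _stage_key(stage)]))
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def stage_seed(seed: int, stage: str) -> int:
    """A plain integer (< 2**31) derived from ``seed`` and ``stage``."""
    ss = np.random.SeedSequence([int(seed), _stage_key(stage)])
    return int(ss.generate_state(1)[0] % (2**31))
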