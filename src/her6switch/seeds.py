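"""Deterministic per-component seed derivation.

One global run seed is fanned out to named substreams by hashing the
component name, so adding a component never perturbs existing streams and
two runs with the same config + seed are bit-identical.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["component_seed", "component_rng"]


def component_seed(seed: int, name: str) -> int:
    """Stable sub-seed (< 2**31) for a named component of a run."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def component_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(component_seed(seed, name))
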