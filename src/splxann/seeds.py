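"""Counter-based seed derivation.

A single master seed plus a named derivation path (stage, condition,
replicate, member, ...) yields an independent random stream for every unit
of work.  Streams depend only on the path, never on execution order, so a
grid evaluated in any order — or resumed from checkpoints — reproduces the
same numbers.  String path components are mapped to integers with CRC-32,
which is stable across platforms and Python versions.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed_sequence", "derive_rng", "derive_seed"]


def _component_to_int(component: int | str) -> int:
    if isinstance(component, (int, np.integer)):
        return int(component)
    if isinstance(component, str):
        return zlib.crc32(component.encode("utf-8"))
    raise TypeError(f"seed path components must be int or str, got {type(component)!r}")


def derive_seed_sequence(master_seed: int, *path: int | str) -> np.random.SeedSequence:
    """Return a SeedSequence for ``(master_seed, *path)``."""
    entropy = [int(master_seed)] + [_component_to_int(p) for p in path]
    return np.random.SeedSequence(entropy)


def derive_rng(master_seed: int, *path: int | str) -> np.random.Generator:
    """Return an independent Generator for the given derivation path."""
    return np.random.default_rng(derive_seed_sequence(master_seed, *path))


def derive_seed(master_seed: int, *path: int | str) -> int:
    """Collapse a derivation path to a single integer seed below 2**31."""
    state = derive_seed_sequence(master_seed, *path).generate_state(1, np.uint32)
    return int(state[0] % (2**31))
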