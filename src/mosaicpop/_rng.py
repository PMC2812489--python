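"""Deterministic sub-seed derivation.

Every stochastic stage receives its own child seed derived from a master
seed plus string labels, so any stage of a large factorial run can be
replayed in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng", "child_seed"]


def _label_words(labels: tuple) -> list[int]:
    words = []
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            words.append(int(lab) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(lab).encode("utf-8")))
    return words


def child_seed_sequence(master: int, *labels) -> np.random.SeedSequence:
    """SeedSequence keyed by (master seed, labels)."""
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, *_label_words(labels)])


def child_rng(master: int, *labels) -> np.random.Generator:
    """Generator keyed by (master seed, labels)."""
    return np.random.default_rng(child_seed_sequence(master, *labels))


def child_seed(master: int, *labels) -> int:
    """A plain integer child seed (< 2**31) keyed by (master seed, labels)."""
    return int(child_seed_sequence(master, *labels).generate_state(1)[0] & 0x7FFFFFFF)
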