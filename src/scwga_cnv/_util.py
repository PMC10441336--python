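"""Small shared helpers: chromosome naming, deterministic seeding."""

from __future__ import annotations

import zlib

import numpy as np

_SEX_CHROMS = {"X", "Y", "M", "MT"}


def is_autosome(chrom: str) -> bool:
    """True for autosomal chromosome labels ('chr1', '1', ...), False for sex/mito."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.upper() not in _SEX_CHROMS


def autosome_mask(chroms) -> np.ndarray:
    return np.fromiter((is_autosome(c) for c in chroms), dtype=bool, count=len(chroms))


def stable_hash(label: str) -> int:
    """Deterministic 32-bit hash of a string, independent of PYTHONHASHSEED."""
    return zlib.crc32(label.encode("utf-8"))


def child_rng(seed: int, *labels: str) -> np.random.Generator:
    """Generator for a named sub-stream of a global seed.

    Streams depend only on the seed and the labels, never on the order in
    which other streams were drawn, so per-cell output is reproducible even
    when cells are processed in a different order.
    """
    entropy = [int(seed)] + [stable_hash(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
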