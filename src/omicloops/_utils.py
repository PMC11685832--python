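"""Shared helpers: named RNG substreams and small validation utilities."""

from __future__ import annotations

import hashlib

import numpy as np

OMIC_TYPES = ("genotype", "microbiome", "metabolite", "bmi")


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for a named substream of a global seed.

    The stream is keyed by a stable hash of ``(seed, name)`` so that adding a
    new named stage never perturbs the draws of an existing one, and the same
    (seed, name) pair yields the same stream on every platform.
    """
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    entropy = int.from_bytes(digest[:16], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy))


def check_unique(values, what: str) -> None:
    seen = set()
    dup = [v for v in values if v in seen or seen.add(v)]
    if dup:
        raise ValueError(f"duplicate {what}: {sorted(set(dup))!r}")


def standardize(x: np.ndarray) -> np.ndarray:
    """Empirically standardise a vector; a constant vector maps to zeros."""
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - np.nanmean(x)) / sd
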