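"""Shared helpers: seeded substreams and array validation."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "check_adjacency", "as_symmetric_weights"]


def rng_for(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-component random stream.

    A single master seed is combined with a path of string labels so that
    every artefact (mesh, cohort, expression, nulls, surrogates, ...) draws
    from its own reproducible substream, independent of the order in which
    the other artefacts are generated.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def check_adjacency(a: np.ndarray, name: str = "adjacency") -> np.ndarray:
    """Validate a square symmetric zero-diagonal matrix; returns the array."""
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    if not np.array_equal(a, a.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diagonal(a) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return a


def as_symmetric_weights(a: np.ndarray) -> np.ndarray:
    a = check_adjacency(a, "weight matrix")
    if np.any(a < 0):
        raise ValueError("weights must be non-negative")
    return a
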