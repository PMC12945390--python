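"""Shared helpers: RNG coercion and error types."""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_rng",
    "DegenerateInputError",
    "DimensionMismatchError",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but numerically degenerate
    (zero-variance unit under z-scoring, all-zero map under peak
    normalization, non-positive total variance, ...)."""


class DimensionMismatchError(ValueError):
    """Raised when two objects that must share an axis do not."""


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce ``seed`` to a :class:`numpy.random.Generator`.

    Generators pass through untouched so callers can thread a single stream
    through a pipeline; integers and ``None`` construct a fresh PCG64 stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
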