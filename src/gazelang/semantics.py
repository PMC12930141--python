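"""Semantic similarity between trials from sentence-embedding vectors.

The default measure is the plain dot product between the two embedding
vectors; cosine similarity is available as an alternative and is identical
when embeddings are unit-normalized. Embeddings are consumed as provided —
no re-normalization is applied by default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_io import EmbeddingVector
from .errors import DimensionError, SimilarityUndefinedError


def dot_similarity(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError(f"dimension mismatch: {u.shape} vs {v.shape}")
    return float(u @ v)


def cosine_similarity(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise SimilarityUndefinedError("cosine similarity undefined for zero vector")
    return float(u @ v / (nu * nv))


def pairwise_similarity(
    vectors: Sequence[EmbeddingVector] | np.ndarray,
    measure: str = "dot",
) -> np.ndarray:
    """Symmetric matrix of semantic similarities over all trial pairs."""
    if isinstance(vectors, np.ndarray):
        X = np.asarray(vectors, dtype=float)
    else:
        dims = {v.dim for v in vectors}
        if len(dims) > 1:
            raise DimensionError(f"inconsistent embedding dimensions: {sorted(dims)}")
        X = np.stack([v.values for v in vectors]) if vectors else np.zeros((0, 0))
    if measure == "dot":
        return X @ X.T
    if measure == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise SimilarityUndefinedError("cosine similarity undefined for zero vector")
        Xn = X / norms[:, None]
        return Xn @ Xn.T
    raise ValueError(f"unknown similarity measure {measure!r}")
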