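"""Cosine-similarity search shared by the tagging and captioning stages."""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity


def cosine_to_index(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Cosine similarity of one query vector against every row of ``matrix``.

    Raises ValueError for a zero-norm query (cosine undefined).
    """
    query = np.asarray(query, dtype=np.float64).ravel()
    if matrix.shape[0] == 0:
        raise ValueError("empty index")
    if query.shape[0] != matrix.shape[1]:
        raise ValueError(
            f"query dimension {query.shape[0]} does not match index dimension {matrix.shape[1]}"
        )
    if np.linalg.norm(query) == 0.0:
        raise ValueError("zero-norm query embedding: cosine similarity undefined")
    return cosine_similarity(query[None, :], matrix)[0]


def top_neighbours(
    sims: np.ndarray, exam_ids: list[str], k: int
) -> list[int]:
    """Indices of the k most similar entries.

    Deterministic tie rule: higher similarity first, then lower exam_id.
    """
    order = sorted(range(len(exam_ids)), key=lambda i: (-sims[i], exam_ids[i]))
    return order[:k]
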