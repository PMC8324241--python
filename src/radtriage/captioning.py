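"""Tag-constrained retrieval of diagnostic captions.

A test exam's caption is copied from the most cosine-similar training exam.
The search is restricted to training exams whose tag set equals the tags
predicted for the test exam (exact set equality, the empty set included);
when no such exam exists the whole database is searched instead, and the
result is flagged as unconstrained.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._similarity import cosine_to_index, top_neighbours
from .data import Exam
from .encoder import EmbeddingTable


class RetrievalIndex:
    """Immutable store of training (embedding, tag set, caption) entries."""

    def __init__(
        self,
        exam_ids: Sequence[str],
        matrix: np.ndarray,
        tag_sets: Sequence[frozenset[str]],
        captions: Sequence[str],
    ):
        if len(exam_ids) == 0:
            raise ValueError("retrieval index cannot be empty")
        if not (len(exam_ids) == matrix.shape[0] == len(tag_sets) == len(captions)):
            raise ValueError("index fields must align")
        for e, c in zip(exam_ids, captions):
            if not c:
                raise ValueError(f"exam {e!r}: empty caption cannot be indexed")
        self.exam_ids = list(exam_ids)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.tag_sets = [frozenset(t) for t in tag_sets]
        self.captions = list(captions)
        # tag-set hash map for the exact-equality filter
        self._by_tags: dict[frozenset[str], list[int]] = {}
        for i, t in enumerate(self.tag_sets):
            self._by_tags.setdefault(t, []).append(i)

    def __len__(self) -> int:
        return len(self.exam_ids)

    def candidates(self, tags: frozenset[str], match: str = "exact") -> list[int]:
        if match == "exact":
            return self._by_tags.get(frozenset(tags), [])
        if match == "subset":  # entries whose tags contain all predicted tags
            tags = frozenset(tags)
            return [i for i, t in enumerate(self.tag_sets) if tags <= t]
        raise ValueError(f"unknown match mode {match!r}")

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            exam_ids=np.array(self.exam_ids, dtype=np.str_),
            matrix=self.matrix,
            tag_sets=np.array(["\t".join(sorted(t)) for t in self.tag_sets], dtype=np.str_),
            captions=np.array(self.captions, dtype=np.str_),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RetrievalIndex":
        with np.load(path) as data:
            tag_sets = [
                frozenset(s.split("\t")) if s else frozenset()
                for s in (str(x) for x in data["tag_sets"])
            ]
            return cls(
                [str(e) for e in data["exam_ids"]],
                data["matrix"],
                tag_sets,
                [str(c) for c in data["captions"]],
            )


@dataclasses.dataclass
class RetrievedCaption:
    """Result of one retrieval; constrained=True means the tag filter held."""

    caption: str
    source_exam_id: str
    similarity: float
    constrained: bool

    def to_json(self, exam_id: str) -> str:
        return json.dumps(
            {
                "exam_id": exam_id,
                "caption": self.caption,
                "source_exam_id": self.source_exam_id,
                "similarity": self.similarity,
                "constrained": self.constrained,
            },
            ensure_ascii=False,
        )


def build_index(
    exams: Iterable[Exam],
    embeddings: EmbeddingTable,
    abnormal_only: bool = False,
) -> RetrievalIndex:
    """Index the training exams' embeddings, gold tags and gold captions."""
    exam_ids, rows, tag_sets, captions = [], [], [], []
    for exam in exams:
        if abnormal_only and not exam.is_abnormal:
            continue
        if exam.exam_id not in embeddings:
            raise ValueError(f"exam {exam.exam_id!r}: no embedding available")
        if not exam.gold_caption:
            raise ValueError(f"exam {exam.exam_id!r}: missing caption")
        exam_ids.append(exam.exam_id)
        rows.append(embeddings[exam.exam_id])
        tag_sets.append(exam.gold_tags)
        captions.append(exam.gold_caption)
    if not exam_ids:
        raise ValueError("no exams to index")
    return RetrievalIndex(exam_ids, np.stack(rows), tag_sets, captions)


def _best_entry(
    query: np.ndarray, index: RetrievalIndex, entry_indices: Sequence[int]
) -> tuple[int, float]:
    sub = index.matrix[list(entry_indices)]
    sims = cosine_to_index(query, sub)
    ids = [index.exam_ids[i] for i in entry_indices]
    local = top_neighbours(sims, ids, 1)[0]
    return entry_indices[local], float(sims[local])


def retrieve_caption(
    query: np.ndarray,
    predicted_tags: Iterable[str],
    index: RetrievalIndex,
    match: str = "exact",
) -> RetrievedCaption:
    """1-NN caption retrieval constrained to exams with the predicted tags.

    Falls back to the whole database when no index entry matches, flagging
    the result with ``constrained=False``.  Ties: higher similarity, then
    lower exam_id.
    """
    tags = frozenset(predicted_tags)
    entries = index.candidates(tags, match=match)
    constrained = bool(entries)
    if not constrained:
        entries = list(range(len(index)))
    best, sim = _best_entry(query, index, entries)
    return RetrievedCaption(
        caption=index.captions[best],
        source_exam_id=index.exam_ids[best],
        similarity=sim,
        constrained=constrained,
    )


def caption_unconstrained(query: np.ndarray, index: RetrievalIndex) -> RetrievedCaption:
    """Plain 1-NN caption over the whole database (no tag filter)."""
    best, sim = _best_entry(query, index, list(range(len(index))))
    return RetrievedCaption(
        caption=index.captions[best],
        source_exam_id=index.exam_ids[best],
        similarity=sim,
        constrained=False,
    )
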