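"""Abnormality-probability ranking of radiography exams.

The trained ranker is a dense sigmoid head on top of the exam embedding,
fit with binary cross-entropy on the normal/abnormal flag of the training
split.  Two reference rankers accompany it: a seeded uniform-random scorer
(the no-screening null) and a ranker that reuses the tagging head's output,
scoring each exam by its maximum per-tag probability.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .encoder import EmbeddingTable, ExamEmbedding
from .nets import SigmoidNet, TrainConfig, train_sigmoid_net


@dataclasses.dataclass
class AbnormalityScore:
    """Probability in [0, 1] that the exam contains an abnormality."""

    exam_id: str
    score: float

    def __post_init__(self) -> None:
        self.score = float(self.score)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"exam {self.exam_id!r}: score {self.score} outside [0, 1]")


class RankedList:
    """Exams ordered by descending abnormality score.

    Ties are broken by ascending exam_id so evaluation is deterministic.
    ``top_k(k)`` returns the prefix H_k handed to the tagging stage.
    """

    def __init__(self, entries: Sequence[tuple[str, float]]):
        self.entries = sorted(entries, key=lambda e: (-e[1], e[0]))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.entries)

    @property
    def exam_ids(self) -> list[str]:
        return [e for e, _ in self.entries]

    def top_k(self, k: int) -> list[tuple[str, float]]:
        if k < 1:
            raise ValueError("k must be >= 1")
        return self.entries[: min(k, len(self.entries))]


def rank_exams(scores: Iterable[AbnormalityScore]) -> RankedList:
    """Stable descending sort of scores into a RankedList."""
    scores = list(scores)
    ids = [s.exam_id for s in scores]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate exam_id(s) in scores: {dupes}")
    return RankedList([(s.exam_id, s.score) for s in scores])


class RankerModel:
    """Sigmoid head mapping an exam embedding to an abnormality probability."""

    def __init__(self, net: SigmoidNet):
        self.net = net

    @property
    def in_dim(self) -> int:
        return self.net.in_dim

    def score(self, vector: np.ndarray) -> float:
        return float(self.net.predict_proba(np.asarray(vector).reshape(1, -1))[0, 0])

    def save(self, path: str | Path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.net.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.biases)})
        arrays["hidden"] = np.array(self.net.hidden, dtype=np.int64)
        arrays["dims"] = np.array([self.net.in_dim, self.net.out_dim], dtype=np.int64)
        if self.net.input_mean is not None:
            arrays["input_mean"] = self.net.input_mean
            arrays["input_scale"] = self.net.input_scale
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RankerModel":
        with np.load(path) as data:
            in_dim, out_dim = (int(v) for v in data["dims"])
            net = SigmoidNet(in_dim, out_dim, tuple(int(h) for h in data["hidden"]))
            net.weights = [data[f"w{i}"] for i in range(len(net.weights))]
            net.biases = [data[f"b{i}"] for i in range(len(net.biases))]
            if "input_mean" in data:
                net.input_mean = data["input_mean"]
                net.input_scale = data["input_scale"]
        return cls(net)


def train_ranker(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[RankerModel, dict]:
    """Fit the abnormality head on embeddings and binary labels.

    Requires both classes in the training labels; returns (model, history)
    where history logs per-epoch train/validation loss and learning rate.
    """
    config = config or TrainConfig()
    y_train = np.asarray(y_train, dtype=np.float64).ravel()
    y_val = np.asarray(y_val, dtype=np.float64).ravel()
    classes = set(np.unique(y_train))
    if not classes.issuperset({0.0, 1.0}):
        raise ValueError(
            "training split must contain both normal and abnormal exams; "
            f"found labels {sorted(classes)}"
        )
    net, history = train_sigmoid_net(
        x_train, y_train[:, None], x_val, y_val[:, None], out_dim=1, config=config
    )
    return RankerModel(net), history


def score_abnormality(
    embedding: ExamEmbedding | np.ndarray, model: RankerModel, exam_id: str | None = None
) -> AbnormalityScore:
    """Score one exam embedding with a trained ranker."""
    if isinstance(embedding, ExamEmbedding):
        exam_id = embedding.exam_id
        vector = embedding.vector
    else:
        vector = np.asarray(embedding)
        exam_id = exam_id or "<anonymous>"
    if vector.shape[-1] != model.in_dim:
        raise ValueError(
            f"embedding dimension {vector.shape[-1]} does not match model ({model.in_dim})"
        )
    return AbnormalityScore(exam_id, model.score(vector))


def score_collection(table: EmbeddingTable, model: RankerModel) -> list[AbnormalityScore]:
    probs = model.net.predict_proba(table.matrix.astype(np.float64))[:, 0]
    return [AbnormalityScore(e, float(p)) for e, p in zip(table.exam_ids, probs)]


def random_ranker(exam_ids: Sequence[str], seed: int) -> list[AbnormalityScore]:
    """Seeded i.i.d. Uniform(0, 1) abnormality scores (no-screening null)."""
    rng = np.random.default_rng(seed)
    draws = rng.uniform(0.0, 1.0, size=len(exam_ids))
    return [AbnormalityScore(e, float(u)) for e, u in zip(exam_ids, draws)]


def max_tag_probability_ranker(tag_probabilities: Iterable) -> list[AbnormalityScore]:
    """Score each exam by the maximum of its per-tag probabilities.

    Accepts any iterable of objects with ``exam_id`` and ``probs`` fields
    (the tagging stage's TagProbabilities).
    """
    scores = []
    for tp in tag_probabilities:
        probs = np.asarray(tp.probs, dtype=np.float64)
        if probs.size == 0:
            raise ValueError(f"exam {tp.exam_id!r}: empty tag-probability vector")
        scores.append(AbnormalityScore(tp.exam_id, float(probs.max())))
    return scores
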