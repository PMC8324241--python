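"""Multi-label abnormality tagging with learned per-tag thresholds.

The tagging head has one sigmoid output node per vocabulary tag (A nodes)
and is trained with per-node binary cross-entropy on abnormal exams only.
A tag is assigned when its probability strictly exceeds a per-tag threshold
selected on the validation split by maximizing that tag's F1 over a fixed
grid.  Retrieval baselines (nearest-neighbour tag copying and k-NN tag
voting) and a seeded random tagger are provided for comparison.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np

from ._similarity import cosine_to_index, top_neighbours
from .data import TagVocabulary
from .nets import SigmoidNet, TrainConfig, train_sigmoid_net

log = logging.getLogger(__name__)

THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)
DEFAULT_THRESHOLD = 0.5


@dataclasses.dataclass
class TagProbabilities:
    """Per-exam probability vector aligned with the TagVocabulary order."""

    exam_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError(f"exam {self.exam_id!r}: probabilities outside [0, 1]")


@dataclasses.dataclass
class KnnConfig:
    """k-NN tag-voting settings; k is the number of retrieved neighbours."""

    k: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


class TagIndex:
    """Training-exam embeddings plus tag sets, for retrieval baselines."""

    def __init__(
        self,
        exam_ids: Sequence[str],
        matrix: np.ndarray,
        tag_sets: Sequence[frozenset[str]],
    ):
        if not (len(exam_ids) == matrix.shape[0] == len(tag_sets)):
            raise ValueError("exam_ids, matrix rows and tag_sets must align")
        if len(exam_ids) == 0:
            raise ValueError("empty tag index")
        self.exam_ids = list(exam_ids)
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.tag_sets = [frozenset(t) for t in tag_sets]

    def __len__(self) -> int:
        return len(self.exam_ids)


class TaggerModel:
    """Multi-label sigmoid head over a fixed tag vocabulary."""

    def __init__(self, net: SigmoidNet, vocabulary: TagVocabulary):
        if net.out_dim != len(vocabulary):
            raise ValueError("output nodes must match vocabulary size")
        self.net = net
        self.vocabulary = vocabulary

    @property
    def in_dim(self) -> int:
        return self.net.in_dim

    def predict(self, matrix: np.ndarray, exam_ids: Sequence[str]) -> list[TagProbabilities]:
        probs = self.net.predict_proba(np.asarray(matrix, dtype=np.float64))
        return [TagProbabilities(e, p) for e, p in zip(exam_ids, probs)]


def train_tagger(
    x_train: np.ndarray,
    train_tags: Sequence[Iterable[str]],
    x_val: np.ndarray,
    val_tags: Sequence[Iterable[str]],
    vocabulary: TagVocabulary,
    config: TrainConfig | None = None,
) -> tuple[TaggerModel, dict]:
    """Fit the A-node sigmoid head on abnormal exams only.

    Every training exam must carry at least one tag (the stage's contract:
    tagging is trained on abnormal exams); a vocabulary tag with zero
    training support triggers a warning, not an error.
    """
    config = config or TrainConfig()
    train_sets = [frozenset(t) for t in train_tags]
    empties = [i for i, t in enumerate(train_sets) if not t]
    if empties:
        raise ValueError(
            f"{len(empties)} training exam(s) have empty tag sets; the tagging "
            "stage is trained on abnormal (tagged) exams only"
        )
    y_train = np.stack([vocabulary.encode(t) for t in train_sets])
    unsupported = [t for i, t in enumerate(vocabulary) if y_train[:, i].sum() == 0]
    if unsupported:
        log.warning("vocabulary tags with zero training support: %s", unsupported)
    y_val = (
        np.stack([vocabulary.encode(t) for t in val_tags])
        if len(val_tags)
        else np.zeros((0, len(vocabulary)))
    )
    net, history = train_sigmoid_net(
        x_train, y_train, x_val, y_val, out_dim=len(vocabulary), config=config
    )
    return TaggerModel(net, vocabulary), history


def _f1_binary(pred: np.ndarray, gold: np.ndarray) -> float:
    tp = float(np.sum(pred * gold))
    denom = float(pred.sum() + gold.sum())
    if denom == 0.0:
        return 0.0
    return 2.0 * tp / denom


def learn_thresholds(
    val_probs: Sequence[TagProbabilities],
    val_tags: Sequence[Iterable[str]],
    vocabulary: TagVocabulary,
    grid: np.ndarray = THRESHOLD_GRID,
    per_tag: bool = True,
) -> np.ndarray:
    """Per-tag decision thresholds maximizing validation F1 on a fixed grid.

    For each tag, the smallest grid value attaining the maximal F1 is kept;
    a tag absent from the validation gold sets, or one where no grid point
    attains positive F1, falls back to 0.5.  With ``per_tag=False`` a single
    global threshold (maximizing mean per-tag F1) is replicated across tags.
    """
    if not len(val_probs):
        raise ValueError("empty validation set: cannot learn thresholds")
    probs = np.stack([tp.probs for tp in val_probs])
    gold = np.stack([vocabulary.encode(t) for t in val_tags])
    if probs.shape != gold.shape:
        raise ValueError("probability matrix and gold tags must align")
    a = len(vocabulary)
    # f1s[g, j] = F1 of tag j at grid point g
    f1s = np.zeros((len(grid), a))
    for gi, t in enumerate(grid):
        pred = (probs > t).astype(np.float64)
        tp = (pred * gold).sum(axis=0)
        denom = pred.sum(axis=0) + gold.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1s[gi] = np.where(denom > 0, 2.0 * tp / np.maximum(denom, 1e-300), 0.0)
    if not per_tag:
        mean_f1 = f1s.mean(axis=1)
        best = mean_f1.max()
        t = DEFAULT_THRESHOLD if best <= 0 else float(grid[int(np.argmax(mean_f1))])
        return np.full(a, t)
    thresholds = np.full(a, DEFAULT_THRESHOLD)
    supported = gold.sum(axis=0) > 0
    for j in range(a):
        if not supported[j]:
            continue
        best = f1s[:, j].max()
        if best <= 0.0:
            continue
        thresholds[j] = float(grid[int(np.argmax(f1s[:, j] == best))])
    return thresholds


def assign_tags(
    probs: TagProbabilities | np.ndarray,
    thresholds: np.ndarray,
    vocabulary: TagVocabulary,
) -> frozenset[str]:
    """Tags whose probability strictly exceeds the per-tag threshold."""
    vec = probs.probs if isinstance(probs, TagProbabilities) else np.asarray(probs, dtype=np.float64)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if vec.shape != thresholds.shape or len(vec) != len(vocabulary):
        raise ValueError("probabilities, thresholds and vocabulary must align")
    return vocabulary.decode(vec > thresholds)


def nn_tagger(query: np.ndarray, index: TagIndex) -> frozenset[str]:
    """Copy the tag set of the most cosine-similar training exam.

    Similarity ties are broken by ascending exam_id.
    """
    sims = cosine_to_index(query, index.matrix)
    best = top_neighbours(sims, index.exam_ids, 1)[0]
    return index.tag_sets[best]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def knn_tagger(query: np.ndarray, index: TagIndex, config: KnnConfig) -> frozenset[str]:
    """k-NN tag voting: keep the r most frequent tags of the k neighbours.

    r is the mean tag count of the retrieved exams, rounded half away from
    zero with a floor of 1.  Frequency ties prefer the tag whose supporting
    neighbour is most similar, then lexicographic order.
    """
    if config.k > len(index):
        raise ValueError(f"k={config.k} exceeds index size {len(index)}")
    sims = cosine_to_index(query, index.matrix)
    picked = top_neighbours(sims, index.exam_ids, config.k)
    counts: dict[str, int] = {}
    best_sim: dict[str, float] = {}
    total_tags = 0
    for i in picked:
        total_tags += len(index.tag_sets[i])
        for tag in index.tag_sets[i]:
            counts[tag] = counts.get(tag, 0) + 1
            best_sim[tag] = max(best_sim.get(tag, -np.inf), sims[i])
    if not counts:
        return frozenset()
    r = max(1, _round_half_away(total_tags / config.k))
    ordered = sorted(counts, key=lambda t: (-counts[t], -best_sim[t], t))
    return frozenset(ordered[:r])


def random_tagger(
    train_tags: Sequence[Iterable[str]],
    vocabulary: TagVocabulary,
    seed: int | np.random.Generator,
) -> frozenset[str]:
    """Seeded random tag set of size round(mean tags per training exam).

    Tags are drawn uniformly without replacement from the vocabulary; the
    draw size is capped at the vocabulary size and floored at 1.
    """
    train_sets = [frozenset(t) for t in train_tags]
    if not train_sets:
        raise ValueError("empty training tag sets")
    mean = sum(len(t) for t in train_sets) / len(train_sets)
    m = min(max(1, _round_half_away(mean)), len(vocabulary))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picked = rng.choice(len(vocabulary), size=m, replace=False)
    return frozenset(vocabulary[int(i)] for i in picked)
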