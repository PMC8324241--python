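"""Evaluation protocols: nDCG@k curves, exam-wise F1, text-overlap metrics
and clinical precision/recall via a pluggable caption labeler.

Ranking quality is measured with nDCG@k under binary relevance
(abnormal = 1), averaged over bootstrap resamples and smoothed along the
k axis with a centered moving average.  Tagging quality is the per-exam
set-overlap F1 between predicted and gold tags, macro-averaged over the
top-k ranked exams.  Caption quality combines word-overlap scores
(corpus BLEU-4, ROUGE-L F-measure) with clinical precision/recall computed
on labels a :class:`TextLabeler` extracts from system and reference texts.
"""

from __future__ import annotations

import dataclasses
import math
import re
from collections import Counter
from typing import Callable, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def ndcg_at_k(relevances: Sequence[int], k: int) -> float:
    """Normalized discounted cumulative gain at k for binary relevances.

    DCG@k = sum_{i=1..k} rel_i / log2(i + 1), normalized by the ideal DCG of
    the same relevance multiset.  Defined as 0.0 when no relevant item
    exists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = np.asarray(relevances, dtype=np.float64)
    if rel.size == 0:
        return 0.0
    if not np.all((rel == 0) | (rel == 1)):
        raise ValueError("relevances must be binary")
    discounts = 1.0 / np.log2(np.arange(2, rel.size + 2))
    k = min(k, rel.size)
    dcg = float(np.sum(rel[:k] * discounts[:k]))
    ideal = np.sort(rel)[::-1]
    idcg = float(np.sum(ideal[:k] * discounts[:k]))
    return dcg / idcg if idcg > 0 else 0.0


def precision_at_k(relevances: Sequence[int], k: int) -> float:
    """Fraction of relevant items among the top k (optional companion metric)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = np.asarray(relevances, dtype=np.float64)
    k = min(k, rel.size)
    return float(rel[:k].mean()) if k else 0.0


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving average; windows shrink at the edges."""
    vals = np.asarray(values, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    half = window // 2
    out = np.empty_like(vals)
    for i in range(vals.size):
        lo, hi = max(0, i - half), min(vals.size, i + half + 1)
        out[i] = vals[lo:hi].mean()
    return out


@dataclasses.dataclass
class EvaluationCurve:
    """A metric-vs-k curve with its bootstrap metadata."""

    ks: np.ndarray
    values: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        self.ks = np.asarray(self.ks, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.ks.shape != self.values.shape:
            raise ValueError("ks and values must align")


def bootstrap_curve(
    scores: Sequence[float],
    labels: Sequence[int],
    exam_ids: Sequence[str] | None = None,
    k_range: Sequence[int] = tuple(range(10, 81)),
    n_bootstrap: int = 1000,
    sample_size: int = 100,
    window: int = 5,
    seed: int = 0,
) -> EvaluationCurve:
    """Bootstrap-averaged nDCG@k curve with a centered moving average.

    Each replicate samples ``sample_size`` exams with replacement, ranks them
    by score (ties broken by exam_id), and computes nDCG@k for each k; the
    curve is the replicate mean, smoothed along k with the given window.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    n = scores.size
    if n == 0:
        raise ValueError("empty population")
    if labels.size != n:
        raise ValueError("scores and labels must align")
    if exam_ids is not None and len(exam_ids) != n:
        raise ValueError("exam_ids must align with scores")
    if sample_size > n:
        raise ValueError("sample_size exceeds population size")
    ks = np.asarray(list(k_range), dtype=np.int64)
    if np.any(ks < 1) or np.any(ks > sample_size):
        raise ValueError("k_range must lie within [1, sample_size]")
    ids = list(exam_ids) if exam_ids is not None else [f"{i:09d}" for i in range(n)]
    # global rank position of each exam: descending score, ascending exam_id
    order = sorted(range(n), key=lambda i: (-scores[i], ids[i]))
    rank_pos = np.empty(n, dtype=np.int64)
    rank_pos[order] = np.arange(n)

    rng = np.random.default_rng(seed)
    samples = rng.integers(0, n, size=(n_bootstrap, sample_size))
    pos = rank_pos[samples]
    sort_idx = np.argsort(pos, axis=1, kind="stable")
    rel = np.take_along_axis(labels[samples], sort_idx, axis=1)

    discounts = 1.0 / np.log2(np.arange(2, sample_size + 2))
    dcg = np.cumsum(rel * discounts, axis=1)
    ideal = np.sort(rel, axis=1)[:, ::-1]
    idcg = np.cumsum(ideal * discounts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ndcg = np.where(idcg > 0, dcg / np.maximum(idcg, 1e-300), 0.0)
    mean_curve = ndcg[:, ks - 1].mean(axis=0)
    smoothed = moving_average(mean_curve, window)
    return EvaluationCurve(
        ks,
        smoothed,
        {"n_bootstrap": n_bootstrap, "sample_size": sample_size, "window": window,
         "seed": seed},
    )


# ---------------------------------------------------------------------------
# tagging metrics
# ---------------------------------------------------------------------------

def f1_per_exam(predicted: Iterable[str], gold: Iterable[str]) -> float:
    """Set-overlap F1 = 2|P∩G| / (|P|+|G|); 1.0 when both sets are empty."""
    p, g = frozenset(predicted), frozenset(gold)
    if not p and not g:
        return 1.0
    if not p or not g:
        return 0.0
    return 2.0 * len(p & g) / (len(p) + len(g))


def f1_at_k(
    ranked_exam_ids: Sequence[str],
    predictions: dict[str, Iterable[str]],
    golds: dict[str, Iterable[str]],
    k: int,
) -> float:
    """Mean per-exam F1 over the top-k exams of a ranked list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ranked_exam_ids):
        raise ValueError(f"k={k} exceeds ranked list length {len(ranked_exam_ids)}")
    top = ranked_exam_ids[:k]
    missing = [e for e in top if e not in predictions]
    if missing:
        raise ValueError(f"missing predictions for top-k exam(s): {missing[:5]}")
    return float(np.mean([f1_per_exam(predictions[e], golds[e]) for e in top]))


# ---------------------------------------------------------------------------
# text preprocessing and word-overlap metrics
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def preprocess_text(text: str) -> list[str]:
    """Tokenize, lowercase, drop digit tokens and single-character tokens."""
    tokens = _TOKEN_RE.findall(text.lower())
    return [t for t in tokens if len(t) > 1 and not t.isdigit()]


def _ngram_counts(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu(
    candidates: Sequence[str],
    references: Sequence[str],
    max_order: int = 4,
    preprocess: bool = True,
) -> float:
    """Corpus-level BLEU (n-grams up to 4, brevity penalty), on a 0-100 scale.

    A corpus with no unigram overlap at all scores 0.  Higher-order
    zero-match counts are exponentially smoothed (each successive zero-count
    order halves a pseudo-count), the standard mteval scheme for short
    texts; orders longer than every candidate are excluded from the
    geometric mean.
    """
    if len(candidates) != len(references):
        raise ValueError("candidate and reference lists must align")
    if not candidates:
        raise ValueError("empty corpus")
    tok: Callable[[str], list[str]] = preprocess_text if preprocess else str.split
    sys_len = ref_len = 0
    correct = [0] * max_order
    total = [0] * max_order
    for cand, ref in zip(candidates, references):
        c_tok, r_tok = tok(cand), tok(ref)
        sys_len += len(c_tok)
        ref_len += len(r_tok)
        for n in range(1, max_order + 1):
            c_counts = _ngram_counts(c_tok, n)
            r_counts = _ngram_counts(r_tok, n)
            total[n - 1] += sum(c_counts.values())
            correct[n - 1] += sum(min(c, r_counts[g]) for g, c in c_counts.items())
    if sys_len == 0 or correct[0] == 0:
        return 0.0
    log_precisions = []
    smooth = 1.0
    for n in range(1, max_order + 1):
        if total[n - 1] == 0:
            break  # no candidate long enough: shorten the effective order
        if correct[n - 1] == 0:
            smooth *= 2.0
            p = 1.0 / (smooth * total[n - 1])
        else:
            p = correct[n - 1] / total[n - 1]
        log_precisions.append(math.log(p))
    if not log_precisions:
        return 0.0
    brevity = 1.0 if sys_len >= ref_len else math.exp(1.0 - ref_len / sys_len)
    return 100.0 * brevity * math.exp(sum(log_precisions) / len(log_precisions))


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def rouge_l_f(candidate: str, reference: str, preprocess: bool = True) -> float:
    """ROUGE-L F-measure: harmonic mean of LCS precision and recall."""
    tok: Callable[[str], list[str]] = preprocess_text if preprocess else str.split
    c_tok, r_tok = tok(candidate), tok(reference)
    if not c_tok or not r_tok:
        return 0.0
    lcs = _lcs_length(c_tok, r_tok)
    if lcs == 0:
        return 0.0
    p, r = lcs / len(c_tok), lcs / len(r_tok)
    return 2.0 * p * r / (p + r)


# ---------------------------------------------------------------------------
# clinical correctness via a pluggable caption labeler
# ---------------------------------------------------------------------------

@runtime_checkable
class TextLabeler(Protocol):
    """Deterministic callable mapping a caption to a set of clinical labels."""

    name: str
    label_space: frozenset[str]

    def __call__(self, caption: str) -> frozenset[str]: ...


DEFAULT_NEGATION_CUES = ("no", "not", "without", "negative for", "free of", "absent")
NEGATION_WINDOW = 3  # tokens before the trigger within which a cue negates


class KeywordLabeler:
    """Rule-based caption labeler: trigger phrases with a negation window.

    A label is assigned when one of its trigger phrases occurs in the
    preprocessed caption and no negation cue ends within ``NEGATION_WINDOW``
    tokens before the phrase.  Uncertainty hedges ("possible", "cannot
    exclude") are not negations, so hedged mentions count as positive.
    """

    def __init__(
        self,
        lexicon: dict[str, Sequence[str]],
        negation_cues: Sequence[str] = DEFAULT_NEGATION_CUES,
    ):
        if not lexicon:
            raise ValueError("empty label lexicon")
        self.name = "keyword-labeler"
        self.label_space = frozenset(lexicon)
        self._triggers = {
            label: [tuple(preprocess_text(p)) for p in phrases]
            for label, phrases in lexicon.items()
        }
        self._negations = [tuple(preprocess_text(c)) for c in negation_cues]

    def __call__(self, caption: str) -> frozenset[str]:
        tokens = preprocess_text(caption)
        found = set()
        for label, phrases in self._triggers.items():
            for phrase in phrases:
                if not phrase:
                    continue
                for start in self._phrase_starts(tokens, phrase):
                    if not self._negated(tokens, start):
                        found.add(label)
                        break
                if label in found:
                    break
        return frozenset(found)

    @staticmethod
    def _phrase_starts(tokens: list[str], phrase: tuple[str, ...]) -> list[int]:
        n = len(phrase)
        return [i for i in range(len(tokens) - n + 1) if tuple(tokens[i : i + n]) == phrase]

    def _negated(self, tokens: list[str], start: int) -> bool:
        lo = max(0, start - NEGATION_WINDOW)
        for cue in self._negations:
            n = len(cue)
            for i in range(lo, start):
                if i + n <= start and tuple(tokens[i : i + n]) == cue:
                    return True
        return False


def keyword_labeler(
    lexicon: dict[str, Sequence[str]],
    negation_cues: Sequence[str] = DEFAULT_NEGATION_CUES,
) -> KeywordLabeler:
    """Build a rule-based trigger-phrase labeler over the given lexicon."""
    return KeywordLabeler(lexicon, negation_cues)


def clinical_scores_per_exam(
    system_captions: Sequence[str],
    gold_captions: Sequence[str],
    labeler: TextLabeler,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-exam clinical precision and recall of extracted label sets.

    P_e = |L_sys ∩ L_gold| / |L_sys| and R_e likewise over |L_gold|; an
    empty denominator set scores 0 against a non-empty one and 1 when both
    are empty (vacuous agreement).
    """
    if len(system_captions) != len(gold_captions):
        raise ValueError("system and gold caption lists must align")
    precisions, recalls = [], []
    for sys_cap, gold_cap in zip(system_captions, gold_captions):
        l_sys, l_gold = labeler(sys_cap), labeler(gold_cap)
        shared = len(l_sys & l_gold)
        if not l_sys and not l_gold:
            p = r = 1.0
        else:
            p = shared / len(l_sys) if l_sys else 0.0
            r = shared / len(l_gold) if l_gold else 0.0
        precisions.append(p)
        recalls.append(r)
    return np.asarray(precisions), np.asarray(recalls)


def clinical_precision_recall(
    system_captions: Sequence[str],
    gold_captions: Sequence[str],
    labeler: TextLabeler,
) -> tuple[float, float]:
    """Mean per-exam clinical precision and recall (CP, CR)."""
    p, r = clinical_scores_per_exam(system_captions, gold_captions, labeler)
    return float(p.mean()), float(r.mean())


def plot_curves(
    curves: dict[str, EvaluationCurve],
    path: str,
    ylabel: str = "nDCG@k",
    title: str | None = None,
) -> None:
    """Plot metric-vs-k curves for several methods to a PNG file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.ks, curve.values, label=label)
    ax.set_xlabel("k")
    ax.set_ylabel(ylabel)
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
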