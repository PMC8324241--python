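"""Evaluation metrics against hand computations and independent oracles."""

import itertools
import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radtriage as rt
from radtriage.evaluation import (
    clinical_scores_per_exam,
    moving_average,
    precision_at_k,
)


# --- independent oracles (deliberately separate code paths) ---------------

def ndcg_oracle(rel, k):
    """Direct formula with explicit loops."""
    dcg = sum(r / math.log2(i + 2) for i, r in enumerate(rel[:k]))
    ideal = sorted(rel, reverse=True)
    idcg = sum(r / math.log2(i + 2) for i, r in enumerate(ideal[:k]))
    return dcg / idcg if idcg > 0 else 0.0


def lcs_oracle(a, b):
    """Recursive memoized LCS length."""
    @lru_cache(maxsize=None)
    def go(i, j):
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + go(i + 1, j + 1)
        return max(go(i + 1, j), go(i, j + 1))
    return go(0, 0)


def bleu_oracle(cands, refs):
    """Corpus BLEU-4 with mteval exponential smoothing, exact fractions."""
    def grams(toks, n):
        out = {}
        for i in range(len(toks) - n + 1):
            g = tuple(toks[i:i + n])
            out[g] = out.get(g, 0) + 1
        return out

    correct = {n: 0 for n in range(1, 5)}
    total = {n: 0 for n in range(1, 5)}
    sys_len = ref_len = 0
    for c, r in zip(cands, refs):
        ct = rt.preprocess_text(c)
        rtoks = rt.preprocess_text(r)
        sys_len += len(ct)
        ref_len += len(rtoks)
        for n in range(1, 5):
            cg, rg = grams(ct, n), grams(rtoks, n)
            total[n] += sum(cg.values())
            for g, cnt in cg.items():
                correct[n] += min(cnt, rg.get(g, 0))
    if sys_len == 0 or correct[1] == 0:
        return 0.0
    logs = []
    smooth = 1
    for n in range(1, 5):
        if total[n] == 0:
            break
        if correct[n] == 0:
            smooth *= 2
            p = Fraction(1, smooth * total[n])
        else:
            p = Fraction(correct[n], total[n])
        logs.append(math.log(p))
    if not logs:
        return 0.0
    bp = 1.0 if sys_len >= ref_len else math.exp(1 - ref_len / sys_len)
    return 100.0 * bp * math.exp(sum(logs) / len(logs))


# --- ranking metrics ------------------------------------------------------

class TestNdcg:
    def test_ideal_order_scores_one(self):
        assert rt.ndcg_at_k([1, 1, 0], 3) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # DCG = 1/log2(3) + 1/log2(4); IDCG = 1 + 1/log2(3)
        want = (1 / math.log2(3) + 0.5) / (1 + 1 / math.log2(3))
        assert rt.ndcg_at_k([0, 1, 1], 3) == pytest.approx(want, abs=1e-10)
        assert rt.ndcg_at_k([0, 1, 1], 3) == pytest.approx(0.6934, abs=1e-4)

    def test_no_relevant_items_scores_zero(self):
        assert rt.ndcg_at_k([0, 0, 0, 0], 2) == 0.0

    def test_matches_enumeration_oracle_up_to_six_items(self):
        for n in range(1, 7):
            for rel in itertools.product([0, 1], repeat=n):
                for k in range(1, n + 1):
                    assert rt.ndcg_at_k(list(rel), k) == pytest.approx(
                        ndcg_oracle(list(rel), k), abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            rt.ndcg_at_k([1, 0], 0)
        with pytest.raises(ValueError):
            rt.ndcg_at_k([2, 0], 1)

    def test_precision_at_k_companion(self):
        assert precision_at_k([1, 0, 1, 0], 2) == pytest.approx(0.5)


class TestMovingAverage:
    def test_centered_window_with_shrinking_edges(self):
        got = moving_average([1, 2, 3, 4, 5], 3)
        assert got == pytest.approx([1.5, 2, 3, 4, 4.5])

    def test_window_one_is_identity(self):
        vals = [0.3, 0.1, 0.9]
        assert moving_average(vals, 1) == pytest.approx(vals)

    def test_constant_series_unchanged(self):
        assert moving_average([0.7] * 10, 5) == pytest.approx([0.7] * 10)


class TestBootstrapCurve:
    def test_perfect_ranker_curve_is_identically_one(self):
        n = 150
        labels = np.array([1] * 50 + [0] * 100)
        scores = np.linspace(1, 0, n)  # abnormal first
        curve = rt.bootstrap_curve(scores, labels, n_bootstrap=50,
                                   sample_size=100, seed=0)
        assert np.allclose(curve.values, 1.0)

    def test_same_seed_reproduces_curve(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=200)
        labels = (rng.uniform(size=200) < 0.4).astype(int)
        a = rt.bootstrap_curve(scores, labels, n_bootstrap=100, seed=5)
        b = rt.bootstrap_curve(scores, labels, n_bootstrap=100, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_random_ranker_curve_matches_permutation_oracle(self):
        """Bootstrap nDCG of uniform-random scores agrees with a brute-force
        random-permutation estimate on the same population (abnormal
        fraction 0.32) to within 0.02."""
        rng = np.random.default_rng(9)
        n = 400
        labels = (rng.uniform(size=n) < 0.32).astype(int)
        ids = [f"e{i}" for i in range(n)]
        ks = [10, 20, 40, 80]
        # expected curve of the random ranker, averaged over score draws
        curves = [
            rt.bootstrap_curve(
                np.array([s.score for s in rt.random_ranker(ids, seed=seed)]),
                labels, ids, k_range=ks, n_bootstrap=100, sample_size=100,
                window=1, seed=10_000 + seed).values
            for seed in range(60)
        ]
        curve = np.mean(curves, axis=0)
        # oracle: sample 100 labels with replacement, shuffle, direct formula
        reps = 4000
        oracle = np.zeros(len(ks))
        for _ in range(reps):
            sample = labels[rng.integers(0, n, size=100)]
            rng.shuffle(sample)
            oracle += [ndcg_oracle(list(sample), k) for k in ks]
        oracle /= reps
        assert np.all(np.abs(curve - oracle) <= 0.02)

    def test_rejects_empty_population_and_bad_k(self):
        with pytest.raises(ValueError):
            rt.bootstrap_curve([], [], n_bootstrap=2)
        with pytest.raises(ValueError):
            rt.bootstrap_curve([0.5] * 10, [1] * 10, k_range=[200],
                               sample_size=10)


# --- tagging metrics ------------------------------------------------------

class TestF1:
    def test_half_overlap(self):
        assert rt.f1_per_exam({"a", "b"}, {"b", "c"}) == pytest.approx(0.5)

    def test_identity_and_boundaries(self):
        assert rt.f1_per_exam({"a"}, {"a"}) == 1.0
        assert rt.f1_per_exam(set(), {"a"}) == 0.0
        assert rt.f1_per_exam({"a"}, set()) == 0.0
        assert rt.f1_per_exam(set(), set()) == 1.0

    def test_matches_set_overlap_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        universe = list("abcdefgh")
        for _ in range(200):
            p = {t for t in universe if rng.uniform() < 0.4}
            g = {t for t in universe if rng.uniform() < 0.4}
            inter = sum(1 for t in universe if t in p and t in g)
            if not p and not g:
                want = 1.0
            elif not p or not g:
                want = 0.0
            else:
                want = 2 * inter / (len(p) + len(g))
            assert rt.f1_per_exam(p, g) == pytest.approx(want)

    def test_f1_at_k_averages_top_k(self):
        ranked = ["a", "b", "c"]
        preds = {"a": {"x"}, "b": {"x", "y"}, "c": set()}
        golds = {"a": {"x"}, "b": {"y", "z"}, "c": {"q"}}
        want = (1.0 + 0.5) / 2
        assert rt.f1_at_k(ranked, preds, golds, 2) == pytest.approx(want)

    def test_f1_at_k_enumeration_oracle(self):
        ranked = [f"e{i}" for i in range(5)]
        preds = {"e0": {"a"}, "e1": {"a", "b"}, "e2": {"c"}, "e3": set(),
                 "e4": {"b", "c"}}
        golds = {"e0": {"a", "b"}, "e1": {"a", "b"}, "e2": {"a"}, "e3": set(),
                 "e4": {"c"}}
        per = [rt.f1_per_exam(preds[e], golds[e]) for e in ranked]
        for k in range(1, 6):
            assert rt.f1_at_k(ranked, preds, golds, k) == pytest.approx(
                sum(per[:k]) / k)

    def test_missing_prediction_rejected(self):
        with pytest.raises(ValueError, match="missing predictions"):
            rt.f1_at_k(["a"], {}, {"a": set()}, 1)


# --- text preprocessing and overlap metrics -------------------------------

class TestPreprocess:
    def test_drops_digits_and_single_characters(self):
        assert rt.preprocess_text("The heart is 2 x normal.") == \
            ["the", "heart", "is", "normal"]

    def test_empty_string(self):
        assert rt.preprocess_text("") == []

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.text(alphabet="abc12 .X-", max_size=40))
    def test_idempotent_under_rejoin(self, text):
        once = rt.preprocess_text(text)
        assert rt.preprocess_text(" ".join(once)) == once


class TestBleu:
    def test_identity_corpus_scores_100(self):
        caps = ["no acute cardiopulmonary abnormality is seen",
                "the heart is enlarged with effusion"]
        assert rt.bleu(caps, caps) == pytest.approx(100.0)

    def test_disjoint_corpus_scores_zero(self):
        assert rt.bleu(["alpha beta gamma delta"], ["omega psi chi phi"]) == 0.0

    def test_matches_independent_oracle_on_random_corpora(self):
        rng = np.random.default_rng(4)
        words = "heart lung clear effusion nodule normal mild seen the is".split()
        for trial in range(30):
            n = int(rng.integers(1, 6))
            cands = [" ".join(rng.choice(words, size=rng.integers(2, 12)))
                     for _ in range(n)]
            refs = [" ".join(rng.choice(words, size=rng.integers(2, 12)))
                    for _ in range(n)]
            assert rt.bleu(cands, refs) == pytest.approx(
                bleu_oracle(cands, refs), abs=1e-4)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty corpus"):
            rt.bleu([], [])


class TestRougeL:
    def test_hand_computed_example(self):
        # LCS=3 over 3 candidate and 4 reference tokens: P=1, R=0.75, F=6/7
        got = rt.rouge_l_f("no acute disease", "no acute cardiopulmonary disease")
        assert got == pytest.approx(6 / 7, abs=1e-10)
        assert got == pytest.approx(0.857, abs=1e-3)

    def test_identical_and_disjoint_texts(self):
        assert rt.rouge_l_f("clear lungs seen", "clear lungs seen") == 1.0
        assert rt.rouge_l_f("alpha beta", "gamma delta") == 0.0
        assert rt.rouge_l_f("", "anything here") == 0.0

    def test_matches_recursive_lcs_oracle(self):
        rng = np.random.default_rng(5)
        words = list("abcdefg")
        for _ in range(100):
            c = [words[i] for i in rng.integers(0, 7, size=rng.integers(1, 10))]
            r = [words[i] for i in rng.integers(0, 7, size=rng.integers(1, 10))]
            cand, ref = " ".join(f"w{w}" for w in c), " ".join(f"w{w}" for w in r)
            lcs = lcs_oracle(tuple(c), tuple(r))
            if lcs == 0:
                want = 0.0
            else:
                p, rr = lcs / len(c), lcs / len(r)
                want = 2 * p * rr / (p + rr)
            assert rt.rouge_l_f(cand, ref) == pytest.approx(want, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["aa", "bb", "cc", "dd"]), max_size=8),
           st.lists(st.sampled_from(["aa", "bb", "cc", "dd"]), max_size=8))
    def test_symmetric_under_candidate_reference_swap(self, a, b):
        # F is the harmonic mean of P and R, which swap roles symmetrically
        assert rt.rouge_l_f(" ".join(a), " ".join(b)) == pytest.approx(
            rt.rouge_l_f(" ".join(b), " ".join(a)))


# --- clinical precision / recall ------------------------------------------

LEXICON = {
    "pneumonia": ["pneumonia"],
    "edema": ["edema", "pulmonary edema"],
    "effusion": ["pleural effusion", "effusion"],
    "cardiomegaly": ["cardiomegaly", "enlarged heart"],
}


class TestKeywordLabeler:
    def test_negation_window_blocks_label(self):
        labeler = rt.keyword_labeler(LEXICON)
        assert "effusion" not in labeler("there is no pleural effusion")

    def test_uncertain_mention_maps_to_positive(self):
        labeler = rt.keyword_labeler(LEXICON)
        assert labeler("possible pneumonia") == frozenset({"pneumonia"})
        assert labeler("cannot exclude pneumonia") == frozenset({"pneumonia"})

    def test_multiple_positive_mentions(self):
        labeler = rt.keyword_labeler(LEXICON)
        got = labeler("mild cardiomegaly and edema")
        assert got == frozenset({"cardiomegaly", "edema"})

    def test_negation_outside_window_does_not_block(self):
        labeler = rt.keyword_labeler(LEXICON)
        got = labeler("no fracture seen but there is clear pulmonary edema")
        assert "edema" in got

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            rt.keyword_labeler({})


class TestClinicalPrecisionRecall:
    def test_hand_computed_overlap(self):
        labeler = rt.keyword_labeler(LEXICON)
        cp, cr = rt.clinical_precision_recall(
            ["pneumonia with edema"], ["pneumonia present"], labeler)
        assert cp == pytest.approx(0.5)
        assert cr == pytest.approx(1.0)

    def test_identical_captions_score_one(self):
        labeler = rt.keyword_labeler(LEXICON)
        caps = ["pneumonia and effusion", "no findings", "edema noted"]
        assert rt.clinical_precision_recall(caps, caps, labeler) == (1.0, 1.0)

    def test_disjoint_labels_score_zero(self):
        labeler = rt.keyword_labeler(LEXICON)
        cp, cr = rt.clinical_precision_recall(
            ["pneumonia"], ["pleural effusion"], labeler)
        assert cp == 0.0 and cr == 0.0

    def test_matches_set_overlap_oracle_on_random_instances(self):
        labeler = rt.keyword_labeler(LEXICON)
        rng = np.random.default_rng(6)
        phrases = ["pneumonia", "pulmonary edema", "pleural effusion",
                   "enlarged heart", "clear lungs"]
        for _ in range(100):
            sys_cap = " and ".join(rng.choice(phrases, size=rng.integers(0, 4)))
            gold_cap = " and ".join(rng.choice(phrases, size=rng.integers(0, 4)))
            ls, lg = labeler(sys_cap), labeler(gold_cap)
            if not ls and not lg:
                wp = wr = 1.0
            else:
                wp = len(ls & lg) / len(ls) if ls else 0.0
                wr = len(ls & lg) / len(lg) if lg else 0.0
            p, r = clinical_scores_per_exam([sys_cap], [gold_cap], labeler)
            assert p[0] == pytest.approx(wp) and r[0] == pytest.approx(wr)
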