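"""Shared fixtures: tiny programmatic collections and a small generated study."""

from __future__ import annotations

import numpy as np
import pytest

import radtriage as rt
from radtriage.data import Exam, ExamCollection, TagVocabulary


@pytest.fixture()
def vocab() -> TagVocabulary:
    return TagVocabulary(["cardiomegaly", "effusion", "nodule"])


@pytest.fixture()
def tiny_exams(tmp_path):
    """Six exams with stub image files (1x1 PNGs) across all splits."""
    from PIL import Image

    def img(name):
        p = tmp_path / name
        Image.new("L", (8, 8), 64).save(p)
        return p

    specs = [
        ("e1", "train", True, {"cardiomegaly", "effusion"}, "enlarged heart with effusion."),
        ("e2", "train", True, {"nodule"}, "a nodule is seen."),
        ("e3", "train", False, set(), "lungs are clear."),
        ("e4", "val", True, {"cardiomegaly"}, "enlarged heart."),
        ("e5", "test", True, {"effusion"}, "effusion present."),
        ("e6", "test", False, set(), "no abnormality."),
    ]
    exams = [
        Exam(eid, (img(f"{eid}_f.png"), img(f"{eid}_l.png")), split, abn,
             frozenset(tags), cap)
        for eid, split, abn, tags, cap in specs
    ]
    return exams


@pytest.fixture()
def tiny_collection(tiny_exams) -> ExamCollection:
    vocab = TagVocabulary(["cardiomegaly", "effusion", "nodule"])
    return ExamCollection(tiny_exams, vocab)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A generated 120-exam collection with its embeddings, reused read-only."""
    out = tmp_path_factory.mktemp("small_study")
    config = rt.SynthConfig(n_exams=120, seed=7)
    collection = rt.generate_collection(config, out)
    encoder = rt.make_small_cnn(config.image_size, 96, seed=7)
    table = rt.encode_collection(collection, encoder)
    return collection, table, encoder


def split_matrix(collection, table, split, abnormal_only=False):
    exams = [e for e in collection.split(split) if e.is_abnormal or not abnormal_only]
    ids = [e.exam_id for e in exams]
    return exams, table.subset(ids).matrix.astype(np.float64)
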