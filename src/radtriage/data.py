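"""Exam collections, tag vocabularies and dataset manifest I/O.

A radiography exam couples two images (one frontal, one lateral view) with a
normal/abnormal flag, a set of free-text abnormality tags and a free-text
"findings" caption.  Collections are exchanged as JSONL manifests, one object
per exam, with image paths resolved relative to the manifest file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")

_MANIFEST_FIELDS = ("exam_id", "frontal", "lateral", "split", "is_abnormal", "tags", "caption")


class ManifestError(ValueError):
    """Raised when a manifest record violates the collection contract."""


def normalize_tag(tag: str) -> str:
    """Canonical tag form: lowercase, trimmed, single internal spaces."""
    return re.sub(r"\s+", " ", tag.strip().lower())


class TagVocabulary:
    """Ordered, duplicate-free list of abnormality tags.

    The order is significant: it fixes the index of each output node of the
    multi-label tagging head, so two vocabularies are equal only when their
    tags appear in the same order.
    """

    def __init__(self, tags: Iterable[str]):
        seen: dict[str, int] = {}
        for tag in tags:
            norm = normalize_tag(tag)
            if not norm:
                raise ManifestError("empty tag string in vocabulary")
            if norm in seen:
                raise ManifestError(f"duplicate tag in vocabulary: {norm!r}")
            seen[norm] = len(seen)
        self._tags: tuple[str, ...] = tuple(seen)
        self._index = seen

    @property
    def tags(self) -> tuple[str, ...]:
        return self._tags

    def __len__(self) -> int:
        return len(self._tags)

    def __iter__(self) -> Iterator[str]:
        return iter(self._tags)

    def __contains__(self, tag: str) -> bool:
        return normalize_tag(tag) in self._index

    def __getitem__(self, i: int) -> str:
        return self._tags[i]

    def index(self, tag: str) -> int:
        return self._index[normalize_tag(tag)]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TagVocabulary) and self._tags == other._tags

    def __repr__(self) -> str:
        return f"TagVocabulary({list(self._tags)!r})"

    def encode(self, tags: Iterable[str]) -> np.ndarray:
        """Binary indicator vector of length A; unknown tags are ignored."""
        vec = np.zeros(len(self._tags), dtype=np.float64)
        for tag in tags:
            idx = self._index.get(normalize_tag(tag))
            if idx is not None:
                vec[idx] = 1.0
        return vec

    def decode(self, indicator: np.ndarray) -> frozenset[str]:
        return frozenset(t for t, on in zip(self._tags, indicator) if on)


@dataclasses.dataclass
class Exam:
    """One radiography exam: two views, label, tags and findings text."""

    exam_id: str
    image_paths: tuple[Path, Path]  # (frontal, lateral)
    split: str
    is_abnormal: bool
    gold_tags: frozenset[str] = frozenset()
    gold_caption: str = ""

    def __post_init__(self) -> None:
        if len(self.image_paths) != 2:
            raise ManifestError(
                f"exam {self.exam_id!r}: expected exactly 2 image paths, "
                f"got {len(self.image_paths)}"
            )
        self.image_paths = (Path(self.image_paths[0]), Path(self.image_paths[1]))
        if self.split not in SPLITS:
            raise ManifestError(f"exam {self.exam_id!r}: unknown split {self.split!r}")
        self.gold_tags = frozenset(normalize_tag(t) for t in self.gold_tags)
        if not self.is_abnormal and self.gold_tags:
            raise ManifestError(
                f"exam {self.exam_id!r}: normal exam must have an empty tag set"
            )

    @property
    def frontal(self) -> Path:
        return self.image_paths[0]

    @property
    def lateral(self) -> Path:
        return self.image_paths[1]


class ExamCollection:
    """A list of exams plus the tag vocabulary in force.

    The vocabulary is, by convention, built from the training split only, in
    first-appearance order; tags on val/test exams that never occur in
    training are kept for evaluation but can never be predicted.
    """

    def __init__(self, exams: Sequence[Exam], vocabulary: TagVocabulary):
        ids = [e.exam_id for e in exams]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ManifestError(f"duplicate exam_id(s): {sorted(dupes)}")
        self.exams: list[Exam] = list(exams)
        self.vocabulary = vocabulary
        self._by_id = {e.exam_id: e for e in self.exams}

    def __len__(self) -> int:
        return len(self.exams)

    def __iter__(self) -> Iterator[Exam]:
        return iter(self.exams)

    def __getitem__(self, exam_id: str) -> Exam:
        return self._by_id[exam_id]

    def __contains__(self, exam_id: str) -> bool:
        return exam_id in self._by_id

    def split(self, name: str) -> list[Exam]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return [e for e in self.exams if e.split == name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExamCollection):
            return NotImplemented
        return self.vocabulary == other.vocabulary and self.exams == other.exams


def build_vocabulary(exams: Iterable[Exam], tag_lists: dict[str, list[str]] | None = None) -> TagVocabulary:
    """Vocabulary from train-split tags in first-appearance order.

    ``tag_lists`` optionally supplies the per-exam tag order (e.g. the order
    in the manifest record); without it, tags within one exam are sorted for
    determinism.
    """
    ordered: dict[str, None] = {}
    for exam in exams:
        if exam.split != "train":
            continue
        if tag_lists is not None and exam.exam_id in tag_lists:
            tags: Iterable[str] = tag_lists[exam.exam_id]
        else:
            tags = sorted(exam.gold_tags)
        for tag in tags:
            ordered.setdefault(normalize_tag(tag), None)
    return TagVocabulary(ordered)


def _warn_out_of_vocabulary(exams: Iterable[Exam], vocab: TagVocabulary) -> None:
    for exam in exams:
        if exam.split == "train":
            continue
        oov = sorted(t for t in exam.gold_tags if t not in vocab)
        if oov:
            log.warning(
                "exam %s (%s split): gold tags %s not in training vocabulary; "
                "they are kept for evaluation but can never be predicted",
                exam.exam_id, exam.split, oov,
            )


def _record_to_exam(rec: dict, base: Path, lineno: int, check_images: bool) -> tuple[Exam, list[str]]:
    missing = [f for f in _MANIFEST_FIELDS if f not in rec]
    if missing:
        raise ManifestError(
            f"manifest line {lineno}: record {rec.get('exam_id', '<no id>')!r} "
            f"missing field(s) {missing}"
        )
    exam_id = str(rec["exam_id"])
    paths = []
    for key in ("frontal", "lateral"):
        p = Path(rec[key])
        if not p.is_absolute():
            p = base / p
        if check_images and not p.is_file():
            raise ManifestError(f"exam {exam_id!r}: image path does not exist: {p}")
        paths.append(p)
    tags = rec["tags"]
    if isinstance(tags, str):  # CSV dialect: ';'-joined
        tags = [t for t in tags.split(";") if t.strip()]
    exam = Exam(
        exam_id=exam_id,
        image_paths=(paths[0], paths[1]),
        split=str(rec["split"]),
        is_abnormal=bool(rec["is_abnormal"]),
        gold_tags=frozenset(tags),
        gold_caption=str(rec["caption"]),
    )
    return exam, [normalize_tag(t) for t in tags]


def load_manifest(path: str | Path, check_images: bool = True) -> ExamCollection:
    """Read a JSONL manifest (one exam object per line) into a collection.

    Relative image paths are resolved against the manifest's directory.  The
    vocabulary is built from train-split tags in first-appearance order.
    """
    path = Path(path)
    base = path.parent
    exams: list[Exam] = []
    tag_lists: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ManifestError(f"manifest line {lineno}: invalid JSON ({exc})") from exc
            exam, tags = _record_to_exam(rec, base, lineno, check_images)
            exams.append(exam)
            tag_lists[exam.exam_id] = tags
    vocab = build_vocabulary(exams, tag_lists)
    collection = ExamCollection(exams, vocab)
    _warn_out_of_vocabulary(exams, vocab)
    return collection


def load_manifest_csv(path: str | Path, check_images: bool = True) -> ExamCollection:
    """Read a flat CSV manifest with ';'-joined tags (same fields as JSONL)."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    exams: list[Exam] = []
    tag_lists: dict[str, list[str]] = {}
    for lineno, row in enumerate(frame.to_dict("records"), start=2):
        rec = dict(row)
        rec["is_abnormal"] = str(rec.get("is_abnormal", "")).strip().lower() in ("1", "true", "yes")
        exam, tags = _record_to_exam(rec, path.parent, lineno, check_images)
        exams.append(exam)
        tag_lists[exam.exam_id] = tags
    vocab = build_vocabulary(exams, tag_lists)
    collection = ExamCollection(exams, vocab)
    _warn_out_of_vocabulary(exams, vocab)
    return collection


def _relative_or_absolute(p: Path, base: Path) -> str:
    try:
        return str(p.relative_to(base))
    except ValueError:
        return str(p)


def write_manifest(collection: ExamCollection, path: str | Path) -> Path:
    """Write a collection as JSONL; ``load_manifest`` round-trips it exactly.

    Per-exam tags are written in vocabulary order (out-of-vocabulary tags
    last, sorted), which reproduces the vocabulary's first-appearance order
    on reload.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent.resolve()
    vocab = collection.vocabulary
    with open(path, "w", encoding="utf-8") as fh:
        for exam in collection:
            in_vocab = sorted((t for t in exam.gold_tags if t in vocab), key=vocab.index)
            oov = sorted(t for t in exam.gold_tags if t not in vocab)
            rec = {
                "exam_id": exam.exam_id,
                "frontal": _relative_or_absolute(exam.frontal.resolve(), base),
                "lateral": _relative_or_absolute(exam.lateral.resolve(), base),
                "split": exam.split,
                "is_abnormal": exam.is_abnormal,
                "tags": in_vocab + oov,
                "caption": exam.gold_caption,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    return path
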