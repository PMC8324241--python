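"""End-to-end orchestration: rank all test exams, tag the top-k, caption them.

The pipeline mirrors the three-stage triage workflow: every test exam is
scored for abnormality and ranked; the top-k prefix H_k is tagged by the
multi-label head with learned per-tag thresholds; each tagged exam receives
a caption retrieved under its predicted tag set.  Stage outputs are written
as ranked.tsv, tags.jsonl, captions.jsonl plus a run_log.jsonl recording
seeds, sizes and per-stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .captioning import RetrievedCaption, build_index, retrieve_caption
from .data import ExamCollection, load_manifest
from .encoder import EmbeddingTable, encode_collection, make_small_cnn
from .nets import TrainConfig
from .ranking import RankedList, rank_exams, score_collection, train_ranker
from .tagging import TagProbabilities, assign_tags, learn_thresholds, train_tagger


@dataclasses.dataclass
class PipelineConfig:
    """Paths, sizes and seeds for one pipeline run."""

    manifest: Path
    out_dir: Path
    k: int = 100
    seed: int = 0
    image_size: int = 64
    encoder_dim: int = 96
    epochs: int = 1000
    hidden: tuple[int, ...] = (64,)
    index_abnormal_only: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)


@dataclasses.dataclass
class PipelineResult:
    """In-memory bundle of all stage outputs."""

    ranked: RankedList
    top_k: list[tuple[str, float]]
    tag_probabilities: dict[str, TagProbabilities]
    predicted_tags: dict[str, frozenset[str]]
    captions: dict[str, RetrievedCaption]
    thresholds: np.ndarray
    out_dir: Path


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(log_path: Path, name: str, started: float, **extra) -> None:
    rec = {"stage": name, "elapsed_s": round(time.perf_counter() - started, 3), **extra}
    with open(log_path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def run_pipeline(
    config: PipelineConfig, collection: ExamCollection | None = None
) -> PipelineResult:
    """Execute rank -> top-k -> tag -> caption on a manifest's test split."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_path.write_text("")
    t0 = time.perf_counter()
    _stage(log_path, "start", t0, seed=config.seed, k=config.k,
           version=__version__, config_hash=_config_hash(config))

    if collection is None:
        collection = load_manifest(config.manifest)
    train, val, test = (collection.split(s) for s in ("train", "val", "test"))
    if not test:
        raise RuntimeError("pipeline: manifest has no test exams")

    # --- encoding -----------------------------------------------------
    t = time.perf_counter()
    encoder = make_small_cnn(config.image_size, config.encoder_dim, config.seed)
    try:
        table = encode_collection(collection, encoder)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'encode' failed: {exc}") from exc
    _stage(log_path, "encode", t, n_exams=len(table), dim=table.dim)

    def matrix(exams) -> tuple[np.ndarray, list[str]]:
        ids = [e.exam_id for e in exams]
        return table.subset(ids).matrix.astype(np.float64), ids

    # --- ranking ------------------------------------------------------
    t = time.perf_counter()
    x_train, _ = matrix(train)
    x_val, _ = matrix(val)
    y_train = np.array([e.is_abnormal for e in train], dtype=np.float64)
    y_val = np.array([e.is_abnormal for e in val], dtype=np.float64)
    train_cfg = TrainConfig(seed=config.seed, epochs=config.epochs, hidden=config.hidden)
    try:
        ranker, _hist = train_ranker(x_train, y_train, x_val, y_val, train_cfg)
        ranked = rank_exams(score_collection(table.subset([e.exam_id for e in test]), ranker))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'rank' failed: {exc}") from exc
    top = ranked.top_k(config.k)
    with open(out / "ranked.tsv", "w", encoding="utf-8") as fh:
        fh.write("exam_id\tscore\trank\n")
        for pos, (exam_id, score) in enumerate(ranked, start=1):
            fh.write(f"{exam_id}\t{score:.6f}\t{pos}\n")
    _stage(log_path, "rank", t, n_test=len(test), k=len(top))

    # --- tagging ------------------------------------------------------
    t = time.perf_counter()
    abn_train = [e for e in train if e.is_abnormal]
    abn_val = [e for e in val if e.is_abnormal]
    if not abn_train or not abn_val:
        raise RuntimeError("pipeline stage 'tag' failed: no abnormal train/val exams")
    xa_train, _ = matrix(abn_train)
    xa_val, _ = matrix(abn_val)
    try:
        tagger, _hist = train_tagger(
            xa_train, [e.gold_tags for e in abn_train],
            xa_val, [e.gold_tags for e in abn_val],
            collection.vocabulary, train_cfg,
        )
        val_probs = tagger.predict(xa_val, [e.exam_id for e in abn_val])
        thresholds = learn_thresholds(
            val_probs, [e.gold_tags for e in abn_val], collection.vocabulary
        )
        top_ids = [e for e, _ in top]
        x_top, _ = matrix([collection[e] for e in top_ids])
        top_probs = tagger.predict(x_top, top_ids)
        predicted = {
            tp.exam_id: assign_tags(tp, thresholds, collection.vocabulary)
            for tp in top_probs
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'tag' failed: {exc}") from exc
    with open(out / "tags.jsonl", "w", encoding="utf-8") as fh:
        for tp in top_probs:
            fh.write(json.dumps({
                "exam_id": tp.exam_id,
                "tags": sorted(predicted[tp.exam_id]),
                "probs": [round(float(p), 6) for p in tp.probs],
            }, ensure_ascii=False) + "\n")
    _stage(log_path, "tag", t, n_tagged=len(predicted))

    # --- captioning ---------------------------------------------------
    t = time.perf_counter()
    try:
        index = build_index(train, table, abnormal_only=config.index_abnormal_only)
        captions: dict[str, RetrievedCaption] = {}
        for exam_id in top_ids:
            captions[exam_id] = retrieve_caption(
                table[exam_id], predicted[exam_id], index
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'caption' failed: {exc}") from exc
    with open(out / "captions.jsonl", "w", encoding="utf-8") as fh:
        for exam_id in top_ids:
            fh.write(captions[exam_id].to_json(exam_id) + "\n")
    _stage(log_path, "caption", t, n_captioned=len(captions))
    _stage(log_path, "done", t0)

    return PipelineResult(
        ranked=ranked,
        top_k=top,
        tag_probabilities={tp.exam_id: tp for tp in top_probs},
        predicted_tags=predicted,
        captions=captions,
        thresholds=thresholds,
        out_dir=out,
    )
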