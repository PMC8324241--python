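"""Synthetic two-view radiography exam collections.

Each abnormality tag is tied to a geometric pixel motif (a bright ellipse,
disk, band or line at a tag-specific location) rendered into BOTH views of
an exam on top of Gaussian noise, and to a caption sentence that mentions
the tag.  Pixels, tags and captions are therefore causally linked: a small
encoder can learn the tags from the images, and a keyword labeler recovers
exactly the gold tags from the gold caption.  Normal exams get motif-free
noise images and a normal-template caption.

Defaults emulate the structure of public two-view chest X-ray collections:
roughly 2-3 tags per abnormal exam, a minority of exams abnormal, identical
tag sets recurring across exams, and boilerplate sentences shared between
normal and abnormal reports.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .data import Exam, ExamCollection, TagVocabulary, build_vocabulary, write_manifest


@dataclasses.dataclass
class MotifSpec:
    """A tag's pixel signature: shape, unit-square position, size, intensity."""

    shape: str            # "ellipse" | "disk" | "hband" | "vline" | "dline"
    row: float            # center row as a fraction of image height
    col: float            # center col as a fraction of image width
    size: float           # radius / half-width as a fraction of image size
    intensity: float      # additive brightness on the [0, 1] pixel scale


# intensities are tiered: some findings are conspicuous (nodule, pneumonia),
# others subtle (edema, degenerative change), as in real radiographs where
# finding conspicuity varies widely
DEFAULT_MOTIFS: dict[str, MotifSpec] = {
    "cardiomegaly": MotifSpec("ellipse", 0.62, 0.50, 0.20, 0.45),
    "pleural effusion": MotifSpec("disk", 0.85, 0.72, 0.10, 0.25),
    "pneumonia": MotifSpec("disk", 0.35, 0.75, 0.11, 0.55),
    "edema": MotifSpec("hband", 0.45, 0.50, 0.05, 0.14),
    "atelectasis": MotifSpec("dline", 0.25, 0.25, 0.22, 0.22),
    "nodule": MotifSpec("disk", 0.20, 0.30, 0.06, 0.70),
    "fracture": MotifSpec("vline", 0.50, 0.12, 0.25, 0.55),
    "degenerative change": MotifSpec("disk", 0.75, 0.22, 0.08, 0.20),
}

DEFAULT_CAPTION_TEMPLATES: dict[str, str] = {
    "cardiomegaly": "The heart is enlarged consistent with cardiomegaly.",
    "pleural effusion": "There is a moderate pleural effusion.",
    "pneumonia": "Focal airspace opacity suggests pneumonia.",
    "edema": "Diffuse interstitial markings indicate pulmonary edema.",
    "atelectasis": "Linear bands of atelectasis are present.",
    "nodule": "A small pulmonary nodule is identified.",
    "fracture": "An acute rib fracture is seen.",
    "degenerative change": "Degenerative change of the spine is noted.",
}

NORMAL_CAPTIONS = (
    "The lungs are clear. Heart size within normal limits.",
    "The cardiomediastinal silhouette is unremarkable. Lungs are clear.",
)

# shared boilerplate recreates the common-phrase overlap between normal and
# abnormal reports that inflates pure word-overlap metrics
BOILERPLATE = "The visualized osseous structures are unremarkable."


def default_lexicon() -> dict[str, list[str]]:
    """Label lexicon under which generated captions are exactly recoverable."""
    return {tag: [tag] for tag in DEFAULT_MOTIFS}


@dataclasses.dataclass
class SynthConfig:
    """Study conditions for the synthetic collection generator.

    abnormal_fraction: probability an exam is abnormal (default 0.39; public
        chest X-ray collections run roughly one- to two-thirds abnormal).
    tags_per_abnormal: mean tag multiplicity of abnormal exams (default 3).
    noise_sd: pixel noise standard deviation on the [0, 1] scale.
    motif_scale: global multiplier on motif intensity (the separability dial
        used by :func:`degrade_signal`).
    """

    n_exams: int = 600
    abnormal_fraction: float = 0.39
    motifs: dict[str, MotifSpec] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MOTIFS)
    )
    caption_templates: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CAPTION_TEMPLATES)
    )
    tags_per_abnormal: float = 3.0
    image_size: int = 64
    noise_sd: float = 0.08
    noise_mean: float = 0.35
    brightness_sd: float = 0.06  # per-exam exposure jitter on the mean level
    tag_pool_size: int = 12      # recurring tag-set "syndromes"
    tag_pool_prob: float = 0.85  # chance an abnormal exam draws from the pool
    n_distractors: int = 6       # benign clutter structures per exam (both views)
    distractor_intensity: float = 0.4
    distractor_size: tuple[float, float] = (0.05, 0.12)
    motif_scale: float = 1.0
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.abnormal_fraction < 1.0:
            raise ValueError("abnormal_fraction must be in (0, 1)")
        if len(self.motifs) < 2:
            raise ValueError("vocabulary needs at least 2 tags")
        missing = [t for t in self.motifs if t not in self.caption_templates]
        if missing:
            raise ValueError(f"caption template missing for tag(s): {missing}")


def _render_motif(img: np.ndarray, spec: MotifSpec, scale: float, view: int) -> None:
    size = img.shape[0]
    # the lateral view shows the same finding at a mirrored horizontal position
    col = spec.col if view == 0 else 1.0 - spec.col
    r, c = int(spec.row * size), int(col * size)
    rad = max(1, int(spec.size * size))
    amp = spec.intensity * scale
    if amp == 0.0:
        return
    if spec.shape == "ellipse":
        rr, cc = draw_ellipse(r, c, rad, int(rad * 1.3), shape=img.shape)
    elif spec.shape == "disk":
        rr, cc = draw_disk((r, c), rad, shape=img.shape)
    elif spec.shape == "hband":
        rr, cc = np.meshgrid(
            np.arange(max(0, r - rad), min(size, r + rad + 1)),
            np.arange(size),
            indexing="ij",
        )
        rr, cc = rr.ravel(), cc.ravel()
    elif spec.shape == "vline":
        rr, cc = draw_line(max(0, r - rad), c, min(size - 1, r + rad), c)
        rr2, cc2 = draw_line(max(0, r - rad), min(c + 1, size - 1),
                             min(size - 1, r + rad), min(c + 1, size - 1))
        rr, cc = np.concatenate([rr, rr2]), np.concatenate([cc, cc2])
    elif spec.shape == "dline":
        extent = rad
        r0, c0 = max(0, r - extent), max(0, c - extent)
        r1, c1 = min(size - 1, r + extent), min(size - 1, c + extent)
        rr, cc = draw_line(r0, c0, r1, c1)
    else:
        raise ValueError(f"unknown motif shape {spec.shape!r}")
    img[rr, cc] += amp


def _draw_tag_count(rng: np.random.Generator, mean: float, n_tags: int) -> int:
    """Poisson around the mean, truncated to [1, vocabulary size]."""
    count = 1 + rng.poisson(max(mean - 1.0, 0.0))
    return int(min(count, n_tags))


def _draw_tag_set(rng: np.random.Generator, vocab_order: list[str], mean: float) -> tuple[str, ...]:
    n_tags = _draw_tag_count(rng, mean, len(vocab_order))
    picked = rng.choice(len(vocab_order), size=n_tags, replace=False)
    return tuple(vocab_order[j] for j in sorted(picked))


def _build_tag_pool(
    rng: np.random.Generator, vocab_order: list[str], config: SynthConfig
) -> list[tuple[str, ...]]:
    """Recurring tag-set 'syndromes'; identical reports recur in real data,
    which keeps the exact-tag retrieval filter regularly non-empty."""
    pool: list[tuple[str, ...]] = []
    while len(pool) < config.tag_pool_size:
        candidate = _draw_tag_set(rng, vocab_order, config.tags_per_abnormal)
        if candidate not in pool:
            pool.append(candidate)
    return pool


def _caption_for(tags: Sequence[str], config: SynthConfig, rng: np.random.Generator) -> str:
    if not tags:
        normal = NORMAL_CAPTIONS[int(rng.integers(len(NORMAL_CAPTIONS)))]
        return f"{normal} {BOILERPLATE}"
    sentences = [config.caption_templates[t] for t in tags]
    return " ".join([*sentences, BOILERPLATE])


def _write_image(img: np.ndarray, path: Path) -> None:
    arr = np.clip(img, 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="L").save(path)


def generate_collection(config: SynthConfig, out_dir: str | Path) -> ExamCollection:
    """Generate images + manifest under ``out_dir``; returns the collection.

    Fully seeded: the same config produces byte-identical images and
    manifest.  The manifest is written to ``out_dir / "manifest.jsonl"`` and
    validates under ``load_manifest``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    vocab_order = list(config.motifs)
    n = config.n_exams

    # deterministic split sizes, shuffled assignment
    n_train = int(round(config.split_fractions[0] * n))
    n_val = int(round(config.split_fractions[1] * n))
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    rng.shuffle(splits)

    pool = _build_tag_pool(rng, vocab_order, config)

    exams: list[Exam] = []
    for i in range(n):
        exam_id = f"synth-{i:05d}"
        abnormal = bool(rng.uniform() < config.abnormal_fraction)
        if abnormal:
            if rng.uniform() < config.tag_pool_prob:
                tags = list(pool[int(rng.integers(len(pool)))])
            else:
                tags = list(_draw_tag_set(rng, vocab_order, config.tags_per_abnormal))
        else:
            tags = []
        caption = _caption_for(tags, config, rng)

        # per-exam exposure jitter, shared by both views
        exam_mean = config.noise_mean + rng.normal(0.0, config.brightness_sd)
        # benign anatomical clutter: tag-independent structures that dominate
        # raw visual similarity, present in normal and abnormal exams alike
        lo, hi = config.distractor_size
        distractors = [
            MotifSpec("disk", rng.uniform(0.08, 0.92), rng.uniform(0.08, 0.92),
                      rng.uniform(lo, hi), config.distractor_intensity)
            for _ in range(config.n_distractors)
        ]
        paths = []
        for view in range(2):
            img = rng.normal(exam_mean, config.noise_sd,
                             size=(config.image_size, config.image_size))
            for spec in distractors:
                _render_motif(img, spec, 1.0, view)
            for tag in tags:
                _render_motif(img, config.motifs[tag], config.motif_scale, view)
            path = img_dir / f"{exam_id}-{'frontal' if view == 0 else 'lateral'}.png"
            _write_image(img, path)
            paths.append(path)

        exams.append(
            Exam(
                exam_id=exam_id,
                image_paths=(paths[0], paths[1]),
                split=splits[i],
                is_abnormal=abnormal,
                gold_tags=frozenset(tags),
                gold_caption=caption,
            )
        )

    vocab = build_vocabulary(exams)
    collection = ExamCollection(exams, vocab)
    collection.synth_config = config  # retained so degrade_signal can re-render
    write_manifest(collection, out_dir / "manifest.jsonl")
    return collection


def degrade_signal(
    collection: ExamCollection,
    separability: float,
    out_dir: str | Path,
) -> ExamCollection:
    """Re-render a generated collection with motif intensity scaled down.

    ``separability=1`` reproduces the collection unchanged (byte-identical
    images); ``separability=0`` leaves pure noise, making abnormal and
    normal exams statistically indistinguishable.  Only collections produced
    by :func:`generate_collection` carry the config needed to re-render.
    """
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must lie in [0, 1]")
    config: SynthConfig | None = getattr(collection, "synth_config", None)
    if config is None:
        raise ValueError("collection was not produced by generate_collection")
    degraded = dataclasses.replace(config, motif_scale=config.motif_scale * separability)
    return generate_collection(degraded, out_dir)
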