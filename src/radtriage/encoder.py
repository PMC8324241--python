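"""Exam embeddings from a pluggable per-image encoder.

An exam embedding is the concatenation of the two per-image embeddings in
fixed (frontal, lateral) order, mirroring the usual practice of extracting a
global-average-pooled CNN feature per view and concatenating views.

The default desk-scale encoder (:class:`SmallConvEncoder`) is a seeded,
fixed random-filter convolutional feature extractor: three conv/ReLU/pool
blocks, coarse spatial average pooling, and a seeded linear projection to the
target dimension.  Random convolutional features are a standard cheap stand-in
for a trained CNN backbone when the downstream heads are trained on top; any
callable satisfying :class:`ImageEncoder` (e.g. a real pretrained backbone)
can be plugged in instead.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from .data import Exam, ExamCollection


@runtime_checkable
class ImageEncoder(Protocol):
    """Callable contract: normalized image array (H, W) in [0, 1] -> R^d."""

    dim: int
    name: str
    input_size: int

    def embed(self, image: np.ndarray) -> np.ndarray: ...


@dataclasses.dataclass
class ExamEmbedding:
    """Fixed-length vector for one exam; dimension is 2 x encoder dim."""

    exam_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float32)
        if self.vector.ndim != 1:
            raise ValueError("exam embedding must be a 1-D vector")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"exam {self.exam_id!r}: non-finite embedding entries")


def load_image(path: str | Path, size: int) -> np.ndarray:
    """Read PNG/JPEG as grayscale, resize to ``size``x``size``, scale to [0,1]."""
    try:
        with Image.open(path) as img:
            img = img.convert("L").resize((size, size), Image.BILINEAR)
            return np.asarray(img, dtype=np.float64) / 255.0
    except FileNotFoundError:
        raise FileNotFoundError(f"image not readable: {path}") from None


class MeanPixelEncoder:
    """d=1 encoder returning the mean pixel intensity; useful for testing."""

    def __init__(self, input_size: int = 32):
        self.dim = 1
        self.name = "mean-pixel"
        self.input_size = input_size

    def embed(self, image: np.ndarray) -> np.ndarray:
        return np.array([float(np.mean(image))])


def _conv3x3(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # x: (C, H, W); w: (F, C, 3, 3); zero-padded 'same' convolution
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C, H, W, 3, 3)
    return np.einsum("chwij,fcij->fhw", win, w, optimize=True)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    return x[:, : h - h % 2, : w - w % 2].reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _grid_pool(x: np.ndarray, grid: int) -> np.ndarray:
    """Average each channel over a ``grid`` x ``grid`` spatial partition."""
    c, h, w = x.shape
    rows = np.array_split(np.arange(h), grid)
    cols = np.array_split(np.arange(w), grid)
    out = np.empty((c, grid, grid))
    for i, r in enumerate(rows):
        for j, cl in enumerate(cols):
            out[:, i, j] = x[np.ix_(np.arange(c), r, cl)].mean(axis=(1, 2))
    return out


class SmallConvEncoder:
    """Seeded fixed-filter conv net: 3 blocks, grid pooling, linear projection.

    Parameters
    ----------
    input_size : side length in pixels images are resized to before encoding.
    dim : output embedding dimension per image.
    n_filters : channels per conv block.
    grid : side of the spatial average-pooling grid before projection.
    seed : RNG seed for filter and projection initialization.
    """

    def __init__(self, input_size: int = 64, dim: int = 96, n_filters: int = 12,
                 grid: int = 6, seed: int = 0):
        if input_size < 8 or dim <= 0:
            raise ValueError("input_size must be >= 8 and dim positive")
        self.input_size = int(input_size)
        self.dim = int(dim)
        self.n_filters = int(n_filters)
        # three 2x2 pooling stages shrink the map 8-fold; the pooling grid
        # cannot be finer than the final feature map
        self.grid = min(int(grid), max(1, input_size // 8))
        self.seed = int(seed)
        self.name = f"small-conv-{input_size}px-d{dim}-s{seed}"
        rng = np.random.default_rng(seed)
        f = self.n_filters
        # He-style scaling for ReLU blocks
        self.filters = [
            rng.normal(0.0, np.sqrt(2.0 / 9.0), size=(f, 1, 3, 3)),
            rng.normal(0.0, np.sqrt(2.0 / (9.0 * f)), size=(f, f, 3, 3)),
            rng.normal(0.0, np.sqrt(2.0 / (9.0 * f)), size=(f, f, 3, 3)),
        ]
        n_feat = f * self.grid * self.grid
        self.proj_w = rng.normal(0.0, 1.0 / np.sqrt(n_feat), size=(dim, n_feat))
        self.proj_b = np.zeros(dim)

    def embed(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError("encoder expects a 2-D grayscale image")
        if image.shape != (self.input_size, self.input_size):
            raise ValueError(
                f"encoder expects {self.input_size}x{self.input_size} input, "
                f"got {image.shape}"
            )
        x = image[None]
        for w in self.filters:
            x = np.maximum(_conv3x3(x, w), 0.0)
            x = _avgpool2(x)
        feat = _grid_pool(x, self.grid).ravel()
        return self.proj_w @ feat + self.proj_b

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"filters_{i}": f for i, f in enumerate(self.filters)}
        state["proj_w"] = self.proj_w
        state["proj_b"] = self.proj_b
        state["meta"] = np.array(
            [self.input_size, self.dim, self.n_filters, self.grid, self.seed]
        )
        return state

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "SmallConvEncoder":
        with np.load(path) as state:
            size, dim, nf, grid, seed = (int(v) for v in state["meta"])
            enc = cls(size, dim, nf, grid, seed)
            enc.filters = [state[f"filters_{i}"] for i in range(3)]
            enc.proj_w = state["proj_w"]
            enc.proj_b = state["proj_b"]
        return enc


def make_small_cnn(input_size: int, d: int, seed: int, **kwargs) -> SmallConvEncoder:
    """Construct the default seeded small convolutional encoder."""
    return SmallConvEncoder(input_size=input_size, dim=d, seed=seed, **kwargs)


def encode_exam(exam: Exam, encoder: ImageEncoder) -> ExamEmbedding:
    """Embed both views and concatenate as [frontal; lateral]."""
    parts = []
    for path in exam.image_paths:
        img = load_image(path, encoder.input_size)
        vec = np.asarray(encoder.embed(img), dtype=np.float64)
        if vec.shape != (encoder.dim,):
            raise ValueError(
                f"encoder {encoder.name!r} returned dimension {vec.shape}, "
                f"expected ({encoder.dim},)"
            )
        parts.append(vec)
    return ExamEmbedding(exam.exam_id, np.concatenate(parts))


class EmbeddingTable:
    """Order-stable exam_id -> float32 vector store, persistable as .npz."""

    def __init__(self, exam_ids: Iterable[str], matrix: np.ndarray):
        self.exam_ids = list(exam_ids)
        self.matrix = np.asarray(matrix, dtype=np.float32)
        if self.matrix.shape[0] != len(self.exam_ids):
            raise ValueError("row count does not match number of exam ids")
        self._row = {e: i for i, e in enumerate(self.exam_ids)}
        if len(self._row) != len(self.exam_ids):
            raise ValueError("duplicate exam_id in embedding table")

    @classmethod
    def from_embeddings(cls, embeddings: Iterable[ExamEmbedding]) -> "EmbeddingTable":
        embeddings = list(embeddings)
        ids = [e.exam_id for e in embeddings]
        if not embeddings:
            return cls([], np.zeros((0, 0), dtype=np.float32))
        return cls(ids, np.stack([e.vector for e in embeddings]))

    def __len__(self) -> int:
        return len(self.exam_ids)

    def __contains__(self, exam_id: str) -> bool:
        return exam_id in self._row

    def __getitem__(self, exam_id: str) -> np.ndarray:
        return self.matrix[self._row[exam_id]]

    def subset(self, exam_ids: Iterable[str]) -> "EmbeddingTable":
        ids = list(exam_ids)
        rows = [self._row[e] for e in ids]
        return EmbeddingTable(ids, self.matrix[rows])

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, exam_ids=np.array(self.exam_ids, dtype=np.str_), matrix=self.matrix
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        with np.load(path) as data:
            return cls([str(e) for e in data["exam_ids"]], data["matrix"])


def encode_collection(
    collection: ExamCollection | Iterable[Exam], encoder: ImageEncoder
) -> EmbeddingTable:
    """One embedding per exam, in collection order."""
    embeddings = []
    for exam in collection:
        try:
            embeddings.append(encode_exam(exam, encoder))
        except Exception as exc:
            raise RuntimeError(f"failed to encode exam {exam.exam_id!r}: {exc}") from exc
    return EmbeddingTable.from_embeddings(embeddings)
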