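"""Frozen patch encoders and the per-slide embedding store.

The classification framework never trains the patch encoder: any callable
that maps a 512x512 RGB patch to a fixed-length embedding can be plugged in.
``StubEncoder`` is a fully deterministic, seeded reference encoder (seeded
Gaussian random projection of the downscaled grayscale patch followed by
tanh) that lets every downstream stage run without foundation-model weights.
An adapter for an external pathology foundation model only needs to satisfy
``encode(patch) -> (D,)`` and advertise its ``spec``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import h5py
import numpy as np

from .tiling_qc import PatchRecord, QCConfig, extract_patch, grayscale_u8

logger = logging.getLogger(__name__)

DEFAULT_EMBEDDING_DIM = 1024
_STUB_INPUT_SIDE = 32  # patches are pooled to 32x32 grayscale before projection


@dataclass
class EncoderSpec:
    encoder_id: str = "stub"
    embedding_dim: int = DEFAULT_EMBEDDING_DIM
    frozen: bool = True

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if not self.frozen:
            raise ValueError("encoders are frozen in this framework")


@dataclass
class EmbeddingStore:
    """N x D patch embeddings of one slide, row-aligned with patch coords."""

    slide_id: str
    embeddings: np.ndarray  # (N, D) float32
    coords: np.ndarray      # (N, 2) int64 -> (x, y)
    magnification: str
    encoder_id: str

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be 2-D")
        if self.coords.shape != (self.embeddings.shape[0], 2):
            raise ValueError("coords must align row-for-row with embeddings")
        if self.embeddings.size and not np.isfinite(self.embeddings).all():
            raise ValueError("embeddings contain non-finite values")

    @property
    def n_patches(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]


def _downscale_gray(gray: np.ndarray, side: int) -> np.ndarray:
    """Block-mean a square grayscale array down to side x side."""
    h, w = gray.shape
    if h % side or w % side:
        raise ValueError(f"patch side {h}x{w} not divisible by {side}")
    fh, fw = h // side, w // side
    return gray.reshape(side, fh, side, fw).mean(axis=(1, 3))


class StubEncoder:
    """Deterministic drop-in patch encoder.

    Pipeline: grayscale -> block-mean to 32x32 -> center to [-0.5, 0.5]
    -> seeded Gaussian projection (1024 x D, scaled by 1/sqrt(1024))
    -> tanh.  The same seed yields bitwise-identical projections across
    processes, and one differing pixel perturbs the whole output vector.

    A synthetic spatial feature map (``grid x grid`` sub-tile embeddings)
    stands in for the final spatial layer of a convolutional/ViT encoder so
    that global-average-pooled features can be exercised end to end.
    """

    def __init__(self, embedding_dim: int = DEFAULT_EMBEDDING_DIM,
                 seed: int = 0, grid: int = 2) -> None:
        if grid < 1:
            raise ValueError("grid must be >= 1")
        self.spec = EncoderSpec(encoder_id=f"stub-d{embedding_dim}-s{seed}",
                                embedding_dim=embedding_dim)
        self.grid = grid
        rng = np.random.default_rng(seed)
        n_in = _STUB_INPUT_SIDE * _STUB_INPUT_SIDE
        self._projection = (rng.standard_normal((n_in, embedding_dim))
                            / np.sqrt(n_in)).astype(np.float64)

    def parameter_hash(self) -> str:
        """Fingerprint of the frozen projection; must never change."""
        return hashlib.sha256(self._projection.tobytes()).hexdigest()

    def _project(self, gray_tile: np.ndarray) -> np.ndarray:
        x = _downscale_gray(gray_tile, _STUB_INPUT_SIDE).ravel() / 255.0 - 0.5
        return np.tanh(x @ self._projection).astype(np.float32)

    def encode(self, patch_pixels: np.ndarray) -> np.ndarray:
        gray = grayscale_u8(patch_pixels)
        if gray.shape[0] != gray.shape[1]:
            raise ValueError("encoder expects square patches")
        return self._project(gray)

    def feature_map(self, patch_pixels: np.ndarray) -> np.ndarray:
        """(grid, grid, D) map: each cell embeds the matching patch sub-tile."""
        gray = grayscale_u8(patch_pixels)
        side = gray.shape[0]
        if side % self.grid:
            raise ValueError("patch side not divisible by spatial grid")
        t = side // self.grid
        out = np.empty((self.grid, self.grid, self.spec.embedding_dim),
                       dtype=np.float32)
        for i in range(self.grid):
            for j in range(self.grid):
                out[i, j] = self._project(gray[i * t:(i + 1) * t, j * t:(j + 1) * t])
        return out


def encode_patch(patch_pixels: np.ndarray, encoder) -> np.ndarray:
    """Embed one patch; validates the advertised embedding dimension."""
    vec = np.asarray(encoder.encode(patch_pixels))
    if vec.shape != (encoder.spec.embedding_dim,):
        raise ValueError(
            f"encoder returned shape {vec.shape}, expected "
            f"({encoder.spec.embedding_dim},)")
    return vec


def pooled_feature(patch_pixels: np.ndarray, encoder) -> np.ndarray:
    """Global-average-pooled feature over the encoder's final spatial layer.

    Encoders without a spatial output fall back to their plain embedding.
    """
    if hasattr(encoder, "feature_map"):
        fmap = np.asarray(encoder.feature_map(patch_pixels))
        return fmap.reshape(-1, fmap.shape[-1]).mean(axis=0)
    return encode_patch(patch_pixels, encoder)


def encode_slide(manifest: Sequence[PatchRecord], slide_image: np.ndarray,
                 encoder, config: Optional[QCConfig] = None,
                 augmentation=None) -> EmbeddingStore:
    """Embed every QC-passing patch of one slide, in manifest order.

    ``augmentation`` (train-time only) is applied to patch pixels before
    encoding; evaluation paths must leave it None.
    """
    config = config or QCConfig()
    passing = [r for r in manifest if r.qc_pass]
    if any(not r.qc_pass for r in manifest):
        raise ValueError("manifest must contain only qc_pass records")
    slide_ids = {r.slide_id for r in passing}
    if len(slide_ids) > 1:
        raise ValueError(f"manifest mixes slides: {sorted(slide_ids)}")
    D = encoder.spec.embedding_dim
    emb = np.zeros((len(passing), D), dtype=np.float32)
    coords = np.zeros((len(passing), 2), dtype=np.int64)
    for i, rec in enumerate(passing):
        try:
            pixels = extract_patch(slide_image, rec, config)
        except IndexError as exc:
            raise IOError(f"cannot read patch ({rec.x},{rec.y}) of "
                          f"{rec.slide_id}: {exc}") from exc
        if augmentation is not None:
            pixels = augmentation(pixels)
        emb[i] = encode_patch(pixels, encoder)
        coords[i] = (rec.x, rec.y)
    if not passing:
        logger.warning("empty manifest: embedding store has zero rows")
        slide_id = manifest[0].slide_id if manifest else "unknown"
    else:
        slide_id = passing[0].slide_id
    mag = passing[0].magnification if passing else "40x"
    return EmbeddingStore(slide_id=slide_id, embeddings=emb, coords=coords,
                          magnification=mag, encoder_id=encoder.spec.encoder_id)


# ---------------------------------------------------------------------------
# HDF5 persistence: /slides/<slide_id>/{embeddings, coords}


def save_stores(path, stores: Sequence[EmbeddingStore], patch_size: int = 512) -> None:
    with h5py.File(path, "a") as f:
        root = f.require_group("slides")
        for st in stores:
            if st.slide_id in root:
                del root[st.slide_id]
            g = root.create_group(st.slide_id)
            g.create_dataset("embeddings", data=st.embeddings)
            g.create_dataset("coords", data=st.coords)
            g.attrs["magnification"] = st.magnification
            g.attrs["encoder_id"] = st.encoder_id
            g.attrs["patch_size"] = patch_size


def load_store(path, slide_id: str) -> EmbeddingStore:
    with h5py.File(path, "r") as f:
        g = f["slides"][slide_id]
        return EmbeddingStore(
            slide_id=slide_id,
            embeddings=g["embeddings"][...],
            coords=g["coords"][...],
            magnification=str(g.attrs["magnification"]),
            encoder_id=str(g.attrs["encoder_id"]))


def list_slides(path) -> list:
    with h5py.File(path, "r") as f:
        return sorted(f["slides"].keys())
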