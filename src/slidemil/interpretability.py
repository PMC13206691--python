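"""Attention interpretability: heatmaps, top-k patches, PCA + GMM clustering.

Attention weights from the MIL head are min-max normalized per slide and
rendered as a colormap overlay on a slide thumbnail.  High-attention
patches are pooled into feature vectors, reduced to 2-D by PCA for
display, and clustered with a Gaussian mixture whose component count is
picked by the elbow (largest discrete second difference) of the
within-cluster sum of squares.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .tiling_qc import PatchRecord

logger = logging.getLogger(__name__)


@dataclass
class HeatmapSpec:
    colormap: str = "jet"
    opacity: float = 0.5
    downsample: int = 32

    def __post_init__(self) -> None:
        if not 0.0 < self.opacity <= 1.0:
            raise ValueError("opacity must be in (0, 1]")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


@dataclass
class ClusterResult:
    pca_coords: np.ndarray        # (M, 2)
    assignments: np.ndarray       # (M,) in 1..chosen_k
    wcss_by_k: Dict[int, float]
    chosen_k: int
    seed: int
    means: Optional[np.ndarray] = None


def minmax_normalize(attention: Sequence[float]) -> np.ndarray:
    """Scale scores to [0, 1]; a constant vector maps to all zeros."""
    a = np.asarray(attention, dtype=np.float64)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("attention must be a non-empty 1-D vector")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def top_k_patches(records: Sequence[PatchRecord], attention: Sequence[float],
                  k: int = 5) -> List[PatchRecord]:
    """Top-k records by attention, descending; ties by (x asc, y asc)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    a = np.asarray(attention, dtype=np.float64)
    if len(records) != a.shape[0]:
        raise ValueError("records/attention length mismatch")
    order = sorted(range(len(records)),
                   key=lambda i: (-a[i], records[i].x, records[i].y))
    return [records[i] for i in order[:min(k, len(records))]]


def render_heatmap(thumbnail: np.ndarray, records: Sequence[PatchRecord],
                   attention: Sequence[float],
                   spec: Optional[HeatmapSpec] = None):
    """Overlay colormapped attention on a slide thumbnail.

    ``thumbnail`` is the slide downsampled by ``spec.downsample``; each
    patch footprint is alpha-blended with colormap(minmax score) at
    ``spec.opacity`` (per channel: round((1-op)*base + op*color)).  Pixels
    outside every footprint are untouched.  Returns (RGB raster, CSV frame
    of x, y, raw score, normalized score).
    """
    spec = spec or HeatmapSpec()
    a = np.asarray(attention, dtype=np.float64)
    if len(records) != a.shape[0]:
        raise ValueError("records/attention length mismatch")
    norm = minmax_normalize(a) if a.size else a
    cmap = colormaps[spec.colormap]
    out = np.asarray(thumbnail).copy()
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    out = out[..., :3].astype(np.uint8)
    h, w = out.shape[:2]
    ds = spec.downsample
    for rec, s in zip(records, norm):
        color = np.round(np.asarray(cmap(float(s))[:3]) * 255.0)
        r0, r1 = rec.y // ds, min((rec.y + rec.side_px) // ds, h)
        c0, c1 = rec.x // ds, min((rec.x + rec.side_px) // ds, w)
        base = out[r0:r1, c0:c1].astype(np.float64)
        blend = (1.0 - spec.opacity) * base + spec.opacity * color
        out[r0:r1, c0:c1] = np.clip(np.round(blend), 0, 255).astype(np.uint8)
    table = pd.DataFrame({
        "x": [r.x for r in records], "y": [r.y for r in records],
        "attention": a, "attention_normalized": norm})
    return out, table


def pca_2d(features: np.ndarray) -> np.ndarray:
    """Project onto the top-2 principal axes of the mean-centered features.

    Component signs are fixed by making each axis's largest-magnitude
    loading positive, so results are reproducible across library versions.
    Rank-deficient inputs keep a zero second coordinate (flagged).
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 samples for a 2-D projection")
    n_comp = min(2, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(coords.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
        warnings.warn("input has a single feature: second PCA axis set to 0")
    else:
        sv = pca.singular_values_
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            coords[:, 1] = 0.0
            warnings.warn("feature rank < 2: second PCA coordinate set to 0")
    return coords


def _wcss(X: np.ndarray, labels: np.ndarray, means: np.ndarray) -> float:
    return float(((X - means[labels]) ** 2).sum())


def elbow_k(wcss_by_k: Dict[int, float]) -> int:
    """Elbow = argmax of the discrete second difference of WCSS over k.

    Needs at least three k values; with fewer, the largest single drop (or
    the only k) wins.
    """
    ks = sorted(wcss_by_k)
    if len(ks) == 1:
        return ks[0]
    if len(ks) == 2:
        return ks[1] if wcss_by_k[ks[0]] > wcss_by_k[ks[1]] else ks[0]
    best_k, best_d2 = ks[1], -np.inf
    for i in range(1, len(ks) - 1):
        d2 = (wcss_by_k[ks[i + 1]] - 2.0 * wcss_by_k[ks[i]]
              + wcss_by_k[ks[i - 1]])
        if d2 > best_d2:
            best_d2, best_k = d2, ks[i]
    return best_k


def gmm_cluster(features: np.ndarray, k_range: Sequence[int] = range(1, 9),
                seed: int = 0, use_pca_coords: bool = False) -> ClusterResult:
    """Fit GMMs over ``k_range``, pick k by the WCSS elbow, hard-assign.

    By default the mixture is fit in the full feature space and PCA is used
    for display only; ``use_pca_coords`` switches the clustering itself to
    the 2-D projection.  WCSS is computed from hard assignments to the
    component means (a mixture has no native WCSS).
    """
    X = np.asarray(features, dtype=np.float64)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    if X.shape[0] < max(ks):
        raise ValueError("need at least max(k_range) samples")
    coords = pca_2d(X)
    fit_space = coords if use_pca_coords else X

    wcss_by_k: Dict[int, float] = {}
    fits: Dict[int, GaussianMixture] = {}
    for k in ks:
        gm = _fit_gmm(fit_space, k, seed)
        labels = gm.predict(fit_space)
        wcss_by_k[k] = _wcss(fit_space, labels, gm.means_)
        fits[k] = gm
    ks_sorted = sorted(wcss_by_k)
    for a, b in zip(ks_sorted, ks_sorted[1:]):
        if wcss_by_k[b] > wcss_by_k[a] * (1 + 1e-9) + 1e-12:
            raise AssertionError(
                f"WCSS increased from k={a} to k={b}: "
                f"{wcss_by_k[a]:.6g} -> {wcss_by_k[b]:.6g}")
    chosen = elbow_k(wcss_by_k)
    labels = fits[chosen].predict(fit_space) + 1  # clusters numbered 1..k
    return ClusterResult(pca_coords=coords, assignments=labels,
                         wcss_by_k=wcss_by_k, chosen_k=chosen, seed=seed,
                         means=fits[chosen].means_)


def _fit_gmm(X: np.ndarray, k: int, seed: int) -> GaussianMixture:
    reg = 1e-6
    for attempt in range(4):
        try:
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 random_state=seed, n_init=3, reg_covar=reg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(X)
            return gm
        except (ValueError, np.linalg.LinAlgError):
            logger.warning("GMM k=%d singular (reg_covar=%g): retrying", k, reg)
            reg *= 100.0
    raise RuntimeError(f"GMM fit failed for k={k} despite regularization")
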