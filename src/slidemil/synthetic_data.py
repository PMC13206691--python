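"""Synthetic fixtures: slide-like rasters with known QC ground truth and
embedding-bag cohorts with planted witness instances.

The slide generator emulates exactly the pixel statistics the QC chain
measures: white glass, sharp H&E-like texture, the same texture defocused,
and a near-achromatic artifact.  The bag generator emulates the weak
supervision MIL assumes: a bag is labeled by its class, but only a small
fraction of instances (the witnesses, at ``witness_rate``) carry the class
signal — a mean shift along a class-specific direction in embedding space.
The "normal" class has no witnesses at all.  Ground truth (region maps,
witness indices) is returned alongside, so attention localization and QC
decisions can be verified instance by instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .training import Cohort, PatientEntry

logger = logging.getLogger(__name__)

REGION_KINDS = {"white": 0, "tissue_sharp": 1, "tissue_blurred": 2,
                "low_saturation_artifact": 3}

# H&E-like base color (pinkish-purple); luminance ~153 on the 8-bit scale.
_TISSUE_RGB = np.array([190.0, 140.0, 180.0])
_TISSUE_NOISE_SD = 40.0
_BLUR_SIGMA = 8.0
_ARTIFACT_GRAY = 200.0
_ARTIFACT_NOISE_SD = 5.0


@dataclass
class FixtureSlideSpec:
    width: int
    height: int
    regions: List[Tuple[Tuple[int, int, int, int], str]]  # ((x, y, w, h), kind)
    seed: int = 0

    def __post_init__(self) -> None:
        for (x, y, w, h), kind in self.regions:
            if kind not in REGION_KINDS:
                raise ValueError(f"unknown region kind {kind!r}")
            if x < 0 or y < 0 or x + w > self.width or y + h > self.height:
                raise ValueError("region outside slide bounds")


@dataclass
class BagCohortSpec:
    """Study conditions for the embedding-bag generator.

    Defaults are the desk-scale conditions used throughout the test suite:
    4 classes (3 tumor-like with witnesses + 1 normal), 32-dim embeddings,
    bags of 30-70 instances, a 10% witness rate, and a 2-SD mean shift.
    """

    n_classes: int = 4
    dim: int = 32
    instances_per_bag: Tuple[int, int] = (30, 70)
    witness_rate: float = 0.1
    class_mean_shift: float = 2.0
    noise_sd: float = 1.0
    n_patients: int = 300
    slides_per_patient: Tuple[int, int] = (3, 6)
    seed: int = 42
    include_normal: bool = True
    informative_witness_boost: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must be in (0, 1]")
        if self.n_classes < 2 or self.dim < 1:
            raise ValueError("need n_classes >= 2 and dim >= 1")
        if self.include_normal and self.n_classes < 2:
            raise ValueError("normal class requires n_classes >= 2")
        lo, hi = self.instances_per_bag
        if lo < 1 or hi < lo:
            raise ValueError("invalid instances_per_bag range")

    @property
    def n_witness_classes(self) -> int:
        return self.n_classes - 1 if self.include_normal else self.n_classes

    @property
    def class_names(self) -> List[str]:
        names = [f"class_{i}" for i in range(self.n_witness_classes)]
        if self.include_normal:
            names.append("normal")
        return names


# ---------------------------------------------------------------------------
# fixture slides


def _fill_region(rng: np.random.Generator, w: int, h: int, kind: str) -> np.ndarray:
    if kind == "white":
        return np.full((h, w, 3), 255, dtype=np.uint8)
    if kind in ("tissue_sharp", "tissue_blurred"):
        tex = (_TISSUE_RGB[None, None, :]
               + rng.normal(0.0, _TISSUE_NOISE_SD, (h, w, 3)))
        if kind == "tissue_blurred":
            for c in range(3):
                tex[..., c] = gaussian_filter(tex[..., c], _BLUR_SIGMA,
                                              mode="reflect")
        return np.clip(np.round(tex), 0, 255).astype(np.uint8)
    if kind == "low_saturation_artifact":
        # one shared noise map across channels -> exactly zero saturation
        g = _ARTIFACT_GRAY + rng.normal(0.0, _ARTIFACT_NOISE_SD, (h, w))
        g = np.clip(np.round(g), 0, 255).astype(np.uint8)
        return np.stack([g] * 3, axis=-1)
    raise ValueError(f"unknown region kind {kind!r}")


def make_fixture_slide(spec: FixtureSlideSpec):
    """Render the fixture raster and its per-pixel ground-truth region map.

    Overlapping regions resolve in list order (the later region wins,
    logged).  Uncovered pixels default to white.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width, 3), 255, dtype=np.uint8)
    region_map = np.zeros((spec.height, spec.width), dtype=np.int8)
    covered = np.zeros((spec.height, spec.width), dtype=bool)
    for (x, y, w, h), kind in spec.regions:
        if covered[y:y + h, x:x + w].any():
            logger.warning("overlapping region %s at (%d,%d): later wins",
                           kind, x, y)
        img[y:y + h, x:x + w] = _fill_region(rng, w, h, kind)
        region_map[y:y + h, x:x + w] = REGION_KINDS[kind]
        covered[y:y + h, x:x + w] = True
    return img, region_map


def twelve_cell_fixture_spec(cell: int = 512, seed: int = 7) -> FixtureSlideSpec:
    """A 4x3 grid of 512-px cells: 4 white, 2 defocused, 6 sharp tissue.

    The canonical QC fixture: the filter chain must keep exactly the 6
    sharp tissue cells (counts 12 -> 8 -> 8 -> 8 -> 6 along the stages).
    """
    layout = [["white", "white", "tissue_sharp", "tissue_sharp"],
              ["white", "tissue_blurred", "tissue_sharp", "tissue_sharp"],
              ["white", "tissue_blurred", "tissue_sharp", "tissue_sharp"]]
    regions = []
    for r, row in enumerate(layout):
        for c, kind in enumerate(row):
            regions.append(((c * cell, r * cell, cell, cell), kind))
    return FixtureSlideSpec(width=4 * cell, height=3 * cell,
                            regions=regions, seed=seed)


# ---------------------------------------------------------------------------
# embedding-bag cohorts


def _witness_directions(rng: np.random.Generator, dim: int, n: int) -> np.ndarray:
    """Orthonormal class directions (rows), via QR of a Gaussian matrix."""
    if n > dim:
        raise ValueError("more witness classes than embedding dimensions")
    A = rng.standard_normal((dim, n))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))[None, :]
    return Q.T  # (n, dim)


def _make_bag(rng: np.random.Generator, spec: BagCohortSpec, label: int,
              directions: np.ndarray, witness_rate: float):
    lo, hi = spec.instances_per_bag
    n = int(rng.integers(lo, hi + 1))
    H = rng.standard_normal((n, spec.dim)) * spec.noise_sd
    is_normal = spec.include_normal and label == spec.n_classes - 1
    if is_normal:
        return H.astype(np.float32), np.empty(0, dtype=np.int64)
    n_wit = max(1, int(round(witness_rate * n)))
    n_wit = min(n_wit, n)
    idx = rng.choice(n, size=n_wit, replace=False)
    H[idx] += spec.class_mean_shift * directions[label]
    return H.astype(np.float32), np.sort(idx).astype(np.int64)


def _label_cycle(spec: BagCohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced class labels (round-robin, then shuffled)."""
    labels = np.array([i % spec.n_classes for i in range(n)])
    rng.shuffle(labels)
    return labels


def make_bag_cohort(spec: Optional[BagCohortSpec] = None) -> Cohort:
    """Slide-level cohort: one slide per patient, witnesses planted per bag."""
    spec = spec or BagCohortSpec()
    rng = np.random.default_rng(spec.seed)
    directions = _witness_directions(rng, spec.dim, spec.n_witness_classes)
    labels = _label_cycle(spec, spec.n_patients, rng)

    patients, bags, slide_labels, witnesses = {}, {}, {}, {}
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        sid = f"{pid}-S0"
        label = int(labels[i])
        H, wit = _make_bag(rng, spec, label, directions, spec.witness_rate)
        patients[pid] = PatientEntry(patient_id=pid, label=label,
                                     slide_ids=[sid])
        bags[sid] = H
        slide_labels[sid] = label
        witnesses[sid] = wit
    return Cohort(patients=patients, bags=bags, slide_labels=slide_labels,
                  n_classes=spec.n_classes, dim=spec.dim,
                  class_names=spec.class_names, witnesses=witnesses)


def make_patient_cohort(spec: Optional[BagCohortSpec] = None) -> Cohort:
    """Patient-level cohort: several slides per patient, one class each.

    One designated "informative" slide per patient carries an elevated
    witness rate (``informative_witness_boost`` times the base rate), which
    gives the slide-level attention a planted target.
    """
    spec = spec or BagCohortSpec()
    rng = np.random.default_rng(spec.seed)
    directions = _witness_directions(rng, spec.dim, spec.n_witness_classes)
    labels = _label_cycle(spec, spec.n_patients, rng)

    patients, bags, slide_labels, witnesses = {}, {}, {}, {}
    informative = {}
    s_lo, s_hi = spec.slides_per_patient
    boosted = min(1.0, spec.witness_rate * spec.informative_witness_boost)
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        label = int(labels[i])
        n_slides = int(rng.integers(s_lo, s_hi + 1))
        info_idx = int(rng.integers(n_slides))
        slide_ids = []
        for s in range(n_slides):
            sid = f"{pid}-S{s}"
            rate = boosted if s == info_idx else spec.witness_rate
            H, wit = _make_bag(rng, spec, label, directions, rate)
            bags[sid] = H
            slide_labels[sid] = label
            witnesses[sid] = wit
            slide_ids.append(sid)
        patients[pid] = PatientEntry(patient_id=pid, label=label,
                                     slide_ids=slide_ids)
        informative[pid] = slide_ids[info_idx]
    return Cohort(patients=patients, bags=bags, slide_labels=slide_labels,
                  n_classes=spec.n_classes, dim=spec.dim,
                  class_names=spec.class_names, witnesses=witnesses,
                  informative_slides=informative)


def make_two_blob_features(n_per_blob: int = 100, dim: int = 16,
                           separation: float = 10.0, seed: int = 0):
    """Two isotropic unit-SD Gaussian blobs ``separation`` SDs apart.

    Returns (features, true labels); the canonical fixture for the
    PCA + GMM clustering pipeline.
    """
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(dim)
    direction /= np.linalg.norm(direction)
    a = rng.standard_normal((n_per_blob, dim))
    b = rng.standard_normal((n_per_blob, dim)) + separation * direction
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], n_per_blob)
    return X, labels
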