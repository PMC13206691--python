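"""Gated-attention multiple-instance learning: slide and patient models.

Each bag is a matrix ``H`` of N instance embeddings (rows ``h_i``).  The
gated attention head scores every instance,

    a_i = w^T ( tanh(W_V h_i) * sigmoid(W_U h_i) ),

softmax-normalizes the scores into weights ``alpha_i``, and pools the bag
into ``z = sum_i alpha_i h_i``.  A linear classifier followed by softmax
turns ``z`` into class probabilities.  The patient model applies the same
mechanism twice: level 1 pools patches into per-slide representations
``z_s``; level 2 pools the slides into ``z_pat`` with slide weights
``beta_s``.

The module also provides the exact reverse-mode gradients of the bag
cross-entropy with respect to every trainable tensor (the encoders stay
frozen, so no gradient flows into the embeddings' producers).  Gradients
are hand-derived and checked against finite differences in the test suite.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: Fixed ordering of the epithelial ovarian carcinoma classes.
CLASS_NAMES = ["HGSC", "LGSC", "CCC", "EC", "MC", "RC", "Normal"]

DEFAULT_HIDDEN_DIM = 164  # with D=1024, C=7 the trainable count is ~344K


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GatedAttentionHead:
    """Parameters (W_V, W_U, w) of one gated attention scorer."""

    W_V: np.ndarray  # (L, D)
    W_U: np.ndarray  # (L, D)
    w: np.ndarray    # (L,)

    def __post_init__(self) -> None:
        self.W_V = np.asarray(self.W_V, dtype=np.float64)
        self.W_U = np.asarray(self.W_U, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        L, D = self.W_V.shape
        if L < 1:
            raise ValueError("hidden dim L must be >= 1")
        if self.W_U.shape != (L, D) or self.w.shape != (L,):
            raise ValueError("inconsistent attention-head shapes")
        for arr in (self.W_V, self.W_U, self.w):
            if not np.isfinite(arr).all():
                raise ValueError("attention parameters must be finite")

    @property
    def hidden_dim(self) -> int:
        return self.W_V.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_V.shape[1]

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(input_dim)
        return cls(W_V=rng.normal(0.0, s, (hidden_dim, input_dim)),
                   W_U=rng.normal(0.0, s, (hidden_dim, input_dim)),
                   w=rng.normal(0.0, 1.0 / np.sqrt(hidden_dim), hidden_dim))

    def n_parameters(self) -> int:
        return self.W_V.size + self.W_U.size + self.w.size


@dataclass
class ClassifierHead:
    weight: np.ndarray  # (C, D)
    bias: np.ndarray    # (C,)

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        C = self.weight.shape[0]
        if C < 2:
            raise ValueError("classifier needs >= 2 classes")
        if self.bias.shape != (C,):
            raise ValueError("bias shape mismatch")

    @property
    def n_classes(self) -> int:
        return self.weight.shape[0]

    @classmethod
    def init(cls, input_dim: int, n_classes: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(input_dim)
        return cls(weight=rng.normal(0.0, s, (n_classes, input_dim)),
                   bias=np.zeros(n_classes))

    def n_parameters(self) -> int:
        return self.weight.size + self.bias.size


@dataclass
class SlideModel:
    attention: GatedAttentionHead
    classifier: ClassifierHead
    class_names: List[str] = field(default_factory=lambda: list(CLASS_NAMES))

    def __post_init__(self) -> None:
        if self.attention.input_dim != self.classifier.weight.shape[1]:
            raise ValueError("attention and classifier widths differ")

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int = DEFAULT_HIDDEN_DIM,
             n_classes: int = len(CLASS_NAMES), seed: int = 0,
             class_names: Optional[List[str]] = None):
        rng = np.random.default_rng(seed)
        return cls(attention=GatedAttentionHead.init(input_dim, hidden_dim, rng),
                   classifier=ClassifierHead.init(input_dim, n_classes, rng),
                   class_names=class_names or [str(i) for i in range(n_classes)])

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"attention.W_V": self.attention.W_V,
                "attention.W_U": self.attention.W_U,
                "attention.w": self.attention.w,
                "classifier.weight": self.classifier.weight,
                "classifier.bias": self.classifier.bias}


@dataclass
class PatientModel:
    level1: GatedAttentionHead
    level2: GatedAttentionHead
    classifier: ClassifierHead
    class_names: List[str] = field(default_factory=lambda: list(CLASS_NAMES))

    def __post_init__(self) -> None:
        D = self.level1.input_dim
        if self.level2.input_dim != D or self.classifier.weight.shape[1] != D:
            raise ValueError("inconsistent widths across patient-model parts")

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int = DEFAULT_HIDDEN_DIM,
             n_classes: int = len(CLASS_NAMES), seed: int = 0,
             class_names: Optional[List[str]] = None):
        rng = np.random.default_rng(seed)
        return cls(level1=GatedAttentionHead.init(input_dim, hidden_dim, rng),
                   level2=GatedAttentionHead.init(input_dim, hidden_dim, rng),
                   classifier=ClassifierHead.init(input_dim, n_classes, rng),
                   class_names=class_names or [str(i) for i in range(n_classes)])

    def parameters(self) -> Dict[str, np.ndarray]:
        return {"level1.W_V": self.level1.W_V,
                "level1.W_U": self.level1.W_U,
                "level1.w": self.level1.w,
                "level2.W_V": self.level2.W_V,
                "level2.W_U": self.level2.W_U,
                "level2.w": self.level2.w,
                "classifier.weight": self.classifier.weight,
                "classifier.bias": self.classifier.bias}


@dataclass
class BagOutput:
    probabilities: np.ndarray       # (C,)
    attention_weights: np.ndarray   # (N,)
    bag_representation: np.ndarray  # (D,)


@dataclass
class PatientOutput:
    probabilities: np.ndarray             # (C,)
    slide_weights: np.ndarray             # (S,) beta
    patch_weights: List[np.ndarray]       # per-slide alpha
    patient_representation: np.ndarray    # (D,) z_pat
    slide_representations: np.ndarray     # (S, D) z_s


# ---------------------------------------------------------------------------
# forward operations


def attention_scores(H: np.ndarray, head: GatedAttentionHead) -> np.ndarray:
    """Unnormalized gated-attention scores a_i for every row of H."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("empty bag: attention needs at least one instance")
    V = np.tanh(H @ head.W_V.T)      # (N, L)
    U = sigmoid(H @ head.W_U.T)      # (N, L)
    return (V * U) @ head.w


def softmax_normalize(a: np.ndarray) -> np.ndarray:
    """Stable softmax (max-subtracted, value-preserving)."""
    a = np.asarray(a, dtype=np.float64)
    e = np.exp(a - a.max())
    return e / e.sum()


def aggregate(alpha: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Attention-weighted bag representation z = sum_i alpha_i h_i."""
    alpha = np.asarray(alpha, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    if alpha.shape[0] != H.shape[0]:
        raise ValueError("alpha/H length mismatch")
    return alpha @ H


def _attention_pool(H: np.ndarray, head: GatedAttentionHead):
    a = attention_scores(H, head)
    alpha = softmax_normalize(a)
    z = aggregate(alpha, H)
    return z, alpha


def slide_forward(H: np.ndarray, model: SlideModel) -> BagOutput:
    """Full slide pass: attention pooling, linear classifier, softmax."""
    z, alpha = _attention_pool(H, model.attention)
    logits = model.classifier.weight @ z + model.classifier.bias
    return BagOutput(probabilities=softmax_normalize(logits),
                     attention_weights=alpha, bag_representation=z)


def patient_forward(slides: Sequence[np.ndarray], model: PatientModel) -> PatientOutput:
    """Two-level pass: patches -> z_s per slide, slides -> z_pat -> y-hat."""
    if len(slides) == 0:
        raise ValueError("patient has no slides")
    zs, alphas = [], []
    for H in slides:
        z, alpha = _attention_pool(H, model.level1)
        zs.append(z)
        alphas.append(alpha)
    Z = np.vstack(zs)                          # (S, D)
    z_pat, beta = _attention_pool(Z, model.level2)
    logits = model.classifier.weight @ z_pat + model.classifier.bias
    return PatientOutput(probabilities=softmax_normalize(logits),
                         slide_weights=beta, patch_weights=alphas,
                         patient_representation=z_pat, slide_representations=Z)


def predict_class(probabilities: np.ndarray) -> int:
    """Argmax class; exact ties resolve to the lowest class index."""
    p = np.asarray(probabilities)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("invalid probability vector")
    return int(np.argmax(p))


def count_parameters(model) -> int:
    """Exact number of trainable scalars (frozen encoder excluded)."""
    return int(sum(arr.size for arr in model.parameters().values()))


# ---------------------------------------------------------------------------
# reverse-mode gradients (bag cross-entropy)


def _gated_pool_backward(H: np.ndarray, head: GatedAttentionHead,
                         dz: np.ndarray) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    """Backprop dL/dz through z = sum alpha_i h_i with gated-attention alpha.

    Returns gradients for the head parameters and dL/dH (needed when the
    pooled output feeds a higher attention level).
    """
    H = np.asarray(H, dtype=np.float64)
    V = np.tanh(H @ head.W_V.T)
    U = sigmoid(H @ head.W_U.T)
    G = V * U
    a = G @ head.w
    alpha = softmax_normalize(a)

    # z = alpha @ H
    dalpha = H @ dz                       # (N,)
    dH = np.outer(alpha, dz)              # (N, D)
    # softmax jacobian
    da = alpha * (dalpha - alpha @ dalpha)
    # a = (V*U) @ w
    dG = np.outer(da, head.w)             # (N, L)
    dw = G.T @ da
    dV = dG * U
    dU = dG * V
    dZv = dV * (1.0 - V * V)              # pre-tanh
    dZu = dU * U * (1.0 - U)              # pre-sigmoid
    dWV = dZv.T @ H
    dWU = dZu.T @ H
    dH += dZv @ head.W_V + dZu @ head.W_U
    return {"W_V": dWV, "W_U": dWU, "w": dw}, dH


def slide_loss_and_grads(H: np.ndarray, label: int, model: SlideModel):
    """Cross-entropy of one bag plus exact gradients for every parameter."""
    out = slide_forward(H, model)
    p = out.probabilities
    C = model.classifier.n_classes
    loss = -float(np.log(max(p[label], 1e-300)))

    dlogits = p.copy()
    dlogits[label] -= 1.0
    z = out.bag_representation
    grads = {"classifier.weight": np.outer(dlogits, z),
             "classifier.bias": dlogits}
    dz = model.classifier.weight.T @ dlogits
    head_grads, _ = _gated_pool_backward(H, model.attention, dz)
    for k, v in head_grads.items():
        grads[f"attention.{k}"] = v
    return loss, grads, out


def patient_loss_and_grads(slides: Sequence[np.ndarray], label: int,
                           model: PatientModel):
    """Cross-entropy of one patient bag-of-bags plus exact gradients."""
    out = patient_forward(slides, model)
    p = out.probabilities
    loss = -float(np.log(max(p[label], 1e-300)))

    dlogits = p.copy()
    dlogits[label] -= 1.0
    z_pat = out.patient_representation
    grads = {"classifier.weight": np.outer(dlogits, z_pat),
             "classifier.bias": dlogits}
    dz_pat = model.classifier.weight.T @ dlogits

    Z = out.slide_representations
    l2_grads, dZ = _gated_pool_backward(Z, model.level2, dz_pat)
    for k, v in l2_grads.items():
        grads[f"level2.{k}"] = v

    l1_acc = {k: 0.0 for k in ("W_V", "W_U", "w")}
    for s, H in enumerate(slides):
        g, _ = _gated_pool_backward(np.asarray(H, dtype=np.float64),
                                    model.level1, dZ[s])
        for k in l1_acc:
            l1_acc[k] = l1_acc[k] + g[k]
    for k, v in l1_acc.items():
        grads[f"level1.{k}"] = v
    return loss, grads, out


# ---------------------------------------------------------------------------
# checkpoints: zip archive of .npy tensors + JSON header


def save_checkpoint(path, model, header: Optional[dict] = None) -> None:
    meta = {"kind": type(model).__name__,
            "class_names": list(model.class_names)}
    meta.update(header or {})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(meta, indent=2))
        for name, arr in model.parameters().items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def load_checkpoint(path):
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("header.json"))
        tensors = {}
        for info in zf.namelist():
            if info.endswith(".npy"):
                tensors[info[:-4]] = np.load(io.BytesIO(zf.read(info)))
    names = meta.get("class_names")
    if meta["kind"] == "SlideModel":
        model = SlideModel(
            attention=GatedAttentionHead(tensors["attention.W_V"],
                                         tensors["attention.W_U"],
                                         tensors["attention.w"]),
            classifier=ClassifierHead(tensors["classifier.weight"],
                                      tensors["classifier.bias"]),
            class_names=names)
    elif meta["kind"] == "PatientModel":
        model = PatientModel(
            level1=GatedAttentionHead(tensors["level1.W_V"],
                                      tensors["level1.W_U"],
                                      tensors["level1.w"]),
            level2=GatedAttentionHead(tensors["level2.W_V"],
                                      tensors["level2.W_U"],
                                      tensors["level2.w"]),
            classifier=ClassifierHead(tensors["classifier.weight"],
                                      tensors["classifier.bias"]),
            class_names=names)
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    return model, meta
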