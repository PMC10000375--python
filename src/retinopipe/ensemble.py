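"""Random-subspace ensemble of convolutional networks.

The base network is a VGG-style stack: five convolutional blocks of
(2, 2, 4, 4, 4) conv+ReLU layers with 64/128/256/512/512 filters, a 2x2
stride-2 max pool after each block, a 4096-unit fully connected layer and
an M-way softmax output.  A ``scale`` factor multiplies the filter and
fully-connected widths so the same topology runs at desk scale.

Ensemble construction follows the random subspace method: each of the L
members trains on a random subset of the input *planes* (RGB channels plus
derived maps such as vesselness and a lesion-probability map); unselected
planes are zeroed at that member's input.  Member scores are fused by a
convex weighted average G = sum_j w_j s_j, and diversity is reported as
the pairwise disagreement rate averaged over member pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters

from . import nn

__all__ = [
    "LayerSpec",
    "CNNArchitecture",
    "EnsembleConfig",
    "EnsembleModel",
    "PredictionScores",
    "build_architecture",
    "shape_propagate",
    "build_network",
    "sample_subspaces",
    "augment",
    "input_planes",
    "train_member",
    "train_ensemble",
    "predict_ensemble",
    "fit_validation_weights",
    "classifier_diversity",
    "ensemble_diversity",
]

#: conv+relu layer counts and full-scale filter widths of the five blocks
_BLOCKS = ((2, 64), (2, 128), (4, 256), (4, 512), (4, 512))
_FC_WIDTH = 4096


@dataclass
class LayerSpec:
    """One layer descriptor: kind in {conv, relu, maxpool, batchnorm, flatten, fc}."""

    kind: str
    filters: int = 0          # conv filter count / fc width
    kernel: tuple = ()        # conv/pool kernel
    stride: tuple = ()
    padding: int = 0


@dataclass
class CNNArchitecture:
    layers: list[LayerSpec]
    input_shape: tuple[int, int, int]  # (H, W, C)
    n_classes: int
    scale: float = 1.0


@dataclass
class EnsembleConfig:
    """Training configuration for the random-subspace ensemble."""

    n_members: int = 3
    r_fraction: float = 0.8
    weights: np.ndarray | None = None     # None -> uniform 1/L
    epochs: int = 15
    learning_rate: float = 1e-3
    batch_size: int = 32
    scale: float = 0.125
    input_size: int = 64
    batch_norm: bool = False
    # augmentation ranges; all zero / False -> augmentation is the identity
    rotation_range: float = 0.0           # degrees
    width_shift_range: float = 0.0        # fraction of width
    height_shift_range: float = 0.0       # fraction of height
    shear_range: float = 0.0              # degrees
    zoom_range: float = 0.0               # fraction
    horizontal_flip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_fraction <= 1:
            raise ValueError(f"r_fraction must lie in (0, 1], got {self.r_fraction}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("fusion weights must be non-negative and sum to 1")
            self.weights = w


@dataclass
class EnsembleModel:
    members: list[nn.Network]
    subspace_masks: np.ndarray   # (L, R) boolean
    weights: np.ndarray          # (L,), non-negative, sums to 1
    class_names: list[str]
    architecture: CNNArchitecture
    training_log: list[dict] = field(default_factory=list)


@dataclass
class PredictionScores:
    member_scores: np.ndarray   # (L, N, M)
    fused: np.ndarray           # (N, M) convex combination of member scores
    predicted: np.ndarray       # (N,) argmax of fused, ties -> lowest index


def build_architecture(
    input_shape: tuple[int, int, int], n_classes: int, scale: float = 1.0
) -> CNNArchitecture:
    """VGG-style topology; ``scale`` in (0, 1] multiplies layer widths.

    The input's spatial dims must be divisible by 2**5 (five pooling
    stages).  At scale=1 with a 224x224x3 input this is the full-size
    network (filters 64..512, fc 4096).
    """
    h, w, _c = input_shape
    if not 0 < scale <= 1:
        raise ValueError(f"scale must lie in (0, 1], got {scale}")
    if h % 32 or w % 32:
        raise ValueError(f"input spatial dims must be divisible by 32, got {h}x{w}")
    layers: list[LayerSpec] = []
    for n_conv, width in _BLOCKS:
        f = max(1, round(width * scale))
        for _ in range(n_conv):
            layers.append(LayerSpec("conv", filters=f, kernel=(3, 3), stride=(1, 1), padding=1))
            layers.append(LayerSpec("relu"))
        layers.append(LayerSpec("maxpool", kernel=(2, 2), stride=(2, 2)))
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("fc", filters=max(1, round(_FC_WIDTH * scale))))
    layers.append(LayerSpec("relu"))
    layers.append(LayerSpec("fc", filters=n_classes))
    return CNNArchitecture(layers=layers, input_shape=input_shape, n_classes=n_classes, scale=scale)


def shape_propagate(
    arch: CNNArchitecture, input_shape: tuple[int, int, int] | None = None
) -> list[tuple]:
    """Propagate (H, W, C) through every layer; errors name the layer.

    conv/pool: out = floor((in + 2*pad - kernel)/stride) + 1 per spatial dim.
    """
    shape = tuple(input_shape or arch.input_shape)
    out: list[tuple] = []
    for i, layer in enumerate(arch.layers):
        if layer.kind == "conv":
            h, w, _c = shape
            kh, kw = layer.kernel
            sh, sw = layer.stride
            h = (h + 2 * layer.padding - kh) // sh + 1
            w = (w + 2 * layer.padding - kw) // sw + 1
            shape = (h, w, layer.filters)
        elif layer.kind == "maxpool":
            h, w, c = shape
            kh, kw = layer.kernel
            sh, sw = layer.stride
            shape = ((h - kh) // sh + 1, (w - kw) // sw + 1, c)
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind == "fc":
            shape = (layer.filters,)
        elif layer.kind in ("relu", "batchnorm"):
            pass
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r} at index {i}")
        if any(s <= 0 for s in shape):
            raise ValueError(f"non-positive dimension {shape} after layer {i} ({layer.kind})")
        out.append(shape)
    return out


def build_network(
    arch: CNNArchitecture, rng: np.random.Generator, batch_norm: bool = False
) -> nn.Network:
    """Instantiate trainable layers for an architecture."""
    layers: list = []
    shape = arch.input_shape
    c = shape[2]
    flat = None
    for layer in arch.layers:
        if layer.kind == "conv":
            layers.append(nn.Conv3x3(c, layer.filters, rng))
            c = layer.filters
            if batch_norm:
                layers.append(nn.BatchNorm2d(c))
        elif layer.kind == "relu":
            layers.append(nn.ReLU())
        elif layer.kind == "maxpool":
            layers.append(nn.MaxPool2x2())
            shape = (shape[0] // 2, shape[1] // 2, c)
        elif layer.kind == "flatten":
            layers.append(nn.Flatten())
            flat = shape[0] * shape[1] * c
        elif layer.kind == "fc":
            layers.append(nn.Dense(flat, layer.filters, rng))
            flat = layer.filters
        shape = (shape[0], shape[1], c)
    return nn.Network(layers)


def sample_subspaces(r: int, r_fraction: float, n_members: int, seed: int) -> np.ndarray:
    """L boolean masks, each selecting ceil(r_fraction * R) of R input planes."""
    if r < 1:
        raise ValueError(f"number of input planes must be >= 1, got {r}")
    k = int(np.ceil(r_fraction * r))
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_members, r), dtype=bool)
    for j in range(n_members):
        masks[j, rng.choice(r, size=k, replace=False)] = True
    return masks


def augment(image: np.ndarray, config: EnsembleConfig, rng: np.random.Generator) -> np.ndarray:
    """Label-preserving random geometric augmentation of an (H, W, C) tensor.

    With all ranges zero and flipping off this is the exact identity.
    """
    out = image
    if config.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1, :].copy()
    angle = rng.uniform(-config.rotation_range, config.rotation_range) if config.rotation_range else 0.0
    shear = np.deg2rad(rng.uniform(-config.shear_range, config.shear_range)) if config.shear_range else 0.0
    zoom = 1.0 + (rng.uniform(-config.zoom_range, config.zoom_range) if config.zoom_range else 0.0)
    dy = rng.uniform(-1, 1) * config.height_shift_range * image.shape[0] if config.height_shift_range else 0.0
    dx = rng.uniform(-1, 1) * config.width_shift_range * image.shape[1] if config.width_shift_range else 0.0
    if angle == 0.0 and shear == 0.0 and zoom == 1.0 and dy == 0.0 and dx == 0.0:
        return out
    theta = np.deg2rad(angle)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    mat = (rot @ shr) / zoom
    center = (np.array(out.shape[:2]) - 1) / 2.0
    offset = center - mat @ center - np.array([dy, dx])
    warped = np.empty_like(out)
    for ch in range(out.shape[2]):
        warped[..., ch] = ndimage.affine_transform(
            out[..., ch], mat, offset=offset, order=1, mode="nearest"
        )
    return warped


def input_planes(image: np.ndarray) -> np.ndarray:
    """Stack the R=5 input planes of one RGB image: R, G, B, vesselness,
    lesion probability.

    ``image`` is HxWx3 in [0, 1].  Vesselness is the Sato ridge response of
    the inverted green channel (vessels are dark, elongated).  The lesion
    probability plane is a soft map combining yellowness (hard exudates)
    with darkness in green (red lesions), each rescaled to [0, 1].
    """
    img = np.asarray(image, dtype=np.float32)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    vessel = filters.sato(1.0 - g, sigmas=(1.0, 2.0), black_ridges=False)
    vmax = vessel.max()
    if vmax > 0:
        vessel = vessel / vmax
    yellow = np.clip((r + g) / 2.0 - b, 0.0, 1.0)
    dark = np.clip(np.median(g) - g, 0.0, 1.0)
    lesion = np.clip(yellow + dark, 0.0, 1.0)
    return np.stack([r, g, b, vessel.astype(np.float32), lesion.astype(np.float32)], axis=-1)


def _apply_mask(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[..., ~mask] = 0.0
    return out


def train_member(
    x: np.ndarray,
    y: np.ndarray,
    arch: CNNArchitecture,
    mask: np.ndarray,
    config: EnsembleConfig,
    seed: int,
) -> tuple[nn.Network, list[float]]:
    """Train one member on its input subspace; returns (network, loss log).

    ``x`` is (N, H, W, R) in [0, 1]; planes not selected by ``mask`` are
    zeroed.  Cross-entropy + Adam, shuffled mini-batches of
    ``config.batch_size`` for ``config.epochs`` epochs.
    """
    rng = np.random.default_rng(seed)
    net = build_network(arch, rng, batch_norm=config.batch_norm)
    opt = nn.AdamOptimizer(lr=config.learning_rate)
    xm = _apply_mask(x.astype(np.float32), mask)
    n = xm.shape[0]
    losses: list[float] = []
    augmenting = (
        config.rotation_range or config.width_shift_range or config.height_shift_range
        or config.shear_range or config.zoom_range or config.horizontal_flip
    )
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = xm[idx]
            if augmenting:
                xb = np.stack([augment(im, config, rng) for im in xb])
            logits = net.forward(xb, train=True)
            loss, grad = nn.cross_entropy_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss} at epoch {_epoch}; aborting"
                )
            net.backward(grad)
            opt.step(net.params())
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    return net, losses


def train_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    config: EnsembleConfig,
    class_names: list[str] | None = None,
) -> EnsembleModel:
    """Train the full random-subspace ensemble on (N, H, W, R) inputs."""
    n_planes = x.shape[-1]
    h, w = x.shape[1], x.shape[2]
    n_classes = int(y.max()) + 1 if class_names is None else len(class_names)
    arch = build_architecture((h, w, n_planes), n_classes, scale=config.scale)
    masks = sample_subspaces(n_planes, config.r_fraction, config.n_members, config.seed)
    weights = (
        np.full(config.n_members, 1.0 / config.n_members)
        if config.weights is None
        else np.asarray(config.weights, dtype=float)
    )
    members, log = [], []
    for j in range(config.n_members):
        net, losses = train_member(x, y, arch, masks[j], config, seed=config.seed + 1000 * (j + 1))
        members.append(net)
        log.append({"member": j, "losses": losses, "mask": masks[j].tolist()})
    return EnsembleModel(
        members=members,
        subspace_masks=masks,
        weights=weights,
        class_names=class_names or [str(i) for i in range(n_classes)],
        architecture=arch,
        training_log=log,
    )


def fit_validation_weights(model: EnsembleModel, x_val: np.ndarray, y_val: np.ndarray) -> np.ndarray:
    """Optional fusion weighting: w_j proportional to member accuracy on a
    validation set (normalized to sum to 1); replaces the uniform default
    in place and returns the new weights."""
    accs = []
    for member, mask in zip(model.members, model.subspace_masks):
        probs = member.predict_proba(_apply_mask(x_val.astype(np.float32), mask))
        accs.append(float(np.mean(probs.argmax(axis=1) == y_val)))
    accs = np.asarray(accs)
    weights = np.full(len(accs), 1.0 / len(accs)) if accs.sum() == 0 else accs / accs.sum()
    model.weights = weights
    return weights


def predict_ensemble(model: EnsembleModel, x: np.ndarray) -> PredictionScores:
    """Fuse member softmax scores by the convex weighted average G = sum w_j s_j."""
    x = np.atleast_3d(x)
    if x.ndim == 3:
        x = x[None]
    scores = np.stack(
        [
            member.predict_proba(_apply_mask(x.astype(np.float32), mask))
            for member, mask in zip(model.members, model.subspace_masks)
        ]
    )
    fused = np.einsum("j,jnm->nm", model.weights, scores)
    predicted = fused.argmax(axis=1)  # np.argmax returns the lowest index on ties
    return PredictionScores(member_scores=scores, fused=fused, predicted=predicted)


def classifier_diversity(pred_i: np.ndarray, pred_j: np.ndarray) -> float:
    """Disagreement rate between two members' predicted labels on a test set."""
    pred_i = np.asarray(pred_i)
    pred_j = np.asarray(pred_j)
    if pred_i.size == 0:
        raise ValueError("empty test set")
    return float(np.mean(pred_i != pred_j))


def ensemble_diversity(member_preds: np.ndarray) -> float:
    """Mean pairwise disagreement over all ordered member pairs i != j."""
    member_preds = np.asarray(member_preds)
    n_members = member_preds.shape[0]
    if n_members < 2:
        raise ValueError("ensemble diversity needs at least 2 members")
    vals = [
        classifier_diversity(member_preds[i], member_preds[j])
        for i in range(n_members)
        for j in range(n_members)
        if i != j
    ]
    return float(np.mean(vals))


def save_model(model: EnsembleModel, out_dir: str | Path) -> None:
    """Persist an ensemble as per-member weight files plus JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, member in enumerate(model.members):
        np.savez(out / f"member_{j}.npz", *member.state())
    meta = {
        "masks": model.subspace_masks.tolist(),
        "weights": model.weights.tolist(),
        "class_names": model.class_names,
        "input_shape": list(model.architecture.input_shape),
        "n_classes": model.architecture.n_classes,
        "scale": model.architecture.scale,
    }
    (out / "ensemble.json").write_text(json.dumps(meta, indent=2))


def load_model(model_dir: str | Path) -> EnsembleModel:
    out = Path(model_dir)
    meta = json.loads((out / "ensemble.json").read_text())
    arch = build_architecture(
        tuple(meta["input_shape"]), meta["n_classes"], scale=meta["scale"]
    )
    members = []
    masks = np.asarray(meta["masks"], dtype=bool)
    for j in range(masks.shape[0]):
        net = build_network(arch, np.random.default_rng(0))
        with np.load(out / f"member_{j}.npz") as data:
            net.load_state([data[k] for k in data.files])
        members.append(net)
    return EnsembleModel(
        members=members,
        subspace_masks=masks,
        weights=np.asarray(meta["weights"]),
        class_names=meta["class_names"],
        architecture=arch,
    )
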