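"""Patch-based wavefront classification on shearlet coefficients.

A wavefront extractor is an ensemble of N + 1 independent binary CNNs: one
per orientation bin, deciding whether the image has a singularity with
that orientation at a patch's center pixel, plus one edge/non-edge
classifier trained on the same patch pool.  Each classifier sees 21x21xL
windows of the shearlet coefficient volume centered at candidate pixels;
border pixels closer than 10 pixels to the image edge are unclassifiable
by design.

Images are min-max normalized to [0, 1] before the shearlet transform;
no further pre-processing of the patches is applied.  Training sets are
class-balanced with a fixed number of distinct patch centers per image.
"""

from __future__ import annotations

import json
import hashlib
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import PatchCNN
from .errors import InvalidConfigError, ShapeError, TrainingError
from .shearlets import CoefficientVolume, ShearletSystem, shearlet_transform
from .wavefront import DigitalWavefrontSet

__all__ = [
    "PATCH_RADIUS",
    "PatchSet",
    "ConstantClassifier",
    "ClassifierSpec",
    "TrainConfig",
    "ClassifierEnsemble",
    "normalize_image",
    "extract_patch",
    "build_training_set",
    "train_classifier",
    "predict_wavefront_set",
]

PATCH_RADIUS = 10  # 21 x 21 patches
PATCH_SIZE = 2 * PATCH_RADIUS + 1


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant images map to zero."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


@dataclass
class PatchSet:
    """Stack of labelled coefficient patches for one binary task."""

    X: np.ndarray  # (n, L, 21, 21)
    y: np.ndarray  # (n,) in {0, 1}
    centers: np.ndarray  # (n, 2) row, col
    source_ids: np.ndarray  # (n,) image index
    task: str  # "edge" or "orientation:<bin>"


@dataclass(frozen=True)
class ClassifierSpec:
    """Topology of each binary classifier.

    Four 3x3 convolution layers with batch normalization, ReLU and 2x2 max
    pooling, followed by a dense layer and a single-probability logistic
    output.  Channel widths and the dense width are configurable.
    """

    conv_channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 3
    dense_units: int = 1024
    pool_layers: tuple[int, ...] = (1, 3)  # which conv blocks are followed by pooling
    n_conv_layers: int = 4
    pool: int = 2
    activation: str = "relu"
    batch_norm: bool = True

    def __post_init__(self):
        if self.n_conv_layers != 4 or len(self.conv_channels) != 4:
            raise InvalidConfigError("the classifier uses exactly four convolutional layers")
        if self.pool != 2 or self.activation != "relu" or not self.batch_norm:
            raise InvalidConfigError("topology must use 2x2 max pooling, ReLU and batch norm")


@dataclass(frozen=True)
class TrainConfig:
    patches_per_image: int = 10
    balance: bool = True
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    weight_decay: float = 0.0  # decoupled L2 on weight matrices
    lr_decay: float = 0.3  # step factor applied at the milestone fractions
    lr_milestones: tuple[float, ...] = (0.6, 0.85)
    seed: int = 0
    n_train: int = 10000
    n_val: int = 2000
    n_test: int = 2000
    positive_floor: float = 0.25  # error if positives fall below this fraction of target

    def __post_init__(self):
        if min(self.patches_per_image, self.epochs + 1, self.batch_size,
               self.n_train, self.n_val, self.n_test) <= 0:
            raise InvalidConfigError("training sizes must be positive")
        if self.optimizer != "adam":
            raise InvalidConfigError("only the adam optimizer is supported")


def _config_hash(*objs) -> str:
    payload = json.dumps([asdict(o) if hasattr(o, "__dataclass_fields__") else o
                          for o in objs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Patch extraction


def extract_patch(volume: CoefficientVolume, center: tuple[int, int]) -> np.ndarray:
    """Exact (L, 21, 21) window of the coefficient volume at a center pixel.

    ``center`` is 0-based (row, col) and must lie at least 10 pixels from
    every border; no padding is ever applied.
    """
    L, M, _ = volume.data.shape
    r, c = int(center[0]), int(center[1])
    if not (PATCH_RADIUS <= r < M - PATCH_RADIUS and PATCH_RADIUS <= c < M - PATCH_RADIUS):
        raise ValueError(
            f"center {center} too close to the border for a {PATCH_SIZE}x{PATCH_SIZE} patch"
        )
    return volume.data[:, r - PATCH_RADIUS : r + PATCH_RADIUS + 1,
                       c - PATCH_RADIUS : c + PATCH_RADIUS + 1].copy()


def _interior_mask(shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[PATCH_RADIUS : shape[0] - PATCH_RADIUS, PATCH_RADIUS : shape[1] - PATCH_RADIUS] = True
    return mask


def _positive_mask(truth: DigitalWavefrontSet, task: str) -> np.ndarray:
    mask = np.zeros(truth.domain_shape, dtype=bool)
    if task == "edge":
        for (r, c) in truth.elements:
            mask[r, c] = True
    elif task.startswith("orientation:"):
        bin_ = int(task.split(":", 1)[1])
        for (r, c), bins in truth.elements.items():
            if bin_ in bins:
                mask[r, c] = True
    else:
        raise InvalidConfigError(f"unknown task {task!r}")
    return mask


def build_training_set(
    volumes: list[CoefficientVolume],
    truths: list[DigitalWavefrontSet],
    task: str,
    config: TrainConfig,
    rng: np.random.Generator,
) -> PatchSet:
    """Assemble a balanced patch set for one binary task.

    Exactly ``patches_per_image`` distinct centers are drawn per image.
    Positive centers are pixels whose truth contains the task's label
    (orientation bin, or any edge); the global positive/negative ratio is
    kept within [0.9, 1.1] whenever enough positives exist, and an error is
    raised if positives fall below the configured floor.
    """
    if len(volumes) != len(truths):
        raise ShapeError("volumes and truths must align")
    ppi = config.patches_per_image
    shape = truths[0].domain_shape
    interior = _interior_mask(shape)

    orientation_task = task.startswith("orientation:")
    pos_pools = []
    neg_pools = []
    for truth in truths:
        pos = _positive_mask(truth, task) & interior
        pos_pools.append(np.argwhere(pos))
        if orientation_task:
            # hard negatives: edges with other orientations, mixed with plain
            # non-edge pixels, so the classifier learns orientation rather
            # than mere edge presence
            edge = _positive_mask(truth, "edge") & interior
            hard = np.argwhere(edge & ~pos)
            easy = np.argwhere(~edge & interior)
            neg_pools.append((hard, easy))
        else:
            neg_pools.append(np.argwhere(~pos & interior))

    n_images = len(volumes)
    target_pos = (n_images * ppi) // 2
    quota = [min(len(p), ppi // 2) for p in pos_pools]
    deficit = target_pos - sum(quota)
    while deficit > 0:
        progressed = False
        for i in range(n_images):
            if deficit == 0:
                break
            if quota[i] < min(len(pos_pools[i]), ppi - 1):
                quota[i] += 1
                deficit -= 1
                progressed = True
        if not progressed:
            break
    total_pos = sum(quota)
    if total_pos == 0:
        raise TrainingError(f"task {task!r}: no positive pixels in any image")
    if config.balance and total_pos < config.positive_floor * target_pos:
        raise TrainingError(
            f"task {task!r}: undersampled positives ({total_pos} of {target_pos} target); "
            "increase the dataset or relax patches_per_image"
        )

    X, y, centers, sources = [], [], [], []
    for i, (vol, truth) in enumerate(zip(volumes, truths)):
        n_pos = quota[i]
        pos_idx = rng.choice(len(pos_pools[i]), size=n_pos, replace=False) if n_pos else []
        n_neg = ppi - n_pos
        if orientation_task:
            hard, easy = neg_pools[i]
            n_hard = min(len(hard), n_neg // 2)
            hard_idx = rng.choice(len(hard), size=n_hard, replace=False) if n_hard else []
            easy_idx = rng.choice(len(easy), size=n_neg - n_hard, replace=False)
            negatives = list(hard[list(hard_idx)]) + list(easy[easy_idx])
        else:
            negatives = list(neg_pools[i][rng.choice(len(neg_pools[i]), size=n_neg,
                                                     replace=False)])
        for r, c in pos_pools[i][list(pos_idx)]:
            X.append(extract_patch(vol, (r, c)))
            y.append(1)
            centers.append((r, c))
            sources.append(i)
        for r, c in negatives:
            X.append(extract_patch(vol, (r, c)))
            y.append(0)
            centers.append((r, c))
            sources.append(i)
    return PatchSet(
        X=np.asarray(X), y=np.asarray(y, dtype=float),
        centers=np.asarray(centers), source_ids=np.asarray(sources), task=task,
    )


# ---------------------------------------------------------------------------
# Training


def _binary_fscore(y_true, y_pred) -> float:
    tp = np.sum((y_pred == 1) & (y_true == 1))
    fp = np.sum((y_pred == 1) & (y_true == 0))
    fn = np.sum((y_pred == 0) & (y_true == 1))
    if tp == 0:
        return 0.0
    p, r = tp / (tp + fp), tp / (tp + fn)
    return 2 * p * r / (p + r)


def train_classifier(
    patchset: PatchSet,
    spec: ClassifierSpec = ClassifierSpec(),
    trainconfig: TrainConfig = TrainConfig(),
    val_fraction: float = 0.15,
) -> tuple[PatchCNN, list[dict]]:
    """Train one binary patch CNN; deterministic given the config seed.

    Returns the model and a per-epoch history with train loss and
    train/validation F-scores.  Zero epochs returns the initialized model.
    """
    rng = np.random.default_rng(trainconfig.seed)
    model = PatchCNN(
        input_shape=patchset.X.shape[1:],
        conv_channels=spec.conv_channels,
        dense_units=spec.dense_units,
        kernel_size=spec.kernel_size,
        seed=trainconfig.seed,
        pool_layers=spec.pool_layers,
    )
    n = len(patchset.X)
    order = rng.permutation(n)
    n_val = max(1, int(n * val_fraction)) if n > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xt, yt = patchset.X[train_idx], patchset.y[train_idx]
    Xv, yv = patchset.X[val_idx], patchset.y[val_idx]
    history = []
    train_probe = train_idx[:512]  # train F reported on a fixed subsample
    Xp, yp = patchset.X[train_probe], patchset.y[train_probe]
    for epoch in range(trainconfig.epochs):
        lr = trainconfig.learning_rate
        for frac in trainconfig.lr_milestones:
            if epoch >= frac * trainconfig.epochs:
                lr *= trainconfig.lr_decay
        loss = model.train_epoch(Xt, yt, rng, lr=lr,
                                 batch_size=trainconfig.batch_size,
                                 weight_decay=trainconfig.weight_decay)
        rec = {"epoch": epoch, "loss": float(loss)}
        rec["train_f"] = _binary_fscore(yp, (model.predict_proba(Xp) > 0.5).astype(int))
        if n_val:
            rec["val_f"] = _binary_fscore(yv, (model.predict_proba(Xv) > 0.5).astype(int))
        history.append(rec)
    return model, history


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class ClassifierEnsemble:
    """N orientation classifiers plus one edge classifier."""

    orientation_models: list
    edge_model: object
    n_orientations: int
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.threshold < 1:
            raise InvalidConfigError("threshold must lie in (0, 1)")
        if len(self.orientation_models) != self.n_orientations:
            raise InvalidConfigError("need one model per orientation bin")

    def save(self, directory) -> None:
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "n_orientations": self.n_orientations,
            "threshold": self.threshold,
            "metadata": self.metadata,
            "models": {},
        }
        for name, model in [("edge", self.edge_model)] + [
            (f"orientation_{i}", m) for i, m in enumerate(self.orientation_models)
        ]:
            if isinstance(model, ConstantClassifier):
                manifest["models"][name] = {
                    "kind": "constant",
                    "probability": model.probability,
                    "input_shape": list(model.input_shape),
                }
                continue
            np.savez_compressed(directory / f"{name}.npz", **model.state_dict())
            manifest["models"][name] = {
                "kind": "cnn",
                "input_shape": list(model.input_shape),
                "conv_channels": list(model.conv_channels),
                "dense_units": model.dense_units,
                "kernel_size": model.kernel_size,
                "seed": model.seed,
                "pool_layers": list(model.pool_layers),
            }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "ClassifierEnsemble":
        directory = pathlib.Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)

        def _load(name):
            meta = manifest["models"][name]
            if meta.get("kind") == "constant":
                return ConstantClassifier(probability=meta["probability"],
                                          input_shape=tuple(meta["input_shape"]))
            model = PatchCNN(
                input_shape=tuple(meta["input_shape"]),
                conv_channels=tuple(meta["conv_channels"]),
                dense_units=meta["dense_units"],
                kernel_size=meta["kernel_size"],
                seed=meta["seed"],
                pool_layers=tuple(meta.get("pool_layers", (1, 3))),
            )
            with np.load(directory / f"{name}.npz") as npz:
                model.load_state_dict(dict(npz))
            return model

        return cls(
            orientation_models=[_load(f"orientation_{i}")
                                for i in range(manifest["n_orientations"])],
            edge_model=_load("edge"),
            n_orientations=manifest["n_orientations"],
            threshold=manifest["threshold"],
            metadata=manifest["metadata"],
        )


@dataclass
class ConstantClassifier:
    """Degenerate classifier with a fixed output probability.

    Stands in for orientation bins with no positive examples (directions
    that cannot occur in the training domain, e.g. sinogram covector
    angles outside the reachable slope range).
    """

    probability: float
    input_shape: tuple

    def predict_proba(self, x, batch_size: int = 512) -> np.ndarray:
        return np.full(len(x), self.probability)


def _interior_patches(volume: CoefficientVolume):
    """All interior patches as a view-stack plus their centers."""
    from numpy.lib.stride_tricks import sliding_window_view

    L, M, _ = volume.data.shape
    windows = sliding_window_view(volume.data, (PATCH_SIZE, PATCH_SIZE), axis=(1, 2))
    # windows: (L, M-20, M-20, 21, 21) -> centers (r, c) = (i+10, j+10)
    return windows, M - 2 * PATCH_RADIUS


def predict_wavefront_set(
    image: np.ndarray,
    system: ShearletSystem,
    ensemble: ClassifierEnsemble,
    batch_size: int = 256,
    already_normalized: bool = False,
    thin: bool = True,
) -> DigitalWavefrontSet:
    """Classify every interior pixel of an image into a digital wavefront set.

    A pixel enters the set when the edge classifier's probability exceeds
    the ensemble threshold; its orientation bins are those whose classifier
    also exceeds the threshold, falling back to the most probable bin when
    none does.

    With ``thin=True`` (default) the edge-probability field is thinned by
    non-maximum suppression along the predicted normal direction before
    thresholding: a candidate is suppressed when either of its two
    neighbours along the normal has strictly greater edge probability.
    Thinning localizes the response to the probability ridge (classifiers
    respond in a band around an edge because the patch topology is nearly
    translation invariant after pooling) and never removes plateau
    responses, so constant classifiers keep every interior pixel.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (system.image_size, system.image_size):
        raise ShapeError("image size does not match the shearlet system")
    if ensemble.edge_model.input_shape[0] != system.n_slices:
        raise ShapeError("ensemble input channels do not match the system's slice count")
    if not already_normalized:
        image = normalize_image(image)
    volume = shearlet_transform(image, system)
    windows, side = _interior_patches(volume)
    centers = [(i + PATCH_RADIUS, j + PATCH_RADIUS) for i in range(side) for j in range(side)]

    def batch_for(indices):
        batch = np.empty((len(indices), system.n_slices, PATCH_SIZE, PATCH_SIZE))
        for k, flat in enumerate(indices):
            i, j = divmod(flat, side)
            batch[k] = windows[:, i, j]
        return batch

    n_centers = side * side
    edge_p = np.empty(n_centers)
    for start in range(0, n_centers, batch_size):
        idx = range(start, min(start + batch_size, n_centers))
        edge_p[start : start + len(idx)] = ensemble.edge_model.predict_proba(batch_for(idx))

    wf = DigitalWavefrontSet((system.image_size,) * 2, n_orientations=ensemble.n_orientations)
    hits = np.nonzero(edge_p > ensemble.threshold)[0]
    if len(hits) == 0:
        return wf
    probs = np.empty((len(hits), ensemble.n_orientations))
    for start in range(0, len(hits), batch_size):
        idx = hits[start : start + batch_size]
        batch = batch_for(idx)
        for b, model in enumerate(ensemble.orientation_models):
            probs[start : start + len(idx), b] = model.predict_proba(batch)

    keep = np.ones(len(hits), dtype=bool)
    if thin:
        grid = edge_p.reshape(side, side)
        for k, flat in enumerate(hits):
            i, j = divmod(flat, side)
            theta = (np.argmax(probs[k]) + 0.5) * np.pi / ensemble.n_orientations
            dc = int(round(np.cos(theta)))
            dr = int(round(np.sin(theta)))
            for sgn in (1, -1):
                ni, nj = i + sgn * dr, j + sgn * dc
                if 0 <= ni < side and 0 <= nj < side and grid[ni, nj] > grid[i, j]:
                    keep[k] = False
                    break

    for k, flat in enumerate(hits):
        if not keep[k]:
            continue
        r, c = centers[flat]
        over = np.nonzero(probs[k] > ensemble.threshold)[0]
        bins = over if len(over) else [int(np.argmax(probs[k]))]
        for b in bins:
            wf.add(r, c, int(b))
    return wf
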