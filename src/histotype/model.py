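"""Weakly supervised tile classifier with a pluggable backbone.

Tiles inherit the protein-based subtype of their parent slide as a weak
label, and a two-class classifier is trained on the tile library.  The
backbone is an abstraction: the default ``"tiny"`` backbone block-averages
each tile down to ``input_edge`` pixels and trains a one-hidden-layer softmax
network with seeded mini-batch SGD, which is fully deterministic on a single
CPU and fast enough for repeated cross-validation on synthetic cohorts.  A
``"resnet50"`` entry (transfer learning from ImageNet weights) is registered
for installations that provide torch/torchvision; custom backbones can be
plugged in via :func:`register_backbone`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture contract for the tile classifier."""

    name: str = "tiny"
    input_edge: int = 64
    pretrained: bool = False
    n_outputs: int = 2


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; the seed fixes init and data order."""

    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 0.05
    frozen_stages: int = 0
    seed: int = 0
    augment_flips: bool = False
    augment_rotations: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0, batch_size and learning_rate > 0")


#: registry of external backbone factories: name -> callable(spec, config) -> estimator
_BACKBONES: dict = {}


def register_backbone(name: str, factory) -> None:
    """Register a custom backbone factory for :class:`TileClassifier`."""
    _BACKBONES[name] = factory


def _downsample(tile: np.ndarray, edge: int) -> np.ndarray:
    """Reduce a square tile to ``edge`` pixels per side by local averaging."""
    tile = np.asarray(tile, dtype=float)
    size = tile.shape[0]
    if size == edge:
        return tile
    if size % edge == 0:
        f = size // edge
        return tile.reshape(edge, f, edge, f, 3).mean(axis=(1, 3))
    from skimage.transform import resize

    return resize(tile, (edge, edge, 3), preserve_range=True, anti_aliasing=True)


def _d4_transform(img: np.ndarray, rot: int, flip: bool) -> np.ndarray:
    out = np.rot90(img, rot)
    if flip:
        out = out[:, ::-1]
    return out


class TileClassifier(ClassifierMixin, BaseEstimator):
    """Seeded tile classifier over a pluggable backbone.

    With the default ``"tiny"`` backbone the model is a one-hidden-layer
    softmax network on block-downsampled tiles, trained with mini-batch SGD
    and momentum.  ``epochs=0`` leaves the network at its (near-symmetric)
    random initialization, so predictions average close to 0.5.

    Parameters follow :class:`TrainConfig`; ``fit`` accepts a stack or list
    of RGB tiles (uint8, any square edge) and their string labels.
    """

    def __init__(
        self,
        backbone: str = "tiny",
        input_edge: int = 64,
        hidden_units: int = 64,
        epochs: int = 8,
        batch_size: int = 32,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        seed: int = 0,
        augment: bool = False,
    ):
        self.backbone = backbone
        self.input_edge = input_edge
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.seed = seed
        self.augment = augment

    # -- featurization ------------------------------------------------------
    def _images(self, X) -> np.ndarray:
        tiles = X if isinstance(X, (list, tuple)) else list(X)
        imgs = np.stack([_downsample(t, self.input_edge) for t in tiles])
        return imgs / 255.0

    @staticmethod
    def _flatten(imgs: np.ndarray) -> np.ndarray:
        return imgs.reshape(len(imgs), -1)

    # -- network ------------------------------------------------------------
    def _init_params(self, n_features: int, n_classes: int, rng) -> dict:
        return {
            "w1": rng.normal(0.0, 0.01, size=(n_features, self.hidden_units)),
            "b1": np.zeros(self.hidden_units),
            "w2": rng.normal(0.0, 0.01, size=(self.hidden_units, n_classes)),
            "b2": np.zeros(n_classes),
        }

    @staticmethod
    def _forward(params: dict, x: np.ndarray):
        h = np.tanh(x @ params["w1"] + params["b1"])
        logits = h @ params["w2"] + params["b2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        proba = expl / expl.sum(axis=1, keepdims=True)
        return h, proba

    def fit(self, X, y) -> "TileClassifier":
        if self.backbone in _BACKBONES:
            spec = BackboneSpec(name=self.backbone, input_edge=self.input_edge)
            config = TrainConfig(
                epochs=self.epochs,
                batch_size=self.batch_size,
                learning_rate=self.learning_rate,
                seed=self.seed,
            )
            self._delegate_ = _BACKBONES[self.backbone](spec, config)
            self._delegate_.fit(X, y)
            self.classes_ = np.asarray(self._delegate_.classes_)
            self.loss_curve_ = list(getattr(self._delegate_, "loss_curve_", []))
            return self
        if self.backbone == "resnet50":
            raise ImportError(
                "backbone 'resnet50' needs torch/torchvision; install them and "
                "register the backbone via histotype.model.register_backbone, "
                "or use the default 'tiny' backbone"
            )
        if self.backbone != "tiny":
            raise ValueError(f"unknown backbone {self.backbone!r}")

        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least two classes to train")
        class_index = {c: i for i, c in enumerate(self.classes_)}
        targets = np.array([class_index[c] for c in y])

        imgs = self._images(X)
        rng = np.random.default_rng(self.seed)
        n_features = self.input_edge * self.input_edge * 3
        params = self._init_params(n_features, n_classes, rng)
        velocity = {k: np.zeros_like(v) for k, v in params.items()}
        onehot = np.eye(n_classes)[targets]

        self.loss_curve_ = []
        self.accuracy_curve_ = []
        n = len(imgs)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                batch = imgs[idx]
                if self.augment:
                    batch = np.stack(
                        [
                            _d4_transform(
                                img,
                                int(rng.integers(4)),
                                bool(rng.integers(2)),
                            )
                            for img in batch
                        ]
                    )
                x = self._flatten(batch) - 0.5
                t = onehot[idx]
                h, proba = self._forward(params, x)
                eps = 1e-12
                epoch_loss += float(
                    -(t * np.log(proba + eps)).sum()
                )
                correct += int((proba.argmax(axis=1) == targets[idx]).sum())
                # backprop
                d_logits = (proba - t) / len(idx)
                grads = {
                    "w2": h.T @ d_logits,
                    "b2": d_logits.sum(axis=0),
                }
                d_h = (d_logits @ params["w2"].T) * (1.0 - h * h)
                grads["w1"] = x.T @ d_h
                grads["b1"] = d_h.sum(axis=0)
                for key in params:
                    velocity[key] = (
                        self.momentum * velocity[key] - self.learning_rate * grads[key]
                    )
                    params[key] = params[key] + velocity[key]
            self.loss_curve_.append(epoch_loss / n)
            self.accuracy_curve_.append(correct / n)
        self.params_ = params
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        if hasattr(self, "_delegate_"):
            return self._delegate_.predict_proba(X)
        imgs = self._images(X)
        x = self._flatten(imgs) - 0.5
        _, proba = self._forward(self.params_, x)
        return proba

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]


def _load_tiles(rows: pd.DataFrame) -> list[np.ndarray]:
    import imageio.v3 as iio

    tiles = []
    for path in rows["tile_path"]:
        try:
            tiles.append(np.asarray(iio.imread(path))[..., :3])
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read tile {path!r}: {exc}") from exc
    return tiles


def train_model(
    train_rows: pd.DataFrame,
    backbone: BackboneSpec = BackboneSpec(),
    config: TrainConfig = TrainConfig(),
    tiles=None,
) -> TileClassifier:
    """Train a tile classifier on a (balanced) manifest of labeled tiles.

    ``tiles`` may pass the tile images directly, aligned with ``train_rows``;
    otherwise they are read from the manifest's ``tile_path`` column.
    """
    if tiles is None:
        tiles = _load_tiles(train_rows)
    clf = TileClassifier(
        backbone=backbone.name,
        input_edge=backbone.input_edge,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
        augment=config.augment_flips or config.augment_rotations,
    )
    clf.fit(tiles, train_rows["label"].to_numpy())
    return clf


def predict_tiles(model: TileClassifier, tiles, refs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tile class probabilities as a DataFrame.

    Columns are ``p_<class>`` for each model class (``p_luminal, p_basal``
    in the standard two-class setting); ``refs`` (slide_id, grid_row,
    grid_col) is carried through when given.
    """
    proba = model.predict_proba(tiles)
    out = {}
    if refs is not None:
        refs = refs.reset_index(drop=True)
        for col in ("slide_id", "grid_row", "grid_col"):
            if col in refs.columns:
                out[col] = refs[col]
    for i, cls in enumerate(model.classes_):
        out[f"p_{cls}"] = proba[:, i]
    return pd.DataFrame(out)
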