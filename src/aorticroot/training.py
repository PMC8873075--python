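"""Training: translation augmentation, k-fold cross-validated training,
validation-based loss selection and the final bagged ensemble.

The protocol mirrors the three-step cascade training scheme: for each step,
one model is trained per candidate loss (the four loss families with the
Tversky beta grid), the four combinations with the best validation result
are selected, six structurally identical models are trained per selected
loss in sixfold cross-validation, and the final model averages all member
outputs (flat uniform mean, which for equal weights coincides with the
two-stage mean of per-loss means).

The learnable surface is the sklearn-style :class:`UNet3DSegmenter`; the
module-level functions (``train_single``, ``crossval_train``, ...) are thin
wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from ._nn import Adam
from .losses import LossSpec, loss_and_grad
from .network import NetworkSpec, TrainedModel, UNet3D, ensemble_predict
from .volume_io import Volume

__all__ = [
    "TrainConfig",
    "ValidationRecord",
    "EnsembleModel",
    "UNet3DSegmenter",
    "augment_translate",
    "train_single",
    "crossval_train",
    "select_losses",
    "build_final_ensemble",
    "dice_score",
]


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the full-scale protocol
    (batch size 2, Adam, shifts of up to five voxels, sixfold CV)."""

    batch_size: int = 2
    learning_rate: float = 1e-4
    lr_schedule: str = "constant"
    epochs: int = 100
    max_shift_voxels: int = 5
    folds: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_shift_voxels < 0:
            raise ValueError("max_shift_voxels must be >= 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class ValidationRecord:
    """Train/validation result of one loss candidate, for loss selection."""

    loss_spec: LossSpec
    metric_name: str  # 'iog', 'f1' or 'mean_error_mm'
    train_value: float
    validation_value: float

    def __post_init__(self):
        if self.metric_name not in ("iog", "f1", "mean_error_mm"):
            raise ValueError(f"unknown metric {self.metric_name!r}")


@dataclass
class EnsembleModel:
    """Bag of trained networks; prediction is the voxel-wise mean probability."""

    members: list = field(default_factory=list)

    def predict(self, vol: Volume) -> Volume:
        return ensemble_predict(self.members, vol)

    def __len__(self):
        return len(self.members)


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Volume) else np.asarray(x)


def augment_translate(vol, label, max_shift: int, rng, pad_value=None):
    """Shift image and label identically by a random integer voxel offset.

    The shift per axis is uniform on [-max_shift, +max_shift]; vacated image
    voxels are filled with ``pad_value`` (default: the image minimum, i.e.
    background), vacated label voxels with 0.  No rotation and no
    deformation are applied.
    """
    v = _values(vol)
    lab = _values(label)
    if v.shape != lab.shape:
        raise ValueError("volume and label must share a grid")
    if max_shift >= min(v.shape):
        raise ValueError("shift exceeds grid size")
    if max_shift == 0:
        return v, lab
    shift = rng.integers(-max_shift, max_shift + 1, size=3)
    fill = float(v.min()) if pad_value is None else float(pad_value)
    out_v = np.full_like(v, fill)
    out_l = np.zeros_like(lab)
    src, dst = [], []
    for ax, s in enumerate(shift):
        n = v.shape[ax]
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out_v[tuple(dst)] = v[tuple(src)]
    out_l[tuple(dst)] = lab[tuple(src)]
    return out_v, out_l


def dice_score(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice / F1 on binary arrays; both-empty is scored 1.0."""
    a = np.asarray(pred_mask) > 0.5
    b = np.asarray(ref_mask) > 0.5
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


class UNet3DSegmenter(BaseEstimator):
    """Sklearn-style binary 3D segmenter around the U-Net.

    Parameters mirror :class:`NetworkSpec` and :class:`TrainConfig`; ``fit``
    expects equally shaped normalized image crops and binary label crops
    (arrays or Volume/Mask objects) whose dimensions are divisible by
    ``2**levels``.  Fitted attributes: ``model_`` (the trained network with
    metadata) and ``history_`` (per-epoch mean training loss).
    """

    def __init__(
        self,
        base_filters: int = 18,
        levels: int = 4,
        convs_per_level: int = 2,
        dropout_rate: float = 0.2,
        loss: str = "tversky",
        beta: float | None = 0.7,
        gamma: float | None = None,
        learning_rate: float = 1e-4,
        lr_schedule: str = "constant",
        epochs: int = 100,
        batch_size: int = 2,
        max_shift_voxels: int = 5,
        seed: int = 0,
        init_model=None,
        verbose: int = 0,
    ):
        self.base_filters = base_filters
        self.levels = levels
        self.convs_per_level = convs_per_level
        self.dropout_rate = dropout_rate
        self.loss = loss
        self.beta = beta
        self.gamma = gamma
        self.learning_rate = learning_rate
        self.lr_schedule = lr_schedule
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_shift_voxels = max_shift_voxels
        self.seed = seed
        self.init_model = init_model
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _loss_spec(self) -> LossSpec:
        beta = self.beta if self.loss in ("tversky", "focal_tversky") else None
        gamma = self.gamma if self.loss in ("focal", "focal_tversky") else None
        return LossSpec(self.loss, beta=beta, gamma=gamma)

    def _network_spec(self) -> NetworkSpec:
        return NetworkSpec(
            base_filters=self.base_filters,
            levels=self.levels,
            convs_per_level=self.convs_per_level,
            dropout_rate=self.dropout_rate,
        )

    def fit(self, X: Sequence, y: Sequence):
        spec = self._network_spec()
        loss_spec = self._loss_spec()
        items = [( _values(v).astype(np.float32), _values(l).astype(np.float32)) for v, l in zip(X, y)]
        if len(items) < 1:
            raise ValueError("empty training set")
        shape = items[0][0].shape
        for v, l in items:
            if v.shape != shape or l.shape != shape:
                raise ValueError("all training crops must share one shape")
        if any(s % spec.pool_factor for s in shape):
            raise ValueError(
                f"crop shape {shape} must be divisible by 2**levels = {spec.pool_factor}"
            )
        rng = np.random.default_rng(self.seed)
        net = UNet3D(spec, seed=int(rng.integers(0, 2**31 - 1)))
        if self.init_model is not None:
            if self.init_model.spec != spec:
                raise ValueError("init_model spec differs from this estimator's spec")
            net.load_state_arrays(self.init_model.net.state_arrays())
        opt = Adam(net.layers(), lr=self.learning_rate)
        n = len(items)
        self.history_ = []
        for epoch in range(self.epochs):
            if self.lr_schedule == "cosine":
                # decay to 1/30 of the initial rate over the run
                frac = epoch / max(1, self.epochs - 1)
                opt.lr = self.learning_rate * (
                    (1 / 30) + (1 - 1 / 30) * 0.5 * (1 + np.cos(np.pi * frac))
                )
            elif self.lr_schedule != "constant":
                raise ValueError("lr_schedule must be 'constant' or 'cosine'")
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xs, ys = [], []
                for i in idx:
                    v, l = augment_translate(items[i][0], items[i][1], self.max_shift_voxels, rng)
                    xs.append(v)
                    ys.append(l)
                xb = np.stack(xs)[..., None]
                yb = np.stack(ys)[..., None]
                opt.zero_grad()
                prob = net.forward(xb, train=True, rng=rng)
                val, grad = loss_and_grad(loss_spec, yb, prob)
                if not np.isfinite(val):
                    raise RuntimeError(
                        f"training diverged (loss={val}) at epoch {epoch}"
                    )
                net.backward(grad)
                opt.step()
                epoch_losses.append(val)
            self.history_.append(float(np.mean(epoch_losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  loss {self.history_[-1]:.4f}")
        self.model_ = TrainedModel(
            spec=spec,
            net=net,
            training_meta={
                "loss": {"family": loss_spec.family, "beta": loss_spec.beta, "gamma": loss_spec.gamma},
                "seed": self.seed,
                "epochs": self.epochs,
                "final_loss": self.history_[-1],
            },
        )
        return self

    def predict_proba(self, X: Sequence) -> list:
        return [self.model_.predict(_values(v).astype(np.float32)) for v in X]

    def predict(self, X: Sequence) -> list:
        return [(p >= 0.5).astype(np.uint8) for p in self.predict_proba(X)]

    def score(self, X: Sequence, y: Sequence) -> float:
        """Mean F1 (Dice) over the given crops."""
        preds = self.predict(X)
        return float(np.mean([dice_score(p, _values(l)) for p, l in zip(preds, y)]))


# ---------------------------------------------------------------------------
# Module-level protocol wrappers
# ---------------------------------------------------------------------------

def _make_estimator(
    loss_spec: LossSpec,
    config: TrainConfig,
    network_spec: NetworkSpec,
    seed: int,
    init_model=None,
):
    return UNet3DSegmenter(
        base_filters=network_spec.base_filters,
        levels=network_spec.levels,
        convs_per_level=network_spec.convs_per_level,
        dropout_rate=network_spec.dropout_rate,
        loss=loss_spec.family,
        beta=loss_spec.beta,
        gamma=loss_spec.gamma,
        learning_rate=config.learning_rate,
        lr_schedule=config.lr_schedule,
        epochs=config.epochs,
        batch_size=config.batch_size,
        max_shift_voxels=config.max_shift_voxels,
        seed=seed,
        init_model=init_model,
    )


def train_single(
    dataset: Sequence,
    loss_spec: LossSpec,
    config: TrainConfig,
    fold_id: int = 0,
    network_spec: NetworkSpec | None = None,
) -> TrainedModel:
    """Train one model on (image, label) pairs with the given loss."""
    network_spec = network_spec or NetworkSpec()
    if len(dataset) < config.batch_size:
        raise ValueError("dataset smaller than one batch")
    est = _make_estimator(loss_spec, config, network_spec, seed=config.seed + 1000 * fold_id)
    X = [v for v, _ in dataset]
    y = [l for _, l in dataset]
    est.fit(X, y)
    est.model_.training_meta["fold_id"] = fold_id
    return est.model_


def crossval_train(
    dataset: Sequence,
    loss_spec: LossSpec,
    config: TrainConfig,
    network_spec: NetworkSpec | None = None,
    init_model=None,
) -> list[TrainedModel]:
    """k-fold cross-validated training: one model per fold.

    Every sample appears in exactly one validation fold; each returned model
    records its fold id and validation F1 in ``training_meta``.  An optional
    ``init_model`` warm-starts every fold member from shared pre-trained
    weights (fine-tuning instead of training from scratch).
    """
    network_spec = network_spec or NetworkSpec()
    n = len(dataset)
    if n < config.folds:
        raise ValueError(f"dataset of {n} smaller than {config.folds} folds")
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    models = []
    for fold_id, (tr, va) in enumerate(kf.split(np.arange(n))):
        est = _make_estimator(
            loss_spec, config, network_spec, seed=config.seed + 1000 * fold_id,
            init_model=init_model,
        )
        est.fit([dataset[i][0] for i in tr], [dataset[i][1] for i in tr])
        val_f1 = est.score([dataset[i][0] for i in va], [dataset[i][1] for i in va])
        est.model_.training_meta.update(
            {"fold_id": fold_id, "validation_f1": val_f1, "validation_indices": [int(i) for i in va]}
        )
        models.append(est.model_)
    return models


def select_losses(records: Sequence[ValidationRecord], k: int = 4) -> list[LossSpec]:
    """Pick the k loss/parameter combinations with the best validation value.

    'Best' is the maximum for overlap metrics (iog, f1) and the minimum for
    mean_error_mm.  Ties are broken by the training value, then by input
    order.
    """
    records = list(records)
    if len(records) < k:
        raise ValueError(f"need at least k={k} records")
    metrics = {r.metric_name for r in records}
    if len(metrics) != 1:
        raise ValueError(f"mixed metrics: {sorted(metrics)}")
    maximize = metrics.pop() in ("iog", "f1")
    sgn = -1.0 if maximize else 1.0
    order = sorted(
        range(len(records)),
        key=lambda i: (sgn * records[i].validation_value, sgn * records[i].train_value, i),
    )
    return [records[i].loss_spec for i in order[:k]]


def build_final_ensemble(
    selected: Sequence[LossSpec],
    dataset: Sequence,
    config: TrainConfig,
    network_spec: NetworkSpec | None = None,
    init_model=None,
) -> EnsembleModel:
    """Train folds x losses members and bag them with a flat uniform mean."""
    selected = list(selected)
    if not selected:
        raise ValueError("no losses selected")
    members = []
    for spec in selected:
        members.extend(crossval_train(dataset, spec, config, network_spec, init_model=init_model))
    return EnsembleModel(members=members)
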