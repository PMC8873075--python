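"""Augmentation, cross-validation protocol, loss selection, training loop."""

import numpy as np
import pytest
from sklearn.model_selection import KFold

from aorticroot.losses import LossSpec
from aorticroot.network import NetworkSpec
from aorticroot.training import (
    EnsembleModel,
    TrainConfig,
    UNet3DSegmenter,
    ValidationRecord,
    augment_translate,
    build_final_ensemble,
    crossval_train,
    select_losses,
    train_single,
)

TINY_NET = NetworkSpec(base_filters=2, levels=2, dropout_rate=0.0)


def _tiny_dataset(n, shape=(16, 16, 16), seed=0):
    """Bright-sphere segmentation toys: learnable in a few epochs."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        c = rng.uniform(5, 11, size=3)
        r = rng.uniform(3.0, 5.0)
        g = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
        mask = (np.linalg.norm(g - c, axis=-1) <= r).astype(np.float32)
        img = mask * 2.0 + rng.normal(0, 0.3, size=shape).astype(np.float32)
        out.append((img.astype(np.float32), mask))
    return out


# -- augmentation ------------------------------------------------------------

def test_augment_zero_shift_is_identity():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(8, 8, 8))
    l = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
    v2, l2 = augment_translate(v, l, 0, rng)
    assert np.array_equal(v, v2) and np.array_equal(l, l2)


def test_augment_moves_centroid_by_drawn_shift():
    v = np.zeros((16, 16, 16), dtype=np.float32)
    l = np.zeros_like(v)
    l[6:10, 6:10, 6:10] = 1
    v[6:10, 6:10, 6:10] = 1
    rng = np.random.default_rng(3)
    expected_shift = np.random.default_rng(3).integers(-5, 6, size=3)
    _, l2 = augment_translate(v, l, 5, rng)
    c1 = np.array(np.nonzero(l)).mean(axis=1)
    c2 = np.array(np.nonzero(l2)).mean(axis=1)
    assert np.allclose(c2 - c1, expected_shift)


def test_augment_reproducible_and_bounded():
    v = np.random.default_rng(1).normal(size=(10, 10, 10))
    l = np.zeros_like(v)
    l[4:6, 4:6, 4:6] = 1
    a = augment_translate(v, l, 3, np.random.default_rng(9))
    b = augment_translate(v, l, 3, np.random.default_rng(9))
    assert np.array_equal(a[0], b[0])
    with pytest.raises(ValueError):
        augment_translate(v, l, 10, np.random.default_rng(0))


# -- cross-validation protocol ----------------------------------------------

def test_crossval_partition_property():
    data = _tiny_dataset(12)
    cfg = TrainConfig(batch_size=2, learning_rate=1e-3, epochs=1, folds=6, seed=1)
    models = crossval_train(data, LossSpec("tversky", beta=0.5), cfg, network_spec=TINY_NET)
    assert len(models) == 6
    val_sets = [set(m.training_meta["validation_indices"]) for m in models]
    assert all(len(s) == 2 for s in val_sets)  # 12 samples / 6 folds
    union = set().union(*val_sets)
    assert union == set(range(12))
    assert sum(len(s) for s in val_sets) == 12  # pairwise disjoint


def test_sixfold_split_of_90_gives_75_15():
    sizes = [
        (len(tr), len(va))
        for tr, va in KFold(n_splits=6, shuffle=True, random_state=0).split(np.arange(90))
    ]
    assert all(s == (75, 15) for s in sizes)


def test_crossval_too_small_dataset_rejected():
    cfg = TrainConfig(folds=6)
    with pytest.raises(ValueError):
        crossval_train(_tiny_dataset(4), LossSpec("tversky", beta=0.5), cfg, TINY_NET)


# -- loss selection ----------------------------------------------------------

def _rec(fam, beta, train, val, metric="f1"):
    gamma = 2.0 if fam in ("focal", "focal_tversky") else None
    return ValidationRecord(LossSpec(fam, beta=beta, gamma=gamma), metric, train, val)


def test_select_losses_direction_and_ties():
    records = [
        _rec("tversky", 0.5, 0.90, 0.91),
        _rec("tversky", 0.6, 0.92, 0.93),
        _rec("tversky", 0.7, 0.91, 0.93),  # tie on validation, lower train
        _rec("binary_cross_entropy", None, 0.80, 0.85),
    ]
    top2 = select_losses(records, k=2)
    assert (top2[0].family, top2[0].beta) == ("tversky", 0.6)  # tie broken by train
    assert (top2[1].family, top2[1].beta) == ("tversky", 0.7)
    # minimization metric flips the order
    err_records = [
        _rec("tversky", 0.5, 2.0, 2.5, "mean_error_mm"),
        _rec("tversky", 0.6, 2.2, 2.1, "mean_error_mm"),
    ]
    assert select_losses(err_records, k=1)[0].beta == 0.6
    assert len(select_losses(records, k=4)) == 4  # k = all -> all returned


def test_select_losses_rejects_mixed_metrics_and_small_k():
    records = [_rec("tversky", 0.5, 1, 1), _rec("tversky", 0.6, 1, 1, "iog")]
    with pytest.raises(ValueError):
        select_losses(records, k=1)
    with pytest.raises(ValueError):
        select_losses(records[:1], k=4)


# -- training loop -----------------------------------------------------------

def test_overfitting_single_case_drives_loss_down():
    """50 epochs on one toy case: final training loss < 20% of the initial."""
    data = _tiny_dataset(1)
    cfg = TrainConfig(batch_size=1, learning_rate=3e-2, epochs=50, max_shift_voxels=0, seed=0)
    model = train_single(data, LossSpec("tversky", beta=0.5), cfg, network_spec=TINY_NET)
    history = model.training_meta["final_loss"]
    est = UNet3DSegmenter(
        base_filters=2, levels=2, dropout_rate=0.0, loss="tversky", beta=0.5,
        learning_rate=3e-2, epochs=50, batch_size=1, max_shift_voxels=0, seed=0,
    )
    est.fit([data[0][0]], [data[0][1]])
    assert est.history_[-1] < 0.2 * est.history_[0]
    assert history == pytest.approx(est.history_[-1])


def test_training_is_seed_deterministic():
    data = _tiny_dataset(4)
    kw = dict(
        base_filters=2, levels=2, dropout_rate=0.1, loss="tversky", beta=0.6,
        learning_rate=3e-3, epochs=2, batch_size=2, max_shift_voxels=2, seed=11,
    )
    a = UNet3DSegmenter(**kw).fit([d[0] for d in data], [d[1] for d in data])
    b = UNet3DSegmenter(**kw).fit([d[0] for d in data], [d[1] for d in data])
    assert a.history_ == b.history_
    xa = a.predict_proba([data[0][0]])[0]
    xb = b.predict_proba([data[0][0]])[0]
    assert np.array_equal(xa, xb)


def test_nan_input_aborts_with_diagnostic():
    data = _tiny_dataset(2)
    bad = data[0][0].copy()
    bad[0, 0, 0] = np.nan
    est = UNet3DSegmenter(
        base_filters=2, levels=2, dropout_rate=0.0, loss="binary_cross_entropy",
        beta=None, epochs=1, batch_size=1, max_shift_voxels=0, seed=0,
    )
    with pytest.raises(RuntimeError, match="diverged"):
        est.fit([bad], [data[0][1]])


def test_sklearn_params_round_trip():
    est = UNet3DSegmenter(base_filters=3, beta=0.6)
    params = est.get_params()
    assert params["base_filters"] == 3
    est2 = UNet3DSegmenter().set_params(**params)
    assert est2.get_params() == params


def test_build_final_ensemble_counts_and_mean():
    data = _tiny_dataset(4)
    cfg = TrainConfig(batch_size=2, learning_rate=1e-3, epochs=1, folds=2, seed=2)
    specs = [LossSpec("tversky", beta=0.5), LossSpec("binary_cross_entropy")]
    ens = build_final_ensemble(specs, data, cfg, network_spec=TINY_NET)
    assert len(ens) == 4  # 2 losses x 2 folds
    from aorticroot.volume_io import Volume

    vol = Volume(data[0][0], (1.0,) * 3, (0.0,) * 3)
    out = ens.predict(vol)
    oracle = np.mean([m.predict(data[0][0]) for m in ens.members], axis=0)
    assert np.allclose(out.values, oracle, atol=1e-6)
    with pytest.raises(ValueError):
        build_final_ensemble([], data, cfg, TINY_NET)
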