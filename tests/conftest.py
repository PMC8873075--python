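"""Shared fixtures.

The expensive fixture (`desk_models`) trains the full desk-scale cascade
once per session: detector, three step-2 segmenters (three seeds), the
annulus-region segmenter, and the 4-loss x 2-fold bagged ensemble.  The
heavy acceptance tests all draw from it so the suite trains each model
exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from aorticroot.losses import LossSpec
from aorticroot.phantom import PhantomParams, generate_dataset, generate_phantom
from aorticroot.pipeline import (
    RunConfig,
    detect_roi_center,
    make_step_crops,
    train_step_models,
)
from aorticroot.training import (
    EnsembleModel,
    TrainConfig,
    UNet3DSegmenter,
    crossval_train,
    dice_score,
)

DESK_BASE_PARAMS = dict(spacing_mm=(1.2, 1.2, 1.2), extent_mm=(96.0, 96.0, 120.0))
COHORT_SEED = 2001
ENSEMBLE_EVAL_SEED = 31337

# the paper's step-2 selection: Tversky 0.55 and focal Tversky 0.55/0.65/0.70
STEP2_SELECTED_LOSSES = [
    LossSpec("tversky", beta=0.55),
    LossSpec("focal_tversky", beta=0.55, gamma=2.0),
    LossSpec("focal_tversky", beta=0.65, gamma=2.0),
    LossSpec("focal_tversky", beta=0.70, gamma=2.0),
]


@pytest.fixture(scope="session")
def small_phantom():
    """One fast, coarse phantom with ground truth (noise-free)."""
    params = PhantomParams(
        noise_sd=0.0,
        calcification_blobs=0,
        spacing_mm=(1.2, 1.2, 1.2),
        extent_mm=(96.0, 96.0, 120.0),
        seed=11,
    )
    return generate_phantom(params)


@pytest.fixture(scope="session")
def desk_models(tmp_path_factory):
    """Train the desk-scale cascade once: returns models plus their metrics.

    Protocol: a cohort of 20 phantoms; the ROI detector trains on 10 of them
    (with upper-aorta hard negatives); steps 2/3 train on ROIs placed by the
    trained detector.  Three differently seeded step-2 models train on 10
    cases with 25 epochs and validate on the held-out 10; the annulus model
    trains on all 20.  The bagged ensemble fine-tunes 4 losses x 2 folds
    from the first step-2 model and is evaluated against its members on six
    fresh phantoms.
    """
    out = tmp_path_factory.mktemp("desk_models")
    cfg = RunConfig(out_dir=str(out))
    base = PhantomParams(**DESK_BASE_PARAMS)
    cohort = generate_dataset(20, None, seed=COHORT_SEED, base_params=base)

    step1 = train_step_models(cohort, 1, cfg, seed=88)
    centers = [detect_roi_center(v, step1, cfg) for v, _ in cohort]

    # -- step 2: three seeds, 25 epochs, 48^3 crops, 10 train / 10 validation
    crops2 = [
        make_step_crops(v, t, 2, cfg, roi_center_mm=c)
        for (v, t), c in zip(cohort, centers)
    ]
    seed_models, seed_val_f1 = [], []
    for seed in (0, 1, 2):
        est = UNet3DSegmenter(
            base_filters=cfg.base_filters,
            levels=cfg.levels,
            dropout_rate=cfg.dropout_rate,
            loss="tversky",
            beta=0.7,
            learning_rate=cfg.learning_rate,
            epochs=25,
            batch_size=cfg.batch_size,
            max_shift_voxels=cfg.max_shift_voxels,
            seed=seed,
        )
        est.fit([c[0] for c in crops2[:10]], [c[1] for c in crops2[:10]])
        seed_val_f1.append(est.score([c[0] for c in crops2[10:]], [c[1] for c in crops2[10:]]))
        seed_models.append(est.model_)
    step2 = EnsembleModel(seed_models)

    # -- step 3: annulus-region model on all 20 cases
    crops3 = [
        make_step_crops(v, t, 3, cfg, roi_center_mm=c)
        for (v, t), c in zip(cohort, centers)
    ]
    est3 = UNet3DSegmenter(
        base_filters=cfg.base_filters,
        levels=cfg.levels,
        dropout_rate=cfg.dropout_rate,
        loss="tversky",
        beta=0.5,
        learning_rate=cfg.learning_rate,
        lr_schedule="cosine",
        epochs=30,
        batch_size=cfg.batch_size,
        max_shift_voxels=cfg.max_shift_voxels,
        seed=7,
    )
    est3.fit([c[0] for c in crops3], [c[1] for c in crops3])
    step3 = EnsembleModel([est3.model_])

    # -- bagged ensemble: 4 selected losses x 2 folds, fine-tuned from the
    #    first step-2 model, evaluated on fresh phantoms
    tc = TrainConfig(
        batch_size=cfg.batch_size,
        learning_rate=1e-2,
        lr_schedule="cosine",
        epochs=6,
        max_shift_voxels=cfg.max_shift_voxels,
        folds=2,
        seed=5,
    )
    net_spec = cfg.network_spec()
    members = []
    for ls in STEP2_SELECTED_LOSSES:
        members.extend(
            crossval_train(crops2, ls, tc, network_spec=net_spec, init_model=seed_models[0])
        )
    eval_set = generate_dataset(6, None, seed=ENSEMBLE_EVAL_SEED, base_params=base)
    eval_crops = [make_step_crops(v, t, 2, cfg) for v, t in eval_set]
    member_f1 = [
        float(np.mean([dice_score(m.predict(x) >= 0.5, y) for x, y in eval_crops]))
        for m in members
    ]
    ens_f1 = float(
        np.mean(
            [
                dice_score(np.mean([m.predict(x) for m in members], axis=0) >= 0.5, y)
                for x, y in eval_crops
            ]
        )
    )

    return {
        "config": cfg,
        "ensembles": {"step1": step1, "step2": step2, "step3": step3},
        "step2_val_f1": seed_val_f1,
        "ensemble_member_f1": member_f1,
        "ensemble_f1": ens_f1,
    }
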