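"""Shared fixtures.

The expensive piece — a desk-scale grouped-CV CNN run on a synthetic
cohort — is computed once per session and shared by the evaluation and
acceptance tests.  Sizes: 40 cases of 30 frames, P-type ROI resized to
32x32, 6 folds x 2 repetitions of the numpy small CNN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from uteroflow import (
    RoiSpec,
    SimulationConfig,
    TrainConfig,
    generate_cohort,
    prepare_type,
    score_grid,
    window_series,
)

#: frame/image sizes for tests that only exercise the clinical table
TINY_STACK = dict(frames_per_case=4, image_size=(32, 32))

DESK_SIM = dict(n_cases=40, seed=11)
DESK_ROI = dict(image_type="P", output_size=(32, 32))
DESK_TRAIN = dict(
    backbone="small_cnn", input_size=(32, 32), batch_size=32, seed=11
)
DESK_FOLDS = 6
DESK_REPS = 2


def prepared_images(cases, roi_kwargs=DESK_ROI):
    """case_id -> (K, H, W, 3) combined-image stacks after ROI prep."""
    spec = RoiSpec(**roi_kwargs)
    return {
        c.case_id: np.stack(
            [
                ci.channels
                for ci in window_series(prepare_type(c.sequence, c.annotation, spec))
            ]
        )
        for c in cases
    }


@pytest.fixture(scope="session")
def desk_cohort():
    return generate_cohort(SimulationConfig(**DESK_SIM))


@pytest.fixture(scope="session")
def desk_truths(desk_cohort):
    return {c.case_id: c.truth for c in desk_cohort}


@pytest.fixture(scope="session")
def desk_scores(desk_cohort, desk_truths) -> pd.DataFrame:
    """Scores from the full desk-scale grouped-CV small-CNN grid."""
    images = prepared_images(desk_cohort)
    return score_grid(
        images,
        desk_truths,
        image_type="P",
        config=TrainConfig(**DESK_TRAIN),
        folds=DESK_FOLDS,
        repetitions=DESK_REPS,
    )


def motion_fixture(n_per_class=20, size=32, amplitude=35.0, seed=0):
    """Linearly separable combined images: near-neutral (success=1) vs
    high-motion sinusoidal texture (failure=0)."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_per_class):
        images.append(np.clip(rng.normal(128.0, 2.0, (size, size, 3)), 0, 255))
        labels.append(1)
        phase = rng.uniform(0, 2 * np.pi)
        wave = amplitude * np.sin(2 * np.pi * xx / 8.0 + phase)
        img = 128.0 + wave[..., None] + rng.normal(0, 2.0, (size, size, 3))
        images.append(np.clip(img, 0, 255))
        labels.append(0)
    return np.stack(images), np.array(labels)
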