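import dataclasses

import numpy as np
import pytest

from cropheight import (
    MarkerReference,
    PipelineConfig,
    apply_threshold,
    longest_vertical_runs,
    render_scene,
    response_plane,
    select_threshold,
)
from cropheight.synthetic_scenes import SceneSpec, sample_training_values


@pytest.fixture(scope="session")
def bare_field_calibration():
    """Pipeline calibrated on a bare-field frame (crop height 0).

    The bar is staked out before the crop emerges, so the initial frame
    shows the whole above-ground bar: initial_crop_cm = 0 and
    initial_cm = the full 230 cm. The clip level is learned from 200
    labelled samples of each class on that frame, and initial_px is the
    bar the pipeline itself detects — so any systematic half-kernel
    overhang at the bar ends is absorbed into the calibration, exactly as
    when the reference is read off the first real frame.
    """
    spec = SceneSpec(crop_height_cm=0.0, seed=101)
    img, truth = render_scene(spec)
    placeholder = MarkerReference(
        initial_px=1,
        initial_cm=230.0,
        initial_crop_cm=0.0,
        above_ground_cm=230.0,
        stripe_cm=10.0,
        marker_width_px=5,
    )
    config = PipelineConfig(marker=placeholder)
    resp = response_plane(img, config)
    marker_vals, other_vals = sample_training_values(resp, truth, kernel_size=11, rng=7)
    model = select_threshold(marker_vals, other_vals)
    run = longest_vertical_runs(apply_threshold(resp, model))[0]
    marker = dataclasses.replace(placeholder, initial_px=run.length)
    return {
        "config": PipelineConfig(marker=marker),
        "threshold": model,
        "scene": spec,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
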