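import dataclasses

import numpy as np
import pytest

from icspectrum import SceneConfig, generate_graph, render_frames
from icspectrum.pipeline import analyze_frames, default_run_config, simulate_eye


@pytest.fixture(scope="session")
def small_scene():
    """Compact noise-free scene for fast structural tests."""
    return SceneConfig(
        grid_px=384, noise_sd=0.0, transient_rate=0.0, n_frames=3, rng_seed=7
    )


@pytest.fixture(scope="session")
def small_eye(small_scene):
    graph, gt = generate_graph(small_scene)
    stack = render_frames(graph, small_scene)
    return {"scene": small_scene, "graph": graph, "gt": gt, "stack": stack}


@pytest.fixture(scope="session")
def small_analysis(small_eye):
    cfg = dataclasses.replace(
        default_run_config(small_eye["scene"].grid_px), blur_radius_px=0.0
    )
    res = analyze_frames(small_eye["stack"], cfg, eye_id="small")
    res["scene"] = small_eye["scene"]
    return res


@pytest.fixture(scope="session")
def noisy_analysis():
    """An eye under realistic conditions (noise, transient loss, dropout)."""
    scene = SceneConfig(
        grid_px=384, noise_sd=0.05, transient_rate=0.1, dropout_rate=0.2, rng_seed=21
    )
    sim = simulate_eye(scene)
    cfg = default_run_config(scene.grid_px)
    res = analyze_frames(sim["frames"], cfg, eye_id="noisy")
    res["scene"] = scene
    res["sim"] = sim
    return res


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
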