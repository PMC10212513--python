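import numpy as np
import pytest

from retscope.synthgen import SceneConfig, build_scene, render_frames


@pytest.fixture(scope="session")
def noiseless_scene():
    """Well-separated spots, zero noise, fixed per-class potentials."""
    cfg = SceneConfig(
        image_shape=(128, 128),
        n_mito=20,
        class_fractions={"fet_responder": 0.5, "stalled": 0.3, "ret": 0.2},
        read_noise_sigma=0.0,
        photon_gain=0.0,
        tmrm_potential_sd_mv=0.0,
        nadph_baseline_cv=0.0,
        fet_log2_response_sd=0.0,
        ret_log2_response_sd=0.0,
        seed=7,
    )
    return build_scene(cfg)


@pytest.fixture(scope="session")
def noiseless_nadph_stack(noiseless_scene):
    return render_frames(
        noiseless_scene, ("before", "after"), "nadph", challenged={"after"}
    )


@pytest.fixture(scope="session")
def noisy_scene():
    cfg = SceneConfig(image_shape=(128, 128), n_mito=40, seed=11)
    return build_scene(cfg)
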