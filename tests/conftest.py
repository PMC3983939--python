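import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ratiokd as rk

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def run_experiment(params, n_fields=5, seed=None, **kw):
    """Generate and analyze one synthetic test/control experiment."""
    seed = params.seed if seed is None else seed
    bundle = rk.generate_experiment(params, n_fields, n_fields, seed=seed)
    result = rk.kd_from_experiment(
        bundle.test_fields,
        bundle.control_fields,
        [bundle.untransfected_field],
        rng=seed,
        **kw,
    )
    return bundle, result


@pytest.fixture(scope="session")
def default_seg():
    return rk.SegmentationConfig()


@pytest.fixture(scope="session")
def noise_free_params():
    """Noise-free scene parameters: flat DNA brightness across cells, no shot
    or read noise, so measured ROI means equal truth exactly."""
    return rk.SceneParams(
        shot_noise=False, read_noise_sd=0.0, dna_cell_sdlog=0.0, seed=21
    )


@pytest.fixture(scope="session")
def null_result():
    """k=0, f=1 experiment with ~500 transfectants per arm."""
    params = rk.SceneParams(knockdown_efficiency=0.0, seed=101)
    return run_experiment(params, n_fields=5, seed=101)


@pytest.fixture(scope="session")
def knockdown_results():
    """One experiment per knockdown efficiency, ~500 transfectants/arm."""
    out = {}
    for k in (0.0, 0.5, 0.8, 0.95, 1.0):
        params = rk.SceneParams(
            knockdown_efficiency=k, outlier_fraction=0.02, seed=202
        )
        out[k] = run_experiment(params, n_fields=5, seed=202)
    return out


@pytest.fixture(scope="session")
def bias_results():
    """Knockdown experiment with a 0.7x green-expression bias on the shRNA
    plasmid, with a matched scrambled-target pair for delta estimation."""
    params = rk.SceneParams(
        knockdown_efficiency=0.95, shrna_gfp_bias=0.7, seed=303
    )
    bundle = rk.generate_experiment(params, 5, 5, seed=303)
    scr_params = rk.SceneParams(
        knockdown_efficiency=0.0, shrna_gfp_bias=0.7, seed=304
    )
    scr = rk.generate_experiment(scr_params, 5, 5, seed=304)
    corrected = rk.kd_from_experiment(
        bundle.test_fields,
        bundle.control_fields,
        [bundle.untransfected_field],
        scramble_test_fields=scr.test_fields,
        scramble_control_fields=scr.control_fields,
        rng=303,
    )
    uncorrected = rk.kd_from_experiment(
        bundle.test_fields,
        bundle.control_fields,
        [bundle.untransfected_field],
        rng=303,
    )
    return corrected, uncorrected
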