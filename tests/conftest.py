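import numpy as np
import pytest

from accelcal.io_cli import RunConfig, calibrate_cohort, extract_calibration_points
from accelcal.synthetic_data import (GeneratorConfig, analytic_cutpoints,
                                     simulate_cohort, simulate_lab_session)


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def _calibrated(seed: int, noise_free: bool):
    gen = GeneratorConfig(seed=seed)
    if noise_free:
        gen.noise.vo2_rel_sd = 0.0
        gen.noise.mg_rel_sd = 0.0
        for gp in gen.groups.values():
            gp.height_sd = 0.0
            gp.weight_sd = 0.0
            gp.vo2rest_per_kg_sd = 0.0
    cfg = RunConfig()
    g = gen.rng()
    cohort = simulate_cohort(gen, g)
    points = []
    for subj in cohort:
        recs, trace = simulate_lab_session(subj, gen, g)
        points.extend(extract_calibration_points(subj.profile, recs, trace, cfg))
    table, report, curves = calibrate_cohort(points, cfg)
    truth = analytic_cutpoints(gen, cohort)
    return {"gen": gen, "config": cfg, "cohort": cohort, "points": points,
            "table": table, "report": report, "curves": curves, "truth": truth}


@pytest.fixture(scope="session")
def calibrated_seed1():
    """Full lab calibration of the default synthetic cohort, seed 1."""
    return _calibrated(seed=1, noise_free=False)


@pytest.fixture(scope="session")
def calibrated_noise_free():
    """Noise-free, homogeneous-cohort calibration (exact-recovery oracle)."""
    return _calibrated(seed=1, noise_free=True)
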