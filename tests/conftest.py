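import numpy as np
import pytest
from hypothesis import settings

import gazersa as gz

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_scenes():
    """Four 48x48 scenes with three feature levels."""
    return gz.make_scene_features(4, 48, 48, 3, [3.0, 8.0, 16.0], seed=11)


@pytest.fixture(scope="session")
def tiny_study():
    """A small but complete synthetic study configuration."""
    return gz.demo_study_config(n_scenes=8, H=32, W=32, n_participants=3,
                                n_voxels=160, seed=7)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_study, tmp_path_factory):
    """The tiny study written to disk as a bundle."""
    outdir = tmp_path_factory.mktemp("bundle")
    gz.generate_study(tiny_study, outdir)
    return outdir


@pytest.fixture(scope="session")
def tiny_run_config(tiny_study):
    return gz.demo_run_config(tiny_study, min_usable_trials=5)


def make_similarity_table(rng, n_per_group=10, groups=("young", "old"),
                          rois=("low", "mid", "high"), sigma_subject=0.7,
                          sigma_resid=1.0, cell_effects=None):
    """Balanced random-intercept similarity table for inference tests."""
    import pandas as pd

    rows = []
    for gi, g in enumerate(groups):
        for s in range(n_per_group):
            pid = f"{g}{s:02d}"
            u = rng.normal(0, sigma_subject)
            for ri, roi in enumerate(rois):
                eff = 0.0 if cell_effects is None else cell_effects[gi][ri]
                rows.append({"participant_id": pid, "age_group": g,
                             "roi_id": roi,
                             "rho": u + eff + rng.normal(0, sigma_resid)})
    return pd.DataFrame(rows)
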