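import numpy as np
import pytest

from tractconfound.synthetic import CohortParams, make_templates
from tractconfound.volumes import GridSpec


@pytest.fixture(scope="session")
def grid48():
    return GridSpec((48, 48, 48), 2.0, -40.0)


@pytest.fixture(scope="session")
def phantom(grid48):
    """Default templates and masks on the 48-cube grid."""
    templates, masks = make_templates(grid48, seed=1)
    return templates, masks


@pytest.fixture()
def quiet_cohort_params():
    """Cohort with every stochastic term switched off."""
    return CohortParams(
        n_pairs=4,
        damage_sd=0.0,
        upreg_noise_sd=0.0,
        walk_noise_sd_m=0.0,
        global_nqa_sd=0.0,
        crst_noise_sd=0.0,
        cst_noise_sd=0.0,
        voxel_noise_sd=0.0,
        scanner_gain_log_sd=0.0,
        misalign_vox=0,
        seed=0,
    )
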