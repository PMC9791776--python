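import numpy as np
import pandas as pd
import pytest

from progdx import CohortProfile, SyntheticSpec, generate_two_cohort_study


@pytest.fixture(scope="session")
def strong_study():
    """Two-cohort synthetic study with strong planted signal (4-fold/step)."""
    spec = SyntheticSpec(
        group_sizes={"NC": 60, "MP": 20, "AA_LGD": 25, "AA_HGD": 25, "CRC_I_II": 25, "CRC_III_IV": 25},
        n_features=400,
        n_progressive_up=8,
        n_progressive_down=8,
        per_step_log_fold=float(np.log(4)),
        zero_inflation=0.1,
        dispersion=0.6,
        seed=11,
    )
    return spec, generate_two_cohort_study(spec)


@pytest.fixture()
def tiny_profile():
    data = pd.DataFrame(
        [[0.6, 0.4], [0.5, 0.5]],
        index=["s1", "s2"],
        columns=["f1", "f2"],
    )
    return CohortProfile(data, level="genus", cohort_id="demo")
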