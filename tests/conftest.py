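import numpy as np
import pytest

import breathdx as bx
from breathdx import reference as ref


@pytest.fixture(scope="session")
def clean_ims_table():
    """53-subject planted IMS cohort (21 AD / 16 PD / 16 HC), no overlap."""
    spec = bx.CohortSpec.single_site({"AD": 21, "PD": 16, "HC": 16}, seed=3)
    return bx.generate_ims_cohort(spec, ref.REFERENCE_TREE, overlap=0.0)


@pytest.fixture(scope="session")
def planted_enose_records():
    """Two-group eNose cohort with the effect confined to sensor 1."""
    spec = bx.CohortSpec.single_site({"AD": 15, "HC": 15}, seed=5)
    effect = bx.EffectModel.planted_sensor(32, group="AD", sensor=1,
                                           shift=4.0, noise_sd=1.0)
    return bx.generate_enose_cohort(spec, effect)


def sensor_values(obs):
    cols = [c for c in obs.columns
            if c.startswith("s") and c not in ("subject_id", "site")]
    return obs[cols].to_numpy(dtype=float)
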