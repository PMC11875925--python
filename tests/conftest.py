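"""Shared fixtures: a water-bath calibration shot reused across TOF/physics tests."""

import numpy as np
import pytest

from usct import phantom, wavesim


@pytest.fixture(scope="session")
def desk_water_shot():
    """Desk-preset simulation of a homogeneous water bath, two emitters.

    Shared by arrival-time, picker, reciprocity and noise tests (the solve is
    the expensive part; each test reads different slices of it).
    """
    array, grid, pulse, T = wavesim.desk_system()
    med = phantom.AcousticMedium(
        sos=np.full(grid.shape, 1.5), density=np.ones(grid.shape),
        attenuation=np.zeros(grid.shape), power_law_exponent=1.5,
        water_sos=1.5, grid_spacing=grid.spacing)
    ms = wavesim.simulate_measurements(med, array, pulse, grid, emitters=[0, 16], T=T)
    return ms, pulse


@pytest.fixture(scope="session")
def study_results():
    """Desk-scale study: data, the three trained channel variants, and two
    fine-tuned models.  Generated once; consumed by the ensemble-ordering and
    fine-tuning-trend tests."""
    from usct import studies

    cfg = studies.DeskStudyConfig()
    data = studies.generate_study_data(cfg, seed=1)
    states = studies.train_variants(data, epochs=150, batch_size=10, seed=0)
    finetuned = {w: studies.finetune_variant(states["rt"], data, w=w, epochs=100)
                 for w in (2.0, 20.0)}
    return data, states, finetuned
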