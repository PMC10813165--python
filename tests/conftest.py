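import numpy as np
import pandas as pd
import pytest

import retscreen as rs


@pytest.fixture(scope="session")
def acq() -> rs.AcquisitionSpec:
    return rs.AcquisitionSpec()


@pytest.fixture(scope="session")
def default_params() -> rs.WaveformModelParams:
    return rs.WaveformModelParams()


@pytest.fixture(scope="session")
def noiseless_params() -> rs.WaveformModelParams:
    from dataclasses import replace

    return replace(rs.WaveformModelParams(), noise_sd_uV=0.0)


@pytest.fixture(scope="session")
def noiseless_wave(noiseless_params, acq) -> rs.ERGWaveform:
    return rs.simulate_waveform(noiseless_params, acq=acq, seed=1)


@pytest.fixture(scope="session")
def tiny_design() -> rs.CohortDesign:
    return rs.CohortDesign(
        n_per_group={g: 3 for g in rs.GROUPS},
        timepoints_min=(0, 15, 30),
        seed=11,
    )


@pytest.fixture()
def hand_table() -> pd.DataFrame:
    """The 2-group x 2-time toy table with a hand-checkable decomposition."""
    rows = []
    for subj, grp, vals in [
        ("A", "g1", (10.0, 12.0)),
        ("B", "g1", (14.0, 16.0)),
        ("C", "g2", (20.0, 22.0)),
        ("D", "g2", (24.0, 26.0)),
    ]:
        for t, v in zip((0.0, 30.0), vals):
            rows.append(
                dict(subject_id=subj, grp=grp, genotype="WT", treatment="VEH",
                     time_min=t, measure="m", value=v)
            )
    return pd.DataFrame(rows)
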