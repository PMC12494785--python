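import numpy as np
import pandas as pd
import pytest

from ctdna_burden import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fixed mid-sized synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=50, seed=11))


@pytest.fixture()
def plasma_calls():
    """Hand-built plasma call table covering every inclusion-rule branch."""
    rows = [
        # sample, vaf, reads, canonical, in_normal, normal_vaf, hotspot, confirmed
        ("keep_boundary",  0.004, 5,  True,  False, np.nan, False, False),
        ("keep_clean",     0.120, 150, True, False, np.nan, False, False),
        ("drop_reads",     0.003, 4,  True,  False, np.nan, False, False),
        ("rescue_hotspot", 0.002, 2,  True,  False, np.nan, True,  False),
        ("rescue_tissue",  0.002, 3,  False, False, np.nan, False, True),
        ("drop_normal",    0.010, 12, True,  True,  0.0100, False, False),
        ("keep_override",  0.070, 90, True,  True,  0.0008, False, True),
        ("drop_noncanon",  0.020, 30, False, False, np.nan, False, False),
    ]
    return pd.DataFrame([
        {"patient_id": "P1", "sample_id": sid, "compartment": "plasma",
         "timepoint": "BL", "chrom": "12", "pos": 25398284 + i, "ref": "G",
         "alt": "T", "gene": "KRAS", "vaf": vaf, "alt_consensus_reads": reads,
         "n_callers": 2, "impact": "moderate", "canonical": canon,
         "detected_in_matched_normal": in_norm, "normal_vaf": nvaf,
         "kras_hotspot": hot, "confirmed_elsewhere": conf}
        for i, (sid, vaf, reads, canon, in_norm, nvaf, hot, conf) in enumerate(rows)
    ])
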