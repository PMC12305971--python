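import numpy as np
import pytest

from strideboard.dataset_assembly import add_split_and_weights, assemble_feature_table
from strideboard.gait_features import ANGLES, N_CYCLE_SAMPLES, StridePair, StrideRecord
from strideboard.synthetic_cohort import SeverityProfile, SimulationConfig, simulate_cohort


def make_record(
    side: str = "ipsi",
    patient_id: str = "P000",
    stance_fraction: float = 0.62,
    foot_strike_s: float = 0.0,
    stride_time_s: float = 1.0,
    stride_length_m: float = 1.25,
    step_length_m: float = 0.625,
    step_width_m: float = 0.10,
    leg_length_m: float = 0.85,
    body_height_m: float = 1.70,
    angles: dict | None = None,
    fill_value: float = 0.0,
) -> StrideRecord:
    """Minimal valid stride record; unspecified angle traces are constant."""
    full = {a: np.full(N_CYCLE_SAMPLES, fill_value, dtype=float) for a in ANGLES}
    if angles:
        for k, v in angles.items():
            full[k] = np.asarray(v, dtype=float)
    return StrideRecord(
        patient_id=patient_id, side=side, angles=full,
        foot_strike_s=foot_strike_s,
        foot_off_s=foot_strike_s + stance_fraction * stride_time_s,
        next_foot_strike_s=foot_strike_s + stride_time_s,
        stride_length_m=stride_length_m, step_length_m=step_length_m,
        step_width_m=step_width_m, leg_length_m=leg_length_m,
        body_height_m=body_height_m)


def make_pair(patient_id="P000", cane=0, afo=0, labels=None, **kwargs) -> StridePair:
    """Symmetric stride pair: contra shifted half a cycle, otherwise identical."""
    ipsi = make_record("ipsi", patient_id=patient_id, **kwargs)
    contra = make_record("contra", patient_id=patient_id,
                         foot_strike_s=kwargs.get("foot_strike_s", 0.0)
                         + 0.5 * kwargs.get("stride_time_s", 1.0),
                         **{k: v for k, v in kwargs.items()
                            if k not in ("foot_strike_s",)})
    return StridePair(patient_id=patient_id, pair_index=0, ipsi=ipsi, contra=contra,
                      walking_cane=cane, afo=afo, labels=labels or {})


def default_profile(**overrides) -> SeverityProfile:
    sev = {s: 0.0 for s in ("trunk", "leg", "arm", "speed", "fluency", "stability")}
    sev.update(overrides)
    return SeverityProfile(severities=sev, affected_side="left")


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(n_patients=20, seed=11))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    table = assemble_feature_table(small_cohort)
    return add_split_and_weights(table, 0.30, seed=5)
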