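"""Synthetic hemiparetic gait cohort driven by latent per-subscore severities.

Real instrumented-gait databases of stroke patients are not publicly
available, so this module generates one with the statistical structure every
downstream stage needs: each patient carries a latent severity theta_k in
[0, 3] for each of the six SMS subscores (trunk, leg, arm, speed, fluency,
stability).  The severities drive

* the joint-angle trajectories -- smooth periodic curves built from low-order
  Fourier templates of normative gait, with amplitudes/offsets modulated by
  the relevant severity (e.g. knee-flexion range shrinks with theta_leg, a
  high-frequency wobble grows with theta_fluency) plus Gaussian jitter;
* the spatiotemporal stride parameters -- stride time grows and stride length
  shrinks with theta_speed, stance fraction grows with theta_stability, the
  contralateral foot strike shifts away from 50 % of the cycle with
  theta_leg (the limp);
* walking-aid use -- cane and ankle-foot-orthosis probabilities are logistic
  in theta_stability;
* the five expert recommendations per subscore --
  clip(round(theta_k + eps), 0, 3) with eps ~ Normal(0, sigma_rater) i.i.d.
  per rater.

Severities are drawn from a Gaussian copula with uniform [0, 3] marginals and
a configurable rank correlation between subscores, emulating the clinical
fact that globally impaired patients tend to be impaired on several criteria
at once.  A single seed fixes the whole cohort bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .expert_board import SUBSCORES
from .gait_features import ANGLES, ANGLE_GROUP, N_CYCLE_SAMPLES, StrideRecord

# --------------------------------------------------------------------------
# configuration & domain types
# --------------------------------------------------------------------------

DEFAULT_COUPLING = {
    "leg_amplitude": 0.50,     # fractional ROM loss of leg/pelvis angles at theta_leg = 3
    "arm_amplitude": 0.60,     # fractional ROM loss of shoulder/elbow angles at theta_arm = 3
    "trunk_lean_deg": 8.0,     # forward/side lean offset of thorax & spine at theta_trunk = 3
    "fluency_wobble_deg": 3.0, # amplitude of the 7th-harmonic wobble at theta_fluency = 3
    "stability_sway": 0.8,     # fractional trunk-sway amplitude gain at theta_stability = 3
    "speed_stride_time_s": 0.50,   # stride-time increase at theta_speed = 3
    "speed_stride_length_m": 0.60, # stride-length decrease at theta_speed = 3
    "stability_stance": 0.08,  # stance-fraction increase at theta_stability = 3
    "leg_asymmetry": 0.06,     # contralateral foot-strike offset beyond 50 % at theta_leg = 3
    "aid_steepness": 2.2,      # logistic slope of aid probability in theta_stability
    "cane_midpoint": 1.7,      # theta_stability at which P(cane) = 0.5
    "afo_midpoint": 2.3,       # theta_stability at which P(AFO) = 0.5
}


@dataclass(frozen=True)
class SeverityProfile:
    """Latent severities theta_k in [0,3] per subscore, plus the affected side."""

    severities: dict[str, float]
    affected_side: str  # "left" or "right"

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected side must be left/right, got {self.affected_side!r}")
        for k in SUBSCORES:
            if k not in self.severities:
                raise ValueError(f"missing severity for subscore {k!r}")
            v = self.severities[k]
            if not (0.0 <= v <= 3.0):
                raise ValueError(f"severity {k}={v} outside [0,3]")

    def __getitem__(self, k: str) -> float:
        return self.severities[k]


@dataclass
class SimulationConfig:
    """Cohort-generation parameters; the seed fixes the cohort bit-for-bit."""

    n_patients: int = 100
    strides_per_patient: tuple[int, int] = (4, 12)
    sigma_rater: float = 0.25   # score units
    sigma_kin: float = 1.0      # degrees of per-sample jitter on angle traces
    severity_correlation: float = 0.5  # Gaussian-copula correlation between subscores
    coupling: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.strides_per_patient
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if lo < 2 or hi < lo:
            raise ValueError("strides_per_patient must be a range with lower bound >= 2")
        if self.sigma_rater < 0 or self.sigma_kin < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not (-1.0 < self.severity_correlation < 1.0):
            raise ValueError("severity_correlation must lie in (-1,1)")


@dataclass
class Patient:
    patient_id: str
    profile: SeverityProfile
    ipsi_strides: list[StrideRecord]
    contra_strides: list[StrideRecord]
    rater_panels: dict[str, list[int]]  # subscore -> five recommendations
    walking_cane: int
    afo: int


@dataclass
class Cohort:
    config: SimulationConfig
    patients: list[Patient]


# --------------------------------------------------------------------------
# normative angle templates (<= 5 Fourier harmonics)
# --------------------------------------------------------------------------

_N_HARMONICS = 5


def _bump(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    # periodic (von-Mises-like) bump centred at cycle fraction mu
    return np.exp((np.cos(2 * np.pi * (t - mu)) - 1.0) / (4 * np.pi**2 * sigma**2))


def _normative_shape(angle: str, t: np.ndarray) -> np.ndarray:
    """Continuous normative trajectory (degrees) at cycle fraction t in [0,1]."""
    s = 2 * np.pi * t
    if angle == "pelvis_tilt":
        return 10.0 + 2.0 * np.cos(2 * s)
    if angle == "pelvis_obliquity":
        return 4.0 * np.sin(s)
    if angle == "pelvis_rotation":
        return 5.0 * np.cos(s)
    if angle == "thorax_tilt":
        return 4.0 + 1.5 * np.cos(2 * s)
    if angle == "thorax_side_tilt":
        return 2.5 * np.sin(s)
    if angle == "thorax_rotation":
        return -5.0 * np.cos(s)
    if angle == "foot_progression":
        return -8.0 + 4.0 * _bump(t, 0.70, 0.10) * 5.0 - 2.0 * np.sin(s)
    if angle == "hip_flexion":
        return 10.0 + 20.0 * np.cos(s + 0.3)
    if angle == "hip_adduction":
        return 2.0 + 5.0 * np.cos(s) - 3.0 * _bump(t, 0.75, 0.12)
    if angle == "knee_flexion":
        # small stance-phase bump, large swing-phase flexion peak
        return 5.0 + 14.0 * _bump(t, 0.15, 0.09) + 55.0 * _bump(t, 0.72, 0.10)
    if angle == "ankle_dorsiflexion":
        return (2.0 + 8.0 * _bump(t, 0.40, 0.12) - 18.0 * _bump(t, 0.62, 0.06)
                + 3.0 * _bump(t, 0.85, 0.10))
    if angle == "ankle_inversion":
        return 1.0 + 4.0 * _bump(t, 0.65, 0.10) - 2.0 * np.sin(s)
    if angle == "spine_tilt":
        return 6.0 + 1.5 * np.cos(2 * s + 0.5)
    if angle == "spine_side_tilt":
        return 2.0 * np.sin(s + 0.4)
    if angle == "spine_rotation":
        return -4.0 * np.cos(s + 0.2)
    if angle == "shoulder_flexion":
        return -8.0 - 12.0 * np.cos(s + 0.3)
    if angle == "shoulder_adduction":
        return 5.0 + 3.0 * np.cos(s)
    if angle == "elbow_flexion":
        return 25.0 + 8.0 * np.cos(s + 0.5)
    raise KeyError(f"unknown angle id {angle!r}")


def _fit_fourier(angle: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Project the normative shape onto <= 5 harmonics (offset, cos, sin)."""
    t = np.arange(400) / 400.0
    y = _normative_shape(angle, t)
    offset = float(y.mean())
    a = np.empty(_N_HARMONICS)
    b = np.empty(_N_HARMONICS)
    for k in range(1, _N_HARMONICS + 1):
        a[k - 1] = 2.0 * float(np.mean(y * np.cos(2 * np.pi * k * t)))
        b[k - 1] = 2.0 * float(np.mean(y * np.sin(2 * np.pi * k * t)))
    return offset, a, b


_TEMPLATE_COEFS: dict[str, tuple[float, np.ndarray, np.ndarray]] = {
    angle: _fit_fourier(angle) for angle in ANGLES
}


def normative_template(angle: str) -> np.ndarray:
    """The unmodulated 101-sample Fourier template of one angle (degrees)."""
    if angle not in _TEMPLATE_COEFS:
        raise KeyError(f"unknown angle id {angle!r}")
    offset, a, b = _TEMPLATE_COEFS[angle]
    t = np.arange(N_CYCLE_SAMPLES) / 100.0
    y = np.full(N_CYCLE_SAMPLES, offset)
    for k in range(1, _N_HARMONICS + 1):
        y = y + a[k - 1] * np.cos(2 * np.pi * k * t) + b[k - 1] * np.sin(2 * np.pi * k * t)
    return y


_LEG_GROUPS = {"pelvis", "foot", "hip", "knee", "ankle"}
_ARM_GROUPS = {"shoulder", "elbow"}
_TRUNK_GROUPS = {"thorax", "spine"}


def angle_template(
    angle: str,
    side: str,
    profile: SeverityProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """One severity-modulated, jittered 101-sample angle trace.

    ``side`` is "ipsi" (the affected side, full modulation) or "contra"
    (attenuated modulation).  The trace is periodic: sample 100 repeats
    sample 0 including its jitter.
    """
    if angle not in _TEMPLATE_COEFS:
        raise KeyError(f"unknown angle id {angle!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    c = config.coupling
    base = normative_template(angle)
    offset = float(base.mean())
    wave = base - offset

    side_factor = 1.0 if side == "ipsi" else 0.35
    group = ANGLE_GROUP[angle]
    th = {k: profile[k] / 3.0 for k in SUBSCORES}

    amp = 1.0
    shift = 0.0
    if group in _LEG_GROUPS:
        amp *= 1.0 - c["leg_amplitude"] * th["leg"] * side_factor
    if group in _ARM_GROUPS:
        amp *= 1.0 - c["arm_amplitude"] * th["arm"] * side_factor
    if group in _TRUNK_GROUPS:
        shift += c["trunk_lean_deg"] * th["trunk"]
        amp *= 1.0 - 0.3 * th["trunk"]
    if angle in ("thorax_side_tilt", "pelvis_obliquity"):
        amp *= 1.0 + c["stability_sway"] * th["stability"]

    t = np.arange(N_CYCLE_SAMPLES) / 100.0
    phase = rng.uniform(0.0, 2 * np.pi)
    wobble = c["fluency_wobble_deg"] * th["fluency"] * np.sin(2 * np.pi * 7 * t + phase)

    trace = offset + shift + amp * wave + wobble
    jitter = rng.normal(0.0, config.sigma_kin, N_CYCLE_SAMPLES - 1)
    trace = trace.copy()
    trace[:-1] += jitter
    trace[-1] = trace[0]  # exact gait-cycle periodicity
    return trace


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


def _draw_severities(rng: np.random.Generator, rho: float) -> dict[str, float]:
    k = len(SUBSCORES)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, method="cholesky")
    u = ndtr(z)  # standard normal CDF -> uniform marginals
    return {s: float(3.0 * u[i]) for i, s in enumerate(SUBSCORES)}


def _rater_panel(theta: float, sigma: float, rng: np.random.Generator) -> list[int]:
    recs = np.clip(np.round(theta + rng.normal(0.0, sigma, 5)), 0, 3)
    return [int(r) for r in recs]


def simulate_patient(
    patient_id: str,
    profile: SeverityProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Patient:
    """Simulate one patient's strides, aid flags and rater panels."""
    c = config.coupling
    th = {k: profile[k] / 3.0 for k in SUBSCORES}

    leg_length = float(np.clip(rng.normal(0.86, 0.04), 0.7, 1.05))
    body_height = float(np.clip(rng.normal(1.72, 0.08), 1.45, 2.0))

    # patient-level gait tempo/geometry
    stride_time = 1.05 + c["speed_stride_time_s"] * th["speed"] + rng.normal(0.0, 0.03)
    stride_length = max(
        1.30 - c["speed_stride_length_m"] * th["speed"] - 0.06 * th["leg"]
        + rng.normal(0.0, 0.04),
        0.30,
    )
    stance = 0.60 + c["stability_stance"] * th["stability"] + rng.normal(0.0, 0.01)
    stance_ipsi = float(np.clip(stance - 0.04 * th["leg"], 0.52, 0.78))
    stance_contra = float(np.clip(stance + 0.02 * th["leg"], 0.52, 0.78))
    step_width = max(0.09 + 0.06 * th["stability"] + rng.normal(0.0, 0.008), 0.03)
    contra_offset = 0.50 + c["leg_asymmetry"] * th["leg"] + rng.normal(0.0, 0.01)
    contra_offset = float(np.clip(contra_offset, 0.40, 0.62))

    cane = int(rng.random() < expit(c["aid_steepness"] * (profile["stability"] - c["cane_midpoint"])))
    afo = int(rng.random() < expit(c["aid_steepness"] * (profile["stability"] - c["afo_midpoint"])))

    n_strides = int(rng.integers(config.strides_per_patient[0],
                                 config.strides_per_patient[1] + 1))

    ipsi_strides: list[StrideRecord] = []
    contra_strides: list[StrideRecord] = []
    t0 = 0.0
    for j in range(n_strides):
        T = stride_time * (1.0 + rng.normal(0.0, 0.02))
        L = max(stride_length * (1.0 + rng.normal(0.0, 0.03)), 0.1)
        step_len_i = L * (0.5 - 0.05 * th["leg"] + rng.normal(0.0, 0.01))
        step_len_c = L - step_len_i

        fs_i = t0
        fo_i = fs_i + stance_ipsi * T
        nfs_i = fs_i + T
        fs_c = fs_i + contra_offset * T
        T_c = T * (1.0 + rng.normal(0.0, 0.01))
        fo_c = fs_c + stance_contra * T_c
        nfs_c = fs_c + T_c

        angles_i = {a: angle_template(a, "ipsi", profile, config, rng=rng) for a in ANGLES}
        angles_c = {a: angle_template(a, "contra", profile, config, rng=rng) for a in ANGLES}

        common = dict(patient_id=patient_id, leg_length_m=leg_length,
                      body_height_m=body_height, step_width_m=step_width)
        ipsi_strides.append(StrideRecord(
            side="ipsi", angles=angles_i, foot_strike_s=fs_i, foot_off_s=fo_i,
            next_foot_strike_s=nfs_i, stride_length_m=L, step_length_m=step_len_i,
            **common))
        contra_strides.append(StrideRecord(
            side="contra", angles=angles_c, foot_strike_s=fs_c, foot_off_s=fo_c,
            next_foot_strike_s=nfs_c, stride_length_m=L * (1.0 + rng.normal(0.0, 0.02)),
            step_length_m=step_len_c, **common))
        t0 = nfs_i

    panels = {s: _rater_panel(profile[s], config.sigma_rater, rng) for s in SUBSCORES}
    return Patient(patient_id=patient_id, profile=profile,
                   ipsi_strides=ipsi_strides, contra_strides=contra_strides,
                   rater_panels=panels, walking_cane=cane, afo=afo)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the full cohort deterministically from ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    patients: list[Patient] = []
    for i, child in enumerate(root.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        profile = SeverityProfile(
            severities=_draw_severities(rng, config.severity_correlation),
            affected_side="left" if rng.random() < 0.5 else "right",
        )
        patients.append(simulate_patient(f"P{i:03d}", profile, config, rng))
    return Cohort(config=config, patients=patients)


# --------------------------------------------------------------------------
# cohort directory I/O
# --------------------------------------------------------------------------

_EVENT_COLS = ["patient", "stride", "side", "foot_strike_s", "foot_off_s",
               "next_foot_strike_s", "stride_length_m", "step_length_m",
               "step_width_m", "leg_length_m", "body_height_m"]


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write cohort.json, events.csv and one CSV per stride into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": {**asdict(cohort.config),
                   "strides_per_patient": list(cohort.config.strides_per_patient)},
        "patients": [
            {
                "patient_id": p.patient_id,
                "affected_side": p.profile.affected_side,
                "severities": p.profile.severities,
                "rater_panels": p.rater_panels,
                "walking_cane": p.walking_cane,
                "afo": p.afo,
            }
            for p in cohort.patients
        ],
    }
    (out / "cohort.json").write_text(json.dumps(meta, indent=1))

    rows = []
    for p in cohort.patients:
        for side, strides in (("ipsi", p.ipsi_strides), ("contra", p.contra_strides)):
            for j, rec in enumerate(strides):
                rows.append({
                    "patient": p.patient_id, "stride": j, "side": side,
                    "foot_strike_s": rec.foot_strike_s, "foot_off_s": rec.foot_off_s,
                    "next_foot_strike_s": rec.next_foot_strike_s,
                    "stride_length_m": rec.stride_length_m,
                    "step_length_m": rec.step_length_m,
                    "step_width_m": rec.step_width_m,
                    "leg_length_m": rec.leg_length_m,
                    "body_height_m": rec.body_height_m,
                })
                df = pd.DataFrame({"percent_cycle": np.arange(N_CYCLE_SAMPLES)}
                                  | {a: rec.angles[a] for a in ANGLES})
                df.to_csv(out / f"patient{p.patient_id}_stride{j}_{side}.csv",
                          index=False, float_format="%.17g")
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(out / "events.csv", index=False,
                                                   float_format="%.17g")


def read_cohort(in_dir) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    meta = json.loads((src / "cohort.json").read_text())
    cfg_d = dict(meta["config"])
    cfg_d["strides_per_patient"] = tuple(cfg_d["strides_per_patient"])
    config = SimulationConfig(**cfg_d)
    events = pd.read_csv(src / "events.csv", float_precision="round_trip")

    patients: list[Patient] = []
    for pm in meta["patients"]:
        pid = pm["patient_id"]
        profile = SeverityProfile(severities=pm["severities"],
                                  affected_side=pm["affected_side"])
        strides: dict[str, list[StrideRecord]] = {"ipsi": [], "contra": []}
        sub = events[events["patient"] == pid]
        for _, row in sub.sort_values(["side", "stride"]).iterrows():
            side, j = row["side"], int(row["stride"])
            tr = pd.read_csv(src / f"patient{pid}_stride{j}_{side}.csv",
                             float_precision="round_trip")
            strides[side].append(StrideRecord(
                patient_id=pid, side=side,
                angles={a: tr[a].to_numpy() for a in ANGLES},
                foot_strike_s=row["foot_strike_s"], foot_off_s=row["foot_off_s"],
                next_foot_strike_s=row["next_foot_strike_s"],
                stride_length_m=row["stride_length_m"],
                step_length_m=row["step_length_m"],
                step_width_m=row["step_width_m"],
                leg_length_m=row["leg_length_m"],
                body_height_m=row["body_height_m"]))
        patients.append(Patient(
            patient_id=pid, profile=profile,
            ipsi_strides=strides["ipsi"], contra_strides=strides["contra"],
            rater_panels={k: [int(v) for v in vals] for k, vals in pm["rater_panels"].items()},
            walking_cane=int(pm["walking_cane"]), afo=int(pm["afo"])))
    return Cohort(config=config, patients=patients)
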