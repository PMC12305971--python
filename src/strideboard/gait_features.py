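"""Per-stride-pair feature extraction from normalized joint-angle trajectories.

Each stride contributes 339 features: 15 spatiotemporal gait parameters and
324 numerical characterizations of movement — for each of 18 joint angles,
the min/median/max of the angle and of its normalized angular velocity (NAV,
the derivative of the angle with respect to gait-cycle progress, in degrees
per % cycle) over the stance phase, the swing phase, and the whole cycle
(18 angles x 18 statistics).  A stride pair (ipsilateral + contralateral
stride) plus the two walking-aid flags therefore yields

    680 = 2 x (15 + 324) + 2

features in a fixed canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_CYCLE_SAMPLES = 101  # 0..100 % of the gait cycle

# 18 relative joint angles per body side.  The grouping (pelvis, thorax,
# foot, hip, knee, ankle, spine, shoulder, elbow) drives the per-subscore
# expert masks in feature_selection.
ANGLES: tuple[str, ...] = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "thorax_tilt",
    "thorax_side_tilt",
    "thorax_rotation",
    "foot_progression",
    "hip_flexion",
    "hip_adduction",
    "knee_flexion",
    "ankle_dorsiflexion",
    "ankle_inversion",
    "spine_tilt",
    "spine_side_tilt",
    "spine_rotation",
    "shoulder_flexion",
    "shoulder_adduction",
    "elbow_flexion",
)

ANGLE_GROUP: dict[str, str] = {a: a.split("_", 1)[0] for a in ANGLES}

SIDES = ("ipsi", "contra")
SIGNALS = ("angle", "nav")
WINDOWS = ("stance", "swing", "cycle")
STATS = ("min", "median", "max")

# 15 spatiotemporal gait parameters, computed per side.
GAIT_PARAMETERS: tuple[str, ...] = (
    "gait_speed",            # m/s
    "cadence",               # steps/s
    "stride_time",           # s
    "step_time",             # s
    "single_support_time",   # s
    "double_support_time",   # s
    "single_support_pct",    # % cycle
    "double_support_pct",    # % cycle
    "step_width_norm",       # step width / body height
    "step_length_norm",      # step length / leg length
    "stride_length_norm",    # stride length / leg length
    "limp_index",            # own-side stance time / other-side stance time
    "swing_start_pct",       # % cycle
    "stance_duration_pct",   # % cycle
    "swing_duration_pct",    # % cycle
)

AID_FLAGS = ("walking_cane", "afo")


@dataclass
class StrideRecord:
    """One stride of one side: 18 normalized angle traces plus events.

    Times are absolute seconds within the trial; traces are sampled on the
    normalized 0-100 % cycle grid (101 points).
    """

    patient_id: str
    side: str  # "ipsi" (affected) or "contra"
    angles: dict[str, np.ndarray]
    foot_strike_s: float
    foot_off_s: float
    next_foot_strike_s: float
    stride_length_m: float
    step_length_m: float
    step_width_m: float
    leg_length_m: float
    body_height_m: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        missing = [a for a in ANGLES if a not in self.angles]
        if missing:
            raise ValueError(f"stride record missing angle traces: {missing}")
        for name, tr in self.angles.items():
            tr = np.asarray(tr, dtype=float)
            if tr.shape != (N_CYCLE_SAMPLES,):
                raise ValueError(
                    f"trace {name!r} has shape {tr.shape}, expected ({N_CYCLE_SAMPLES},)"
                )
            self.angles[name] = tr
        if not (self.foot_strike_s < self.foot_off_s < self.next_foot_strike_s):
            raise ValueError("events must satisfy foot strike < foot off < next foot strike")

    @property
    def stride_time_s(self) -> float:
        return self.next_foot_strike_s - self.foot_strike_s

    @property
    def stance_time_s(self) -> float:
        return self.foot_off_s - self.foot_strike_s

    @property
    def stance_fraction(self) -> float:
        return self.stance_time_s / self.stride_time_s


@dataclass
class StridePair:
    """Consecutive ipsilateral + contralateral strides with walking-aid flags."""

    patient_id: str
    pair_index: int
    ipsi: StrideRecord
    contra: StrideRecord
    walking_cane: int = 0
    afo: int = 0
    labels: dict[str, int] = field(default_factory=dict)


def feature_names() -> list[str]:
    """Canonical ordered names of the 680 per-stride-pair features."""
    names: list[str] = []
    for side in SIDES:
        for p in GAIT_PARAMETERS:
            names.append(f"{p}_{side}")
    for side in SIDES:
        for angle in ANGLES:
            for signal in SIGNALS:
                for window in WINDOWS:
                    for stat in STATS:
                        names.append(f"{angle}_{signal}_{window}_{stat}_{side}")
    names.extend(AID_FLAGS)
    return names


FEATURE_NAMES: list[str] = feature_names()
assert len(FEATURE_NAMES) == 680 == 2 * 15 + 2 * 18 * 18 + 2


def feature_side(name: str) -> str | None:
    """Side annotation of a feature: 'ipsi', 'contra', or None for aid flags."""
    if name.endswith("_ipsi"):
        return "ipsi"
    if name.endswith("_contra"):
        return "contra"
    return None


def compute_nav(trace: np.ndarray) -> np.ndarray:
    """Normalized angular velocity: d(angle)/d(% cycle) on the 0-100 grid.

    Central differences at interior points, one-sided at the endpoints
    (second-order accurate; exact on linear traces).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape != (N_CYCLE_SAMPLES,):
        raise ValueError(f"expected a {N_CYCLE_SAMPLES}-sample trace, got {trace.shape}")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    return np.gradient(trace, 1.0)


def characterize_angle(trace: np.ndarray, stance_fraction: float) -> dict[str, float]:
    """The 18 descriptive statistics of one angle trace and its NAV.

    Min/median/max of the angle and the NAV over the stance window
    (0 % .. stance_fraction*100 %), the swing window (remainder), and the
    whole cycle.  The boundary sample at foot off belongs to both windows
    (closed windows).
    """
    if not (0.0 < stance_fraction < 1.0):
        raise ValueError(f"stance_fraction must be in (0,1), got {stance_fraction}")
    trace = np.asarray(trace, dtype=float)
    nav = compute_nav(trace)
    cut = int(round(stance_fraction * 100))
    cut = min(max(cut, 1), 99)
    windows = {
        "stance": slice(0, cut + 1),
        "swing": slice(cut, N_CYCLE_SAMPLES),
        "cycle": slice(0, N_CYCLE_SAMPLES),
    }
    out: dict[str, float] = {}
    for signal, values in (("angle", trace), ("nav", nav)):
        for window, sl in windows.items():
            seg = values[sl]
            out[f"{signal}_{window}_min"] = float(np.min(seg))
            out[f"{signal}_{window}_median"] = float(np.median(seg))
            out[f"{signal}_{window}_max"] = float(np.max(seg))
    return out


def _support_times(own: StrideRecord, other: StrideRecord) -> tuple[float, float]:
    """(single, double) support time of ``own``'s cycle, in seconds.

    Single support of a side is the other side's swing time; total double
    support uses the periodic-gait identity stance_own + stance_other -
    stride_time (clamped at zero).
    """
    single = other.next_foot_strike_s - other.foot_off_s
    double = max(own.stance_time_s + other.stance_time_s - own.stride_time_s, 0.0)
    return single, double


def compute_gait_parameters(ipsi: StrideRecord, contra: StrideRecord) -> dict[str, dict[str, float]]:
    """The 15 spatiotemporal gait parameters for each side of a stride pair.

    Step time of a side is the interval ending at that side's foot strike and
    starting at the preceding foot strike of the other side; the limp index
    of a side is its stance time divided by the other side's stance time, so
    a value of 1 indicates temporally symmetric gait.
    """
    for rec in (ipsi, contra):
        if rec.stride_time_s <= 0:
            raise ValueError("zero or negative stride time")
        if rec.body_height_m <= 0 or rec.leg_length_m <= 0:
            raise ValueError("body height and leg length must be positive")

    step_time = {
        # contra foot strike happens inside the ipsi stride
        "ipsi": ipsi.next_foot_strike_s - contra.foot_strike_s,
        "contra": contra.foot_strike_s - ipsi.foot_strike_s,
    }
    out: dict[str, dict[str, float]] = {}
    for side, own, other in (("ipsi", ipsi, contra), ("contra", contra, ipsi)):
        t_stride = own.stride_time_s
        single, double = _support_times(own, other)
        stance_pct = 100.0 * own.stance_fraction
        out[side] = {
            "gait_speed": own.stride_length_m / t_stride,
            "cadence": 2.0 / t_stride,
            "stride_time": t_stride,
            "step_time": step_time[side],
            "single_support_time": single,
            "double_support_time": double,
            "single_support_pct": 100.0 * single / t_stride,
            "double_support_pct": 100.0 * double / t_stride,
            "step_width_norm": own.step_width_m / own.body_height_m,
            "step_length_norm": own.step_length_m / own.leg_length_m,
            "stride_length_norm": own.stride_length_m / own.leg_length_m,
            "limp_index": own.stance_time_s / other.stance_time_s,
            "swing_start_pct": stance_pct,
            "stance_duration_pct": stance_pct,
            "swing_duration_pct": 100.0 - stance_pct,
        }
    return out


def extract_feature_vector(pair: StridePair) -> pd.Series:
    """The 680-entry named feature vector of one stride pair.

    Ordering: 30 gait parameters (15 per side), then 648 numerical
    characterizations (18 angles x 18 statistics x 2 sides), then the two
    walking-aid flags.
    """
    params = compute_gait_parameters(pair.ipsi, pair.contra)
    values: dict[str, float] = {}
    for side in SIDES:
        for p in GAIT_PARAMETERS:
            values[f"{p}_{side}"] = params[side][p]
    for side, rec in (("ipsi", pair.ipsi), ("contra", pair.contra)):
        sf = rec.stance_fraction
        for angle in ANGLES:
            if angle not in rec.angles:
                raise ValueError(f"missing angle trace {angle!r} on {side} stride")
            stats = characterize_angle(rec.angles[angle], sf)
            for key, val in stats.items():
                signal, window, stat = key.split("_")
                values[f"{angle}_{signal}_{window}_{stat}_{side}"] = val
    values["walking_cane"] = float(pair.walking_cane)
    values["afo"] = float(pair.afo)
    vec = pd.Series(values).reindex(FEATURE_NAMES)
    if vec.isna().any():
        raise ValueError("feature vector incomplete")
    return vec


META_COLUMNS = ["patient_id", "pair_index"]


def pairs_to_feature_table(pairs: list[StridePair]) -> pd.DataFrame:
    """Feature table: one row per stride pair, metadata + labels + 680 features."""
    rows = []
    for pair in pairs:
        row = {"patient_id": pair.patient_id, "pair_index": pair.pair_index}
        row.update(pair.labels)
        row.update(extract_feature_vector(pair).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
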