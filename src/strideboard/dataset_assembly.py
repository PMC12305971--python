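"""Stride-pair assembly, patient-grouped stratified splitting, sample weights.

Models are trained at stride-pair level (to use every measured stride) while
labels live at patient level, which creates two biases the weighting formula
corrects: imbalanced subscore classes and an inhomogeneous number of stride
pairs per patient.  The weight of pair i with label s(i) from patient p(i) is

    w_i = (max_s N_s / N_{s(i)}) / M_{p(i)}

with N_s the number of training pairs labelled s and M_p the number of
training pairs of patient p.  Within each label class the weights then sum
to max_s N_s / (number of patients' shares), and total weighted mass is equal
across non-empty classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expert_board import SUBSCORES, board_subscore
from .gait_features import StridePair, pairs_to_feature_table
from .synthetic_cohort import Cohort, Patient

logger = logging.getLogger(__name__)

LABEL_COLUMNS = list(SUBSCORES) + ["sms"]


def patient_board_labels(patient: Patient) -> dict[str, int]:
    """Board subscores and SMS of one patient from its five-rater panels."""
    labels = {s: board_subscore(patient.rater_panels[s]) for s in SUBSCORES}
    labels["sms"] = sum(labels.values())
    return labels


def build_stride_pairs(cohort: Cohort) -> list[StridePair]:
    """Couple each ipsilateral stride with the contralateral stride starting
    within it, and attach the patient's board labels and aid flags.

    Patients without any valid pair are excluded with a warning.
    """
    pairs: list[StridePair] = []
    for patient in cohort.patients:
        labels = patient_board_labels(patient)
        n_before = len(pairs)
        used_contra: set[int] = set()
        k = 0
        for ipsi in patient.ipsi_strides:
            match = None
            for idx, contra in enumerate(patient.contra_strides):
                if idx in used_contra:
                    continue
                if ipsi.foot_strike_s <= contra.foot_strike_s < ipsi.next_foot_strike_s:
                    match = idx
                    break
            if match is None:
                continue
            used_contra.add(match)
            pairs.append(StridePair(
                patient_id=patient.patient_id, pair_index=k,
                ipsi=ipsi, contra=patient.contra_strides[match],
                walking_cane=patient.walking_cane, afo=patient.afo,
                labels=dict(labels)))
            k += 1
        if len(pairs) == n_before:
            logger.warning("patient %s has no valid stride pair; excluded",
                           patient.patient_id)
    return pairs


def assemble_feature_table(cohort: Cohort) -> pd.DataFrame:
    """Feature table with patient ids, board labels and the 680 features."""
    return pairs_to_feature_table(build_stride_pairs(cohort))


def stratified_patient_split(
    table: pd.DataFrame,
    test_fraction: float = 0.30,
    seed: int = 0,
    stratify_by: str = "sms",
) -> pd.Series:
    """Assign each stride pair to 'train' or 'test' at patient level.

    Patients are stratified by their SMS; within each stratum the number of
    test patients follows a largest-remainder allocation of the overall test
    fraction (single-patient strata go to training), so all of one patient's
    pairs land in exactly one partition.  Deterministic for a fixed seed.

    Returns a Series aligned with ``table`` holding 'train'/'test'.
    """
    if table.empty:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    per_patient = table.groupby("patient_id")[stratify_by].first()

    test_patients: set[str] = set()
    quotas: list[tuple[float, str]] = []  # (remainder, stratum)
    chosen: dict[str, list[str]] = {}
    for stratum, members in per_patient.groupby(per_patient):
        ids = sorted(members.index)
        if len(ids) < 2:
            continue  # lone patient: keep in training
        quota = test_fraction * len(ids)
        n_take = int(np.floor(quota))
        order = list(rng.permutation(ids))
        chosen[stratum] = order
        test_patients.update(order[:n_take])
        quotas.append((quota - n_take, stratum))

    # largest-remainder top-up toward the overall test fraction
    target = int(round(test_fraction * per_patient.size))
    quotas.sort(key=lambda q: (-q[0], str(q[1])))
    for _, stratum in quotas:
        if len(test_patients) >= target:
            break
        order = chosen[stratum]
        n_already = sum(1 for pid in order if pid in test_patients)
        if n_already < len(order) - 1:  # never empty a stratum's training side
            test_patients.add(order[n_already])

    return table["patient_id"].map(
        lambda pid: "test" if pid in test_patients else "train"
    ).rename("split")


def compute_weights(table: pd.DataFrame, target: str) -> pd.Series:
    """Bias-correcting weight per stride pair for one target subscore.

    w_i = (max_s N_s / N_{s(i)}) / M_{p(i)} with N_s the pair count of label
    class s and M_p the pair count of patient p, computed over ``table``
    (normally the training partition).
    """
    labels = table[target]
    class_counts = labels.value_counts()
    patient_counts = table["patient_id"].value_counts()
    n_max = class_counts.max()
    w = (n_max / labels.map(class_counts)) / table["patient_id"].map(patient_counts)
    return w.astype(float).rename(f"weight_{target}")


def add_split_and_weights(
    table: pd.DataFrame,
    test_fraction: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a copy of the table with a split column and per-target weights
    (weights computed on the training partition; test rows get weight 1)."""
    out = table.copy()
    out["split"] = stratified_patient_split(out, test_fraction, seed)
    train = out[out["split"] == "train"]
    for target in LABEL_COLUMNS:
        col = f"weight_{target}"
        out[col] = 1.0
        out.loc[train.index, col] = compute_weights(train, target)
    return out
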