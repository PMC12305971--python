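"""Patient-level testing: clipped mean predictions, SMS composition, R^2, ICC(1,1).

The board assesses patients, not strides, so model outputs are averaged over
each test patient's stride pairs and cut to the subscore range [0, 3]; the
SMS prediction is the sum of the six range-adjusted subscore predictions
(hence in [0, 18]).  Agreement with the board is summarized by the
coefficient of determination R^2 over test patients, and the board's own
consistency by the one-way random-effects single-rater intraclass
correlation ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW) over the five-rater
panels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .expert_board import SUBSCORES

SUBSCORE_RANGE = (0.0, 3.0)
SMS_RANGE = (0.0, 18.0)


def clip_subscore(x: float) -> float:
    return float(min(max(x, SUBSCORE_RANGE[0]), SUBSCORE_RANGE[1]))


def predict_patient(model, patient_table: pd.DataFrame) -> float:
    """Patient-level subscore: mean over the patient's stride-pair outputs,
    cut to the nearest boundary of [0, 3]."""
    if patient_table.empty:
        raise ValueError("patient has no test stride pairs")
    return clip_subscore(float(np.mean(model.predict(patient_table))))


def predict_sms(subscore_predictions: dict[str, float]) -> float:
    """SMS prediction: sum of the six range-adjusted subscore predictions."""
    missing = [s for s in SUBSCORES if s not in subscore_predictions]
    if missing:
        raise ValueError(f"missing subscore predictions: {missing}")
    total = sum(clip_subscore(subscore_predictions[s]) for s in SUBSCORES)
    return float(min(max(total, SMS_RANGE[0]), SMS_RANGE[1]))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot, unweighted.

    Returns NaN (with a warning) when the observed values have no variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("R^2 undefined: observed values have zero variance")
        return float("nan")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def icc_1_1(ratings: np.ndarray) -> float:
    """One-way random-effects single-rater ICC over a patients x raters matrix.

    ICC(1,1) = (MSB - MSW) / (MSB + (k-1) MSW) with MSB/MSW the between- and
    within-patient mean squares and k the number of raters.
    """
    ratings = np.asarray(ratings, dtype=float)
    n, k = ratings.shape
    if n < 2:
        raise ValueError("need ratings of at least two patients")
    if k < 2:
        raise ValueError("need at least two raters")
    row_means = ratings.mean(axis=1)
    grand = ratings.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((ratings - row_means[:, None]) ** 2) / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


def panel_icc(cohort_panels: dict[str, dict[str, list[int]]]) -> dict[str, float]:
    """ICC(1,1) per subscore and for the rater-level SMS sums.

    ``cohort_panels`` maps patient id -> subscore -> five recommendations
    (rater identity is positional).
    """
    patients = sorted(cohort_panels)
    out: dict[str, float] = {}
    for s in SUBSCORES:
        mat = np.array([cohort_panels[p][s] for p in patients], dtype=float)
        out[s] = icc_1_1(mat)
    sms_mat = np.array(
        [[sum(cohort_panels[p][s][r] for s in SUBSCORES) for r in range(5)]
         for p in patients], dtype=float)
    out["sms"] = icc_1_1(sms_mat)
    return out


def evaluate_models(
    models: dict[str, object],
    test_table: pd.DataFrame,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Patient-level test R^2 per subscore and for the composed SMS.

    ``models`` maps subscore -> TrainedScoreModel (one family).  Returns the
    R^2 dict (keys: six subscores + 'sms') and the per-patient scatter table
    (patient, target, board value, prediction).
    """
    rows = []
    compose_sms = all(s in models for s in SUBSCORES)
    per_patient: dict[str, dict[str, float]] = {}
    board: dict[str, dict[str, float]] = {}
    for pid, sub in test_table.groupby("patient_id"):
        per_patient[pid] = {}
        board[pid] = {s: float(sub[s].iloc[0]) for s in models}
        board[pid]["sms"] = float(sub["sms"].iloc[0])
        for s, model in models.items():
            per_patient[pid][s] = predict_patient(model, sub)
        if compose_sms:
            per_patient[pid]["sms"] = predict_sms(per_patient[pid])

    r2: dict[str, float] = {}
    targets = list(models) + (["sms"] if compose_sms else [])
    pids = sorted(per_patient)
    for t in targets:
        obs = [board[p][t] for p in pids]
        pred = [per_patient[p][t] for p in pids]
        r2[t] = r_squared(obs, pred)
        rows.extend({"patient_id": p, "target": t, "board": o, "prediction": q}
                    for p, o, q in zip(pids, obs, pred))
    return r2, pd.DataFrame(rows)
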