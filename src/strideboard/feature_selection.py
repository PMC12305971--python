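"""Two-step per-subscore feature selection.

Step 1 applies expert knowledge: each subscore sees only the feature families
that its functional definition can plausibly depend on (e.g. the arm-movement
subscore sees trunk/spine/shoulder/elbow characterizations plus gait speed,
cadence and the aid flags).  Step 2 filters the remaining features with an
Alexander-Govern (AG) heteroscedastic one-way test of equal group means,
computed on one representative stride pair per training patient (grouped by
the board subscore), retaining features with p < alpha.

The AG test replaces ANOVA's pooled-variance assumption with per-group
standard errors: with group means m_j, standard errors se_j and weights
w_j proportional to 1/se_j^2 (normalized to sum 1), the variance-weighted
grand mean is m+ = sum_j w_j m_j, each group contributes
t_j = (m_j - m+)/se_j, and Hill's normalizing transformation turns each t_j
into an approximately standard-normal z_j; A = sum_j z_j^2 is referred to a
chi-square distribution with k-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expert_board import SUBSCORES
from .gait_features import (
    AID_FLAGS,
    ANGLE_GROUP,
    ANGLES,
    FEATURE_NAMES,
    GAIT_PARAMETERS,
    SIDES,
)

logger = logging.getLogger(__name__)

# Feature families visible to each subscore (step 1).  trunk/fluency/stability
# keep the full feature set.
_LEG_ANGLE_GROUPS = {"pelvis", "foot", "hip", "knee", "ankle"}
_ARM_ANGLE_GROUPS = {"thorax", "spine", "shoulder", "elbow"}


@dataclass(frozen=True)
class FeatureMask:
    """Ordered subset of the canonical 680 feature names for one subscore."""

    target: str
    features: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class AGTestResult:
    feature: str
    group_means: dict[int, float]
    statistic: float
    df: int
    p_value: float


def _characterization_names(groups: set[str]) -> list[str]:
    keep_angles = {a for a in ANGLES if ANGLE_GROUP[a] in groups}
    return [
        n for n in FEATURE_NAMES
        if n.rsplit("_", 4)[0] in keep_angles and n not in AID_FLAGS
        and not any(n == f"{p}_{s}" for p in GAIT_PARAMETERS for s in SIDES)
    ]


def step1_mask(target: str) -> FeatureMask:
    """The expert-knowledge mask for one subscore, in canonical order.

    trunk / fluency / stability -> all 680 features; speed -> the 30 gait
    parameters + aid flags (32); leg -> gait parameters + leg-chain angle
    characterizations + aid flags (356); arm -> gait speed & cadence + axial
    and arm angle characterizations + aid flags (330).
    """
    if target not in SUBSCORES:
        raise ValueError(f"unknown target subscore {target!r}")
    if target in ("trunk", "fluency", "stability"):
        keep = list(FEATURE_NAMES)
    elif target == "speed":
        keep = [f"{p}_{s}" for s in SIDES for p in GAIT_PARAMETERS] + list(AID_FLAGS)
    elif target == "leg":
        keep = ([f"{p}_{s}" for s in SIDES for p in GAIT_PARAMETERS]
                + _characterization_names(_LEG_ANGLE_GROUPS) + list(AID_FLAGS))
    else:  # arm
        keep = ([f"{p}_{s}" for s in SIDES for p in ("gait_speed", "cadence")]
                + _characterization_names(_ARM_ANGLE_GROUPS) + list(AID_FLAGS))
    ordered = tuple(n for n in FEATURE_NAMES if n in set(keep))
    return FeatureMask(target=target, features=ordered)


def select_representative_pair(
    patient_table: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    scale: pd.Series | None = None,
) -> int:
    """Index (into ``patient_table``) of the patient's most typical pair.

    The representative stride pair minimizes the Euclidean distance, in
    z-score space (``scale`` = training-set standard deviations), to the
    patient's component-wise median feature vector; ties break to the lowest
    pair index.
    """
    X = patient_table.loc[:, list(features)].to_numpy(dtype=float)
    if len(X) == 1:
        return 0
    if scale is None:
        scale_v = np.ones(X.shape[1])
    else:
        scale_v = scale.reindex(list(features)).to_numpy(dtype=float)
    scale_v = np.where(scale_v > 0, scale_v, 1.0)
    Z = X / scale_v
    med = np.median(Z, axis=0)
    d = np.linalg.norm(Z - med, axis=1)
    return int(np.argmin(d))  # argmin takes the first minimum: lowest index


def representative_pairs(
    train_table: pd.DataFrame,
    features: list[str] | tuple[str, ...],
) -> pd.Index:
    """Row index of one representative stride pair per training patient."""
    scale = train_table.loc[:, list(features)].std(ddof=0)
    idx = []
    for _, sub in train_table.groupby("patient_id", sort=True):
        pos = select_representative_pair(sub, features, scale)
        idx.append(sub.index[pos])
    return pd.Index(idx)


def alexander_govern(groups: list[np.ndarray], feature: str = "") -> AGTestResult:
    """Alexander-Govern test of equal means across >= 2 heteroscedastic groups.

    Raises ValueError on degenerate groups (n < 2 or zero variance).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
        if np.var(g) == 0:
            raise ValueError("zero-variance group")

    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    se = np.array([g.std(ddof=1) / np.sqrt(len(g)) for g in groups])
    w = (1.0 / se**2) / np.sum(1.0 / se**2)
    grand = float(np.sum(w * means))
    t = (means - grand) / se

    # Hill's normalizing transformation of each t_j (nu_j = n_j - 1 df)
    nu = n - 1.0
    a = nu - 0.5
    b = 48.0 * a**2
    c = np.sqrt(a * np.log1p(t**2 / nu))
    z = (c + (c**3 + 3.0 * c) / b
         - (4.0 * c**7 + 33.0 * c**5 + 240.0 * c**3 + 855.0 * c)
         / (10.0 * b**2 + 8.0 * b * c**4 + 1000.0 * b))
    z = np.sign(t) * z
    A = float(np.sum(z**2))
    df = len(groups) - 1
    p = float(stats.chi2.sf(A, df))
    return AGTestResult(feature=feature,
                        group_means={i: float(m) for i, m in enumerate(means)},
                        statistic=A, df=df, p_value=p)


def ag_screen(
    table: pd.DataFrame,
    features: list[str] | tuple[str, ...],
    labels: pd.Series,
) -> pd.DataFrame:
    """AG test per feature, grouping rows of ``table`` by ``labels``.

    Label levels represented by fewer than two rows cannot form a test group
    and are dropped from the grouping (logged once).  Features with zero
    variance in a remaining group are flagged (p = NaN) and logged rather
    than tested.
    """
    rows = []
    counts = labels.value_counts()
    level_values = sorted(counts[counts >= 2].index)
    dropped = sorted(counts[counts < 2].index)
    if dropped:
        logger.warning("label levels %s have fewer than two representative "
                       "pairs; dropped from AG grouping", dropped)
    if len(level_values) < 2:
        logger.warning("fewer than two usable label groups; AG screen skipped")
        return pd.DataFrame([{"feature": f, "statistic": np.nan,
                              "df": 0, "p_value": np.nan} for f in features])
    for feat in features:
        col = table[feat].to_numpy(dtype=float)
        groups = [col[(labels == lv).to_numpy()] for lv in level_values]
        try:
            res = alexander_govern(groups, feature=feat)
            rows.append({"feature": feat, "statistic": res.statistic,
                         "df": res.df, "p_value": res.p_value})
        except ValueError as exc:
            logger.warning("feature %s excluded from AG testing: %s", feat, exc)
            rows.append({"feature": feat, "statistic": np.nan,
                         "df": len(groups) - 1, "p_value": np.nan})
    return pd.DataFrame(rows)


def step2_filter(
    mask: FeatureMask,
    rep_table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
) -> tuple[FeatureMask, pd.DataFrame]:
    """Retain mask features whose AG p-value over representative pairs < alpha.

    Returns the reduced mask and the per-feature AG report.  If fewer than
    two label groups are present, selection is skipped and the mask returned
    unchanged.
    """
    usable = (labels.value_counts() >= 2).sum()
    if usable < 2:
        logger.warning("fewer than two usable label groups for %s; step-2 "
                       "filter skipped", mask.target)
        return mask, pd.DataFrame(columns=["feature", "statistic", "df", "p_value"])
    report = ag_screen(rep_table, mask.features, labels)
    keep = set(report.loc[report["p_value"] < alpha, "feature"])
    reduced = FeatureMask(target=mask.target,
                          features=tuple(f for f in mask.features if f in keep))
    return reduced, report


def select_features(
    train_table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
) -> tuple[FeatureMask, pd.Index, pd.DataFrame]:
    """Full two-step selection for one subscore on the training table.

    Returns (reduced mask, representative-pair row index, AG report).
    """
    mask = step1_mask(target)
    rep_idx = representative_pairs(train_table, mask.features)
    rep_table = train_table.loc[rep_idx]
    labels = rep_table[target]
    reduced, report = step2_filter(mask, rep_table, labels, alpha)
    return reduced, rep_idx, report
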