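"""Expert masks, representative-pair rule, and the Alexander-Govern filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strideboard.feature_selection import (
    ag_screen,
    alexander_govern,
    representative_pairs,
    select_features,
    select_representative_pair,
    step1_mask,
    step2_filter,
)
from strideboard.gait_features import AID_FLAGS, FEATURE_NAMES


class TestStep1Masks:
    @pytest.mark.parametrize("target, expected", [
        ("trunk", 680), ("leg", 356), ("arm", 330),
        ("speed", 32), ("fluency", 680), ("stability", 680),
    ])
    def test_mask_sizes_exact(self, target, expected):
        assert len(step1_mask(target)) == expected

    def test_masks_are_canonical_subsets(self):
        for target in ("trunk", "leg", "arm", "speed", "fluency", "stability"):
            feats = step1_mask(target).features
            assert set(feats) <= set(FEATURE_NAMES)
            order = {n: i for i, n in enumerate(FEATURE_NAMES)}
            assert list(feats) == sorted(feats, key=order.get)

    def test_content_by_functional_definition(self):
        leg = set(step1_mask("leg").features)
        arm = set(step1_mask("arm").features)
        speed = set(step1_mask("speed").features)
        assert "knee_flexion_nav_swing_max_ipsi" in leg
        assert "shoulder_flexion_angle_cycle_max_ipsi" not in leg
        assert "shoulder_flexion_angle_cycle_max_ipsi" in arm
        assert "knee_flexion_nav_swing_max_ipsi" not in arm
        assert {"gait_speed_ipsi", "cadence_contra"} <= arm
        assert "stride_time_ipsi" not in arm
        assert all(f in speed for f in AID_FLAGS)
        assert not any("_angle_" in f or "_nav_" in f for f in speed)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            step1_mask("sms")


class TestRepresentativePair:
    def test_single_pair_returns_itself(self):
        df = pd.DataFrame({"x": [3.0]})
        assert select_representative_pair(df, ["x"]) == 0

    def test_identical_pairs_tie_to_lowest_index(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        assert select_representative_pair(df, ["x"]) == 0

    def test_closest_to_componentwise_median(self):
        """1-D pairs at {0, 0.1, 5}: the median is 0.1, chosen by brute-force
        distance scan."""
        df = pd.DataFrame({"x": [0.0, 0.1, 5.0]})
        assert select_representative_pair(df, ["x"]) == 1

    def test_one_representative_per_training_patient(self, small_table):
        train = small_table[small_table["split"] == "train"]
        rep = representative_pairs(train, step1_mask("speed").features)
        assert len(rep) == train["patient_id"].nunique()
        assert train.loc[rep, "patient_id"].is_unique


class TestAlexanderGovern:
    def test_identical_groups_give_null_result(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = alexander_govern([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_separated_groups_are_detected(self):
        rng = np.random.default_rng(0)
        res = alexander_govern([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        assert res.p_value < 1e-3

    def test_matches_reference_implementation(self):
        """100 random instances agree with scipy's implementation to >= 6
        decimals in both the statistic and the p-value."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            groups = [rng.normal(rng.normal(0, 2), rng.uniform(0.5, 3),
                                 int(rng.integers(3, 30))) for _ in range(k)]
            mine = alexander_govern(groups)
            ref = stats.alexandergovern(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_type_one_error_controlled_under_heteroscedastic_null(self):
        """Equal means, unequal variances and sizes: rejection rate at
        alpha = 0.05 stays within [0.03, 0.07] over 1000 replicates."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            groups = [rng.normal(0, 1, 10), rng.normal(0, 2, 15), rng.normal(0, 4, 20)]
            rejections += alexander_govern(groups).p_value < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            alexander_govern([np.array([1.0]), np.array([1.0, 2.0, 3.0])])
        with pytest.raises(ValueError):
            alexander_govern([np.zeros(5), np.array([1.0, 2.0, 3.0])])


class TestStep2Filter:
    @staticmethod
    def _rep_table(n_per_group=8, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1, 2, 3], n_per_group)
        df = pd.DataFrame({
            "constant_feature": 1.0 + rng.normal(0, 1e-12, len(labels)),
            "separator": labels + rng.normal(0, 0.01, len(labels)),
            "noise": rng.normal(0, 1, len(labels)),
        })
        return df, pd.Series(labels)

    def test_separator_retained_constant_removed(self):
        from strideboard.feature_selection import FeatureMask

        df, labels = self._rep_table()
        df["constant_feature"] = 1.0  # exactly constant: degenerate, excluded
        mask = FeatureMask(target="leg",
                           features=("constant_feature", "separator", "noise"))
        reduced, report = step2_filter(mask, df, labels)
        assert "separator" in reduced.features
        assert "constant_feature" not in reduced.features
        assert report.set_index("feature").loc["separator", "p_value"] < 0.05

    def test_filter_is_idempotent(self):
        from strideboard.feature_selection import FeatureMask

        df, labels = self._rep_table()
        mask = FeatureMask(target="leg", features=tuple(df.columns))
        once, _ = step2_filter(mask, df, labels)
        twice, _ = step2_filter(once, df, labels)
        assert once.features == twice.features

    def test_single_group_skips_with_warning(self, caplog):
        from strideboard.feature_selection import FeatureMask

        df, _ = self._rep_table()
        labels = pd.Series(np.zeros(len(df), dtype=int))
        mask = FeatureMask(target="leg", features=tuple(df.columns))
        with caplog.at_level("WARNING"):
            reduced, _ = step2_filter(mask, df, labels)
        assert reduced.features == mask.features
        assert "skipped" in caplog.text

    def test_leg_selection_enriched_for_leg_chain_features(self, small_table):
        """The generator couples theta_leg into knee/hip kinematics and the
        limp; the retained leg set should be enriched for knee features
        beyond chance (hypergeometric tail)."""
        train = small_table[small_table["split"] == "train"]
        mask, _, _ = select_features(train, "leg")
        pool = step1_mask("leg").features
        knee_pool = [f for f in pool if f.startswith("knee_")]
        knee_kept = [f for f in mask.features if f.startswith("knee_")]
        p = stats.hypergeom.sf(len(knee_kept) - 1, len(pool), len(knee_pool),
                               len(mask.features))
        assert p < 0.05
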