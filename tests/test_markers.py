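import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progdx import (
    CohortProfile,
    bh_fdr,
    kruskal_wallis,
    mcc,
    mcc_panel_select,
    mrmr_rank,
    progressive_filter,
    wilcoxon_rank_sum,
)
from progdx.markers import SpeciesPanelParams, _discretize_tertiles, wilcoxon_prefilter

from oracles import bh_step_up, greedy_mrmr, kruskal_h, rank_sum_exact_p


class TestWilcoxon:
    def test_exact_small_case(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_distributions_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2], [1, 2])
        assert p == pytest.approx(1.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_permutation_oracle_exact_regime(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 6))
            pooled = rng.permutation(rng.normal(size=n1 + n2))  # tie-free
            x, y = pooled[:n1], pooled[n1:]
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(rank_sum_exact_p(x, y), abs=1e-9)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert h == 0.0 and p == 1.0

    def test_hand_value(self):
        h, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7, abs=1e-12)

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=5), rng.normal(size=4), rng.normal(size=6)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            sizes = rng.integers(2, 4, size=3)
            groups = [rng.integers(0, 5, size=s).astype(float) for s in sizes]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_h(groups), abs=1e-9)


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.random(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), bh_step_up(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_q_in_unit_interval(self, pvals):
        q = bh_fdr(pvals)
        assert ((q >= 0) & (q <= 1 + 1e-12)).all()


def _profile_from_medians(medians_by_group, cohort_id, n_per_group=30, jitter=0.05, seed=0):
    """Three-group cohort whose target feature has the given group medians.

    Group values are tightly jittered around each median so the KW q-value
    is far below 0.05; a filler feature absorbs the remaining mass.
    """
    rng = np.random.default_rng(seed)
    rows, stages = [], []
    stage_of = {"NC": "NC", "AA": "AA_LGD", "CRC": "CRC_I_II"}
    for group, med in medians_by_group.items():
        for _ in range(n_per_group):
            v = med * (1 + jitter * rng.uniform(-1, 1))
            rows.append([v, 1 - v])
            stages.append(stage_of[group])
    sample_ids = [f"{cohort_id}_s{i}" for i in range(len(rows))]
    profile = CohortProfile(
        pd.DataFrame(rows, index=sample_ids, columns=["target", "filler"]), cohort_id=cohort_id
    )
    metadata = pd.DataFrame({"sample_id": sample_ids, "stage": stages, "cohort": cohort_id})
    return profile, metadata


class TestProgressiveFilter:
    def test_planted_up_marker_retained(self):
        c1 = _profile_from_medians({"NC": 0.001, "AA": 0.002, "CRC": 0.004}, "c1", seed=1)
        c2 = _profile_from_medians({"NC": 0.001, "AA": 0.002, "CRC": 0.004}, "c2", seed=2)
        result = progressive_filter(c1, c2)
        assert result.markers.get("target") == "up"

    def test_insufficient_first_fold_rejected(self):
        c1 = _profile_from_medians({"NC": 0.001, "AA": 0.0012, "CRC": 0.01}, "c1", seed=1)
        c2 = _profile_from_medians({"NC": 0.001, "AA": 0.0012, "CRC": 0.01}, "c2", seed=2)
        result = progressive_filter(c1, c2)
        assert "target" not in result.markers

    def test_direction_conflict_rejected(self):
        c1 = _profile_from_medians({"NC": 0.001, "AA": 0.002, "CRC": 0.004}, "c1", seed=1)
        c2 = _profile_from_medians({"NC": 0.004, "AA": 0.002, "CRC": 0.001}, "c2", seed=2)
        result = progressive_filter(c1, c2)
        assert "target" not in result.markers

    def test_missing_stage_group_rejected(self):
        c1 = _profile_from_medians({"NC": 0.001, "AA": 0.002, "CRC": 0.004}, "c1")
        profile2, metadata2 = _profile_from_medians({"NC": 0.001, "AA": 0.002, "CRC": 0.004}, "c2")
        metadata2 = metadata2[metadata2["stage"] != "CRC_I_II"]
        profile2 = CohortProfile(profile2.data.loc[metadata2["sample_id"]], cohort_id="c2")
        with pytest.raises(ValueError, match="CRC"):
            progressive_filter(c1, (profile2, metadata2))

    def test_threshold_monotonicity(self, strong_study):
        """Stricter thresholds can only shrink the marker set."""
        _, (c1, c2, _) = strong_study
        base = set(progressive_filter(c1, c2).markers)
        stricter_fold = set(progressive_filter(c1, c2, fold_threshold=2.5).markers)
        stricter_fdr = set(progressive_filter(c1, c2, fdr_threshold=0.001).markers)
        assert stricter_fold <= base
        assert stricter_fdr <= base


def _two_class_profile(features: dict[str, np.ndarray], cohort_id="c"):
    n = len(next(iter(features.values())))
    arr = np.column_stack(list(features.values()))
    arr = arr / max(1.0, arr.sum(axis=1).max() + 1e-9)  # keep rows <= 1
    data = pd.DataFrame(arr, index=[f"s{i}" for i in range(n)], columns=list(features))
    return CohortProfile(data, cohort_id=cohort_id)


class TestMrmr:
    def test_perfect_separator_ranked_first(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1], 15)
        profile = _two_class_profile(
            {
                "noise1": rng.random(30) * 0.1,
                "signal": labels * 0.2 + 0.05,
                "noise2": rng.random(30) * 0.1,
            }
        )
        assert mrmr_rank(profile, labels, 3)[0] == "signal"

    def test_duplicate_demoted_matches_oracle(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 20)
        strong = labels * 0.2 + 0.02 + rng.random(40) * 0.01
        weak = labels * 0.05 + 0.02 + rng.random(40) * 0.04
        features = {
            "strong": strong,
            "strong_copy": strong.copy(),
            "weak_independent": weak,
            "noise": rng.random(40) * 0.1,
        }
        profile = _two_class_profile(features)
        ranked = mrmr_rank(profile, labels, 4)
        disc = np.column_stack([_discretize_tertiles(profile.values[:, j]) for j in range(4)])
        expected = [profile.feature_ids[j] for j in greedy_mrmr(disc, labels, 4)]
        assert ranked == expected
        assert ranked.index("weak_independent") < ranked.index("strong_copy")

    def test_matches_exhaustive_greedy_small(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            n_feat = 8
            labels = rng.integers(0, 2, size=30)
            if len(np.unique(labels)) < 2:
                continue
            arr = rng.random((30, n_feat)) * 0.1
            profile = _two_class_profile({f"f{j}": arr[:, j] for j in range(n_feat)})
            disc = np.column_stack(
                [_discretize_tertiles(profile.values[:, j]) for j in range(n_feat)]
            )
            expected = [profile.feature_ids[j] for j in greedy_mrmr(disc, labels, n_feat)]
            assert mrmr_rank(profile, labels, n_feat) == expected

    def test_top_k_too_large_rejected(self):
        profile = _two_class_profile({"a": np.ones(4) * 0.1})
        with pytest.raises(ValueError):
            mrmr_rank(profile, [0, 0, 1, 1], 2)


class TestMcc:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5, 0, 5, 0), 1.0), ((0, 5, 0, 5), -1.0), ((25, 25, 25, 25), 0.0)],
    )
    def test_values(self, counts, expected):
        tp, fp, tn, fn = counts
        assert mcc(tp, fp, tn, fn) == pytest.approx(expected)

    def test_zero_denominator_is_zero(self):
        assert mcc(5, 0, 0, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(-1, 0, 0, 1)


@pytest.fixture(scope="module")
def informative_data():
    rng = np.random.default_rng(12)
    n = 200
    labels = np.repeat([0, 1], n // 2)
    features = {}
    for j in range(5):
        features[f"info{j}"] = np.exp(rng.normal(labels * 1.6, 0.7)) * 1e-3
    for j in range(95):
        features[f"noise{j}"] = np.exp(rng.normal(0, 0.7, size=n)) * 1e-3
    return _two_class_profile(features), labels


class TestPanelSelection:
    def test_informative_features_recovered(self, informative_data):
        profile, labels = informative_data
        kept = wilcoxon_prefilter(profile, labels, 0.05)
        ranked = mrmr_rank(profile.restrict(kept), labels, min(25, len(kept)))
        panel = mcc_panel_select(ranked, profile, labels, SpeciesPanelParams(panel_size=25, seed=0))
        informative = {f"info{j}" for j in range(5)}
        assert len(informative & set(panel.feature_ids)) >= 4
        assert len(panel.mcc_curve) == len(panel.feature_ids)

    def test_fixed_panel_size_contract(self, informative_data):
        profile, labels = informative_data
        ranked = mrmr_rank(profile, labels, 30)
        panel = mcc_panel_select(ranked, profile, labels, SpeciesPanelParams(panel_size=25, seed=0))
        assert len(panel.feature_ids) == 25
        assert panel.feature_ids == ranked[:25]
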