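import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nscpipe.classify import (
    RuleConfig,
    call_dep,
    categorize,
    classify_abundance,
    select_set,
    venn_partition,
)
from nscpipe.model import DepCall, SpectralCountMatrix, StudyDesign
from nscpipe.quantify import ConfigurationError, compute_nsc, nsc_ratio, summarize_groups

from conftest import random_matrix


def build(counts_rows, sizes):
    design = StudyDesign.from_groups(sizes)
    df = pd.DataFrame.from_dict(counts_rows, orient="index")
    df.columns = list(design.replicate_ids)
    df.index.name = "accession"
    return SpectralCountMatrix(df, design)


def run_calls(m, config=RuleConfig()):
    classification = classify_abundance(m, config)
    ratios = nsc_ratio(summarize_groups(compute_nsc(m), m, config.detection_floor))
    return classification, call_dep(ratios, config, classification)


class TestRuleConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sc_threshold": 0},
            {"presence_fraction": 0.0},
            {"presence_fraction": 1.5},
            {"over_threshold": 0.9},
            {"under_threshold": 1.5},
            {"presence_rounding": "banker"},
            {"discordant_policy": "sometimes"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            RuleConfig(**kwargs)

    def test_presence_quota_floor_and_ceil(self):
        floor, ceil = RuleConfig(), RuleConfig(presence_rounding="ceil")
        assert [floor.presence_quota(n) for n in (1, 2, 4, 5)] == [1, 1, 2, 2]
        assert [ceil.presence_quota(n) for n in (1, 2, 4, 5)] == [1, 1, 2, 3]


class TestClassifyAbundance:
    def test_high_counts_with_full_presence_significant(self):
        m = build({"A": [12, 11, 9, 8, 7]}, {"NN": 5})
        c = classify_abundance(m)
        assert c.significant_groups("A") == {"NN"}
        assert not c.global_low_abundant["A"]

    def test_single_detection_fails_quota_and_is_not_low(self):
        m = build({"A": [12, 0, 0, 0, 0], "B": [1, 1, 1, 1, 1]}, {"NN": 5})
        c = classify_abundance(m)
        assert c.significant_groups("A") == set()
        assert c.low_groups("A") == set()  # max exceeds the low threshold

    def test_boundary_count_significance_dominates_low(self):
        """SC exactly 10 meets both printed rules; significance wins."""
        m = build({"A": [10, 10], "B": [1, 1]}, {"NN": 2})
        c = classify_abundance(m)
        assert c.significant_groups("A") == {"NN"}
        assert c.low_groups("A") == set()
        assert not c.global_low_abundant["A"]

    def test_low_everywhere_is_globally_low(self):
        m = build({"A": [9, 2, 0, 1], "B": [30, 30, 30, 30]}, {"NN": 2, "NA": 2})
        c = classify_abundance(m)
        assert c.global_low_abundant["A"]
        assert c.low_groups("A") == {"NN", "NA"}

    @given(st.integers(min_value=0, max_value=2 ** 31))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_global_low_and_significance_exclusive(self, seed):
        m = random_matrix(np.random.default_rng(seed))
        c = classify_abundance(m)
        both = c.global_low_abundant & c.significant_in.any(axis=1)
        assert not both.any()

    @given(st.integers(min_value=0, max_value=2 ** 31))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_raising_sc_threshold_shrinks_significance(self, seed):
        m = random_matrix(np.random.default_rng(seed))
        lo = classify_abundance(m, RuleConfig(sc_threshold=5))
        hi = classify_abundance(m, RuleConfig(sc_threshold=12))
        assert (hi.significant_in <= lo.significant_in).all().all()


class TestCallDep:
    @pytest.mark.parametrize(
        "nn,na,expected",
        [
            ([4, 4], [4, 4], "none"),  # ratio 1
            ([2, 2], [4, 4], "none"),  # ratio exactly 2: strict >
            ([4, 4], [1, 1], "down"),
            ([1, 1], [12, 12], "up"),
        ],
    )
    def test_threshold_directions(self, nn, na, expected):
        m = build(
            {"A": nn + na, "B": [20 - x for x in nn] + [20 - x for x in na]},
            {"NN": 2, "NA": 2},
        )
        _, calls = run_calls(m)
        got = {c.comparison: c.direction for c in calls if c.protein == "A"}
        assert got["NA"] == expected

    def test_down_in_all_three_comparisons(self):
        m = build(
            {
                "A": [20, 20, 20, 20, 20, 2, 2, 2, 2, 2, 2, 2],
                "B": [80, 80, 80, 80, 80, 98, 98, 98, 98, 98, 98, 98],
            },
            {"NN": 5, "NA": 4, "ON": 1, "OA": 2},
        )
        _, calls = run_calls(m)
        got = {c.comparison: c.direction for c in calls if c.protein == "A"}
        assert got == {"NA": "down", "ON": "down", "OA": "down"}

    def test_test_absent_side_is_never_called(self):
        m = build({"A": [10, 10, 0, 0], "B": [10, 10, 30, 30]}, {"NN": 2, "NA": 2})
        _, calls = run_calls(m)
        a_calls = {c.comparison: c for c in calls if c.protein == "A"}
        assert a_calls["NA"].direction == "none"
        assert a_calls["NA"].presence_discordant

    def test_baseline_absent_calls_gated_on_test_significance(self):
        m = build(
            {
                "sig": [0, 0, 15, 14],
                "weak": [0, 0, 2, 1],
                "bulk": [30, 30, 30, 30],
            },
            {"NN": 2, "NA": 2},
        )
        _, calls = run_calls(m)
        got = {c.protein: c.direction for c in calls if c.comparison == "NA"}
        assert got["sig"] == "up"
        assert got["weak"] == "none"

    def test_epsilon_sign_policy_calls_unconditionally(self):
        m = build(
            {"weak": [0, 0, 2, 1], "tiny": [1, 0, 0, 0], "bulk": [30, 30, 30, 30]},
            {"NN": 2, "NA": 2},
        )
        config = RuleConfig(discordant_policy="epsilon-sign")
        classification = classify_abundance(m, config)
        ratios = nsc_ratio(summarize_groups(compute_nsc(m), m))
        calls = call_dep(ratios, config, classification)
        got = {c.protein: c.direction for c in calls if c.comparison == "NA"}
        assert got["weak"] == "up"

    @given(st.integers(min_value=0, max_value=2 ** 31))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_raising_over_threshold_shrinks_up_calls(self, seed):
        m = random_matrix(np.random.default_rng(seed))
        lo_cfg = RuleConfig(over_threshold=1.5, under_threshold=1 / 1.5)
        hi_cfg = RuleConfig(over_threshold=3.0, under_threshold=1 / 3.0)
        up = lambda cfg: {
            (c.protein, c.comparison)
            for c in run_calls(m, cfg)[1]
            if c.direction == "up"
        }
        assert up(hi_cfg) <= up(lo_cfg)


class TestVennPartition:
    def test_empty_calls_empty_cells(self):
        assert venn_partition([]) == {}

    def test_matches_bruteforce_subset_enumeration(self):
        rng = np.random.default_rng(17)
        comparisons = ["NA", "ON", "OA"]
        for _ in range(200):
            calls = []
            n = rng.integers(0, 8)
            expected_membership = {}
            for i in range(n):
                p = f"P{rng.integers(0, 5)}"
                for g in comparisons:
                    d = rng.choice(["up", "down", "none"])
                    if (p, g) not in {(c.protein, c.comparison) for c in calls}:
                        calls.append(DepCall(p, g, 1.0, d))
                        if d != "none":
                            expected_membership.setdefault(p, set()).add(g)
            cells = venn_partition(calls)
            brute = {}
            for subset in expected_membership.values():
                brute[frozenset(subset)] = brute.get(frozenset(subset), 0) + 1
            assert cells == brute
            assert sum(cells.values()) == len(expected_membership)


class TestCategorizeAndSelect:
    @pytest.fixture
    def classified(self):
        m = build(
            {
                "common": [30, 30, 30, 30],
                "uniq": [0, 0, 12, 12],
                "low": [2, 1, 2, 1],
            },
            {"NN": 2, "NA": 2},
        )
        classification, calls = run_calls(m)
        flags, summary = categorize(m, classification, calls)
        return m, classification, calls, flags, summary

    def test_flags_and_summary(self, classified):
        m, _, _, flags, summary = classified
        assert bool(flags.loc["common", "is_common"])
        assert bool(flags.loc["uniq", "is_unique"])
        assert not flags.loc["uniq", "is_common"]
        assert summary.n_common == 2  # 'common' and 'low' detected everywhere
        assert summary.n_unique == 1
        assert summary.n_low_abundant == 1
        assert sum(summary.venn.values()) == summary.n_dep

    def test_selectors(self, classified):
        m, classification, calls, _, _ = classified
        assert select_set(classification, calls, "common", m.design) == [
            "common",
            "low",  # detected in every replicate despite low abundance
        ]
        assert select_set(classification, calls, "unique", m.design) == ["uniq"]
        assert select_set(classification, calls, "low_abundant") == ["low"]
        assert select_set(classification, calls, "significant:NN") == ["common"]

    def test_unknown_selector_group_rejected(self, classified):
        _, classification, calls, _, _ = classified
        with pytest.raises(ConfigurationError):
            select_set(classification, calls, "significant:ZZ")
        with pytest.raises(ConfigurationError):
            select_set(classification, calls, "frobnicate")
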