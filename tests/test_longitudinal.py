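import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neostate.longitudinal import (ParticipantTimeline, assign_week1_state,
                                   build_timelines, carriage,
                                   paired_group_tests, retention_test,
                                   strain_retention_summary, transition_table)


def timeline(pid, mode, **states):
    obs = {tp: {"sample_id": f"{pid}-{tp}", "state": s} for tp, s in states.items()}
    return ParticipantTimeline(participant_id=pid, birth_mode=mode, observations=obs)


class TestWeek1State:
    def test_day4_preferred_over_day7(self):
        assert assign_week1_state(timeline("p", "VD", day4="EF", day7="BL")) == "EF"

    def test_day7_used_when_day4_absent(self):
        assert assign_week1_state(timeline("p", "CS", day7="BB")) == "BB"

    def test_no_week1_sample_gives_missing(self):
        assert assign_week1_state(timeline("p", "VD", day21="BL")) is None

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError):
            ParticipantTimeline("p", "VD", {"day99": {"sample_id": "x", "state": "BB"}})


class TestTransitionTable:
    def test_full_retention_is_diagonal(self):
        tls = [timeline(f"p{i}", "VD", day7="BB", day21="BB") for i in range(10)]
        [table] = transition_table(tls, "week1", "day21")
        assert table.counts.loc["BB", "BB"] == 10
        assert table.retention()["BB"] == 1.0

    def test_hand_crosstabulated_toy_set(self):
        tls = (
            [timeline(f"a{i}", "VD", day7="BB", day21="BB") for i in range(2)]
            + [timeline("b", "VD", day7="BB", day21="EF")]
            + [timeline(f"c{i}", "CS", day7="EF", day21="BL") for i in range(3)]
        )
        [table] = transition_table(tls, "week1", "day21")
        assert table.counts.loc["BB"].to_dict() == {"BB": 2, "BL": 0, "EF": 1}
        assert table.counts.loc["EF"].to_dict() == {"BB": 0, "BL": 3, "EF": 0}

    def test_stratified_counts_sum_to_pooled(self):
        rng = np.random.default_rng(0)
        tls = [timeline(f"p{i}", rng.choice(["VD", "CS"]),
                        day7=rng.choice(["BB", "EF", "BL"]),
                        day21=rng.choice(["BB", "EF", "BL"]))
               for i in range(50)]
        pooled, *strata = transition_table(tls, "week1", "day21", stratify=True)
        total = sum((t.counts for t in strata), 0 * pooled.counts)
        assert total.equals(pooled.counts)

    def test_participants_missing_a_timepoint_are_excluded_and_counted(self):
        tls = [timeline("p1", "VD", day7="BB", day21="BB"),
               timeline("p2", "VD", day7="EF")]
        [table] = transition_table(tls, "week1", "day21")
        assert table.n_excluded == 1
        assert table.counts.to_numpy().sum() == 1

    def test_empty_eligible_set_rejected(self):
        with pytest.raises(ValueError):
            transition_table([timeline("p", "VD", day7="BB")], "week1", "day21")


class TestRetentionTest:
    def _table(self, counts):
        from neostate.longitudinal import TransitionTable
        df = pd.DataFrame(counts, index=["A", "B"], columns=["A", "B"])
        return TransitionTable("pooled", df, "week1", "day21")

    def test_identical_proportions_give_zero_statistic(self):
        out = retention_test(self._table([[50, 50], [50, 50]]))
        assert out.loc[0, "chi2"] == pytest.approx(0.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_closed_form_2x2_chi_square(self):
        # (90/10) vs (30/70): n(ad-bc)^2/((a+b)(c+d)(a+c)(b+d)) = 75.0
        out = retention_test(self._table([[90, 10], [70, 30]]))
        a, b, c, d = 90, 10, 30, 70
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert closed == pytest.approx(75.0)
        assert out.loc[0, "chi2"] == pytest.approx(closed, abs=1e-10)

    def test_bh_step_up_on_three_pairs(self):
        from statsmodels.stats.multitest import multipletests
        # hand application of the step-up procedure
        q = multipletests([0.01, 0.02, 0.9], method="fdr_bh")[1]
        assert np.allclose(q, [0.03, 0.03, 0.9])

    def test_low_expected_cells_flagged_but_tested(self):
        with pytest.warns(UserWarning, match="expected cell"):
            out = retention_test(self._table([[1, 0], [0, 1]]))
        assert len(out) == 1


class TestCarriage:
    @pytest.mark.parametrize("abundance, expected", [
        (0.002, True), (0.0005, False), (0.001, True), (0.0, False), (1.0, True)])
    def test_inclusive_threshold(self, abundance, expected):
        assert carriage(abundance) is expected

    def test_monotone_in_abundance(self):
        grid = np.linspace(0, 0.01, 101)
        flags = [carriage(a) for a in grid]
        assert flags == sorted(flags)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            carriage(1.5)


class TestStrainRetention:
    @pytest.mark.parametrize("retained, n, pct", [
        (35, 44, 79.5), (24, 32, 75.0), (43, 69, 62.3), (0, 10, 0.0)])
    def test_percentages_to_one_decimal(self, retained, n, pct):
        events = [True] * retained + [False] * (n - retained)
        out = strain_retention_summary(events)
        assert out["percentage"] == pct
        assert out["retained"] == retained and out["n"] == n

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            strain_retention_summary([])


class TestPairedGroupTests:
    def test_identical_paired_vectors_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            out = paired_group_tests({"a": ([1, 2, 3], [1, 2, 3])}, "paired_t")
        assert out.loc[0, "p"] == 1.0

    def test_wilcoxon_exact_enumeration_of_signs(self):
        # diffs (-3,-3,-3): P(W+ = 0) = 1/8, two-sided p = 0.25
        out = paired_group_tests({"a": ([1, 2, 3], [4, 5, 6])}, "wilcoxon")
        assert out.loc[0, "p"] == pytest.approx(0.25)

    def test_wilcoxon_exact_matches_scipy_when_no_ties(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = x + rng.normal(0.5, 1.0, size=12)
        ours = paired_group_tests({"a": (x, y)}, "wilcoxon").loc[0, "p"]
        ref = stats.wilcoxon(x, y, method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_large_n_uses_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = x + rng.normal(0.3, 1.0, size=40)
        ours = paired_group_tests({"a": (x, y)}, "wilcoxon").loc[0, "p"]
        ref = stats.wilcoxon(x, y, method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_chisq_design_matches_retention_machinery(self):
        out = paired_group_tests({"a": [[90, 10], [30, 70]]}, "chisq")
        assert out.loc[0, "statistic"] == pytest.approx(75.0, abs=1e-10)

    def test_family_is_bh_corrected(self):
        rng = np.random.default_rng(4)
        comparisons = {f"c{i}": (rng.normal(size=10), rng.normal(size=10))
                       for i in range(5)}
        out = paired_group_tests(comparisons, "paired_t")
        assert (out["q_fdr"] >= out["p"] - 1e-12).all()


class TestBuildTimelines:
    def test_assembles_states_and_prefers_earliest_day_per_window(self):
        meta = pd.DataFrame([
            {"sample_id": "s1", "participant_id": "p1", "day_of_life": 7,
             "birth_mode": "VD", "timepoint_label": "day7"},
            {"sample_id": "s2", "participant_id": "p1", "day_of_life": 21,
             "birth_mode": "VD", "timepoint_label": "day21"},
        ]).set_index("sample_id", drop=False)
        states = pd.Series({"s1": "BB", "s2": "EF"})
        [tl] = build_timelines(meta, states)
        assert assign_week1_state(tl) == "BB"
        assert tl.state_at("day21") == "EF"
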