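"""Reliable change, trajectory labelling and the transition table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogpheno import (
    build_transition_table,
    classify_trajectories,
    compute_rci,
    estimate_change_norms,
)
from cogpheno.datasets import expand_transitions, published_transition_counts
from cogpheno.longitudinal import RCIError, TrajectoryError
from cogpheno.phenotyping import PHENOTYPES


def _wide(values, name="score"):
    return pd.DataFrame({name: values}, index=[f"s{i}" for i in range(len(values))])


def _exact_hc(n=50, r=0.5, sd=1.0, seed=0):
    """Control pairs with *exact* sample SDs and correlation (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    y = rng.standard_normal(n)
    y = y - y.mean()
    y = y - x * (x @ y) / (x @ x)  # orthogonal to x
    y = y / y.std(ddof=1)
    x2 = r * x + math.sqrt(1 - r * r) * y
    x2 = x2 / x2.std(ddof=1)
    return _wide(sd * x), _wide(sd * x2)


class TestChangeNorms:
    def test_sed_closed_form_at_r_half(self):
        # SD1 = SD2 = 1, r12 = 0.5 -> SEd = sqrt(2 * (1 - 0.5)) = 1 exactly
        hc1, hc2 = _exact_hc(n=60, r=0.5, sd=1.0)
        cn = estimate_change_norms(hc1, hc2)["score"]
        assert cn.r12 == pytest.approx(0.5, abs=1e-10)
        assert cn.se_diff == pytest.approx(1.0, abs=1e-10)

    def test_sd_of_differences_estimator(self):
        hc1, hc2 = _exact_hc(n=60, r=0.5, sd=2.0, seed=1)
        cn = estimate_change_norms(hc1, hc2, estimator="sd_of_differences")["score"]
        diff = (hc2["score"] - hc1["score"]).to_numpy()
        assert cn.se_diff == pytest.approx(np.std(diff, ddof=1))

    def test_too_few_pairs_raises(self):
        hc1, hc2 = _exact_hc(n=60)
        with pytest.raises(RCIError, match="score"):
            estimate_change_norms(hc1.iloc[:10], hc2.iloc[:10])

    def test_degenerate_changes_raise(self):
        vals = np.linspace(0, 1, 30)
        with pytest.raises(RCIError, match="zero SEd"):
            estimate_change_norms(
                _wide(vals), _wide(vals + 5.0), estimator="sd_of_differences"
            )


class TestComputeRCI:
    def test_change_equal_to_hc_mean_change_gives_zero(self):
        hc1, hc2 = _exact_hc(n=60, r=0.5)
        hc2 = hc2 + 3.0  # practice effect of +3
        t1 = _wide([10.0, 12.0])
        t2 = t1 + 3.0
        res = compute_rci(t1, t2, hc1, hc2)
        assert np.allclose(res["rci"], 0.0, atol=1e-10)
        assert not res["reliable"].any()

    def test_boundary_is_inclusive(self):
        hc1, hc2 = _exact_hc(n=60, r=0.5)  # SEd = 1, mean change = 0
        t1 = _wide([0.0])
        t2 = _wide([1.64])
        res = compute_rci(t1, t2, hc1, hc2)
        assert res["rci"].iloc[0] == pytest.approx(1.64, abs=1e-9)
        assert bool(res["reliable"].iloc[0])

    def test_null_reliable_rate_matches_two_sided_tail(self):
        """HC-like simulees: |RCI| >= 1.64 in about 2*Phi(-1.64) = 10% of cases."""
        rng = np.random.default_rng(42)
        n, r = 1000, 0.6
        x1 = rng.standard_normal(n)
        x2 = r * x1 + math.sqrt(1 - r * r) * rng.standard_normal(n) + 0.5
        sim1, sim2 = _wide(x1), _wide(x2)
        res = compute_rci(sim1, sim2, sim1, sim2)
        rate = res["reliable"].mean()
        assert rate == pytest.approx(0.10, abs=0.025)
        assert abs(res["rci"].mean()) < 0.1


class TestTrajectories:
    @pytest.mark.parametrize(
        "bl,fu,expected",
        [
            ("isolated_ips", "multidomain", "declining"),
            ("isolated_attention", "isolated_memory", "stable"),  # domain switch
            ("isolated_efwm", "preserved", "improving"),
            ("multidomain", "isolated_ips", "improving"),
            ("preserved", "isolated_memory", "declining"),
            ("preserved", "preserved", "stable"),
            ("multidomain", "multidomain", "stable"),
        ],
    )
    def test_category_rules(self, bl, fu, expected):
        t = classify_trajectories(
            pd.DataFrame({"subject_id": ["a"], "phenotype": [bl]}),
            pd.DataFrame({"subject_id": ["a"], "phenotype": [fu]}),
        )
        assert t["change"].iloc[0] == expected

    def test_count_rule_with_n_impaired(self):
        bl = pd.DataFrame(
            {"subject_id": ["a", "b"], "phenotype": ["multidomain"] * 2,
             "n_impaired": [2, 4]}
        )
        fu = pd.DataFrame(
            {"subject_id": ["a", "b"], "phenotype": ["multidomain"] * 2,
             "n_impaired": [3, 2]}
        )
        t = classify_trajectories(bl, fu).set_index("subject_id")
        assert t.loc["a", "change"] == "declining"  # 2 -> 3 impaired domains
        assert t.loc["b", "change"] == "stable"  # 4 -> 2 stays multidomain

    def test_followup_only_subject_raises(self):
        with pytest.raises(TrajectoryError):
            classify_trajectories(
                pd.DataFrame({"subject_id": ["a"], "phenotype": ["preserved"]}),
                pd.DataFrame({"subject_id": ["a", "b"], "phenotype": ["preserved"] * 2}),
            )

    def test_lost_to_followup_counted(self):
        bl = pd.DataFrame({"subject_id": ["a", "b"], "phenotype": ["preserved"] * 2})
        fu = pd.DataFrame({"subject_id": ["a"], "phenotype": ["preserved"]})
        t = classify_trajectories(bl, fu)
        assert len(t) == 1
        assert t.attrs["n_no_followup"] == 1

    def test_exactly_one_label_per_subject(self, small_sim):
        from cogpheno import classify_profiles, compose_domains, score

        z = score(small_sim.patients, small_sim.norms_t1)
        prof = compose_domains(z)
        bl = classify_profiles(prof[prof["timepoint"] == 1])
        fu = classify_profiles(prof[prof["timepoint"] == 2])
        cols = ["subject_id", "phenotype", "n_impaired"]
        t = classify_trajectories(bl[cols], fu[cols])
        assert t["subject_id"].is_unique
        counts = t["change"].value_counts()
        assert counts.sum() == len(t)


class TestTransitionTable:
    def test_single_subject_preserved(self):
        t = classify_trajectories(
            pd.DataFrame({"subject_id": ["a"], "phenotype": ["preserved"]}),
            pd.DataFrame({"subject_id": ["a"], "phenotype": ["preserved"]}),
        )
        table = build_transition_table(t)
        assert table.counts.loc["preserved", "preserved"] == 1
        assert table.decline_pct_display["preserved"] == 0

    def test_published_isolated_rows_accounting(self):
        """The printed five-year cross-tabulation: 26 of 73 isolated-baseline
        patients declined, 32 stayed stable, 15 improved."""
        bl, fu = expand_transitions()
        t = classify_trajectories(bl, fu)
        table = build_transition_table(t)
        iso = [c for c in PHENOTYPES if c.startswith("isolated")]
        assert int(table.decline_counts[iso].sum()) == 26
        assert int(table.stable_counts[iso].sum()) == 32
        assert int(table.improve_counts[iso].sum()) == 15
        assert int(table.row_totals[iso].sum()) == 73
        assert table.decline_pct_display["isolated_ips"] == 69
        assert table.decline_pct_display["preserved"] == 54

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_any_transition_matrix(self, seed):
        """A cohort constructed to realise an arbitrary transition matrix is
        reproduced cell-for-cell."""
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 6, size=(6, 6)), index=list(PHENOTYPES), columns=list(PHENOTYPES)
        )
        if counts.to_numpy().sum() == 0:
            counts.iloc[0, 0] = 1
        bl, fu = expand_transitions(counts)
        table = build_transition_table(classify_trajectories(bl, fu))
        pd.testing.assert_frame_equal(
            table.counts, counts, check_names=False, check_dtype=False
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_transition_table(pd.DataFrame(columns=["baseline_phenotype"]))

    def test_half_up_display_rounding(self):
        # 5/8 = 62.5% must display as 63
        bl = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(8)],
             "phenotype": ["isolated_ips"] * 8}
        )
        fu = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(8)],
             "phenotype": ["multidomain"] * 5 + ["isolated_ips"] * 3}
        )
        table = build_transition_table(classify_trajectories(bl, fu))
        assert table.decline_pct["isolated_ips"] == pytest.approx(62.5)
        assert table.decline_pct_display["isolated_ips"] == 63
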