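"""Statistical layer: normalisation, ROUT, mixed ANOVA, Sidak, post hocs, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import retscreen as rs


class TestNormalizeToBaseline:
    def test_simple_arithmetic(self):
        t = pd.DataFrame(
            dict(subject_id=["a", "a"], genotype=["WT"] * 2, treatment=["VEH"] * 2,
                 time_min=[0.0, 30.0], measure=["m"] * 2, value=[200.0, 250.0])
        )
        out = rs.normalize_to_baseline(t)
        assert sorted(out["value"]) == [100.0, 125.0]

    def test_constant_series_all_100(self):
        t = pd.DataFrame(
            dict(subject_id=["a"] * 3, genotype=["WT"] * 3, treatment=["VEH"] * 3,
                 time_min=[0.0, 15.0, 30.0], measure=["m"] * 3, value=[77.0] * 3)
        )
        assert rs.normalize_to_baseline(t)["value"].tolist() == [100.0, 100.0, 100.0]

    def test_zero_baseline_subject_excluded_with_warning(self):
        t = pd.DataFrame(
            dict(subject_id=["a", "a", "b", "b"], genotype=["WT"] * 4, treatment=["VEH"] * 4,
                 time_min=[0.0, 30.0] * 2, measure=["m"] * 4, value=[0.0, 5.0, 10.0, 11.0])
        )
        with pytest.warns(UserWarning, match="zero baseline"):
            out = rs.normalize_to_baseline(t)
        assert set(out["subject_id"]) == {"b"}

    def test_group_mean_recovers_generating_growth(self):
        # HOM+LDOPA growth 1.47 with jitter: normalised 30-min group mean
        # lands within 2 SEM of 147 (checked over several seeds).
        hits = 0
        for seed in range(10):
            d = rs.CohortDesign(n_per_group={"HOM_LDOPA": 11}, seed=seed)
            tr = rs.simulate_cohort_amplitudes(d)
            tab = tr.rename(columns={"p2_amp_true_uV": "value"}).assign(measure="p2")[
                ["subject_id", "genotype", "treatment", "time_min", "measure", "value"]
            ]
            norm = rs.normalize_to_baseline(tab)
            cell = norm[norm.time_min == 30.0]["value"]
            sem = cell.std(ddof=1) / np.sqrt(len(cell))
            hits += abs(cell.mean() - 147.0) <= 2.0 * sem
        assert hits >= 8


class TestRout:
    def test_clean_small_sample_unflagged(self):
        assert rs.rout_outliers([1, 2, 3, 4, 5]).is_empty

    def test_gross_outlier_flagged(self):
        rep = rs.rout_outliers([1, 2, 3, 4, 1000])
        assert rep.flagged == [4]

    def test_constant_vector_empty_report(self):
        rep = rs.rout_outliers([5.0] * 6)
        assert rep.is_empty and rep.rsdr == 0.0

    def test_all_residuals_below_two_rsdr_never_flagged(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.normal(size=8)
            rep = rs.rout_outliers(v, q=0.5)
            resid = np.abs(v - rep.center)
            if rep.rsdr > 0 and np.all(resid < 2 * rep.rsdr):
                assert rep.is_empty

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            rs.rout_outliers([1.0, 2.0])


class TestSidak:
    def test_identity_at_m_one(self):
        assert rs.sidak_adjust(0.05, 1) == pytest.approx(0.05)

    def test_zero_stays_zero(self):
        assert rs.sidak_adjust(0.0, 7) == 0.0

    def test_known_value(self):
        assert rs.sidak_adjust(0.05, 2) == pytest.approx(0.0975)

    @given(p=st.floats(0.0, 1.0), m1=st.integers(1, 50), m2=st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_m_and_bounded(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        a, b = rs.sidak_adjust(p, lo), rs.sidak_adjust(p, hi)
        assert 0.0 <= a <= b <= 1.0
        assert a >= p - 1e-12  # adjusted never below raw


class TestMixedAnova:
    def test_hand_computed_decomposition(self, hand_table):
        res = rs.mixed_anova(hand_table, "m", between="grp")
        assert res.effects["between"].ss == pytest.approx(200.0, abs=1e-10)
        assert res.effects["time"].ss == pytest.approx(8.0, abs=1e-10)
        assert res.effects["interaction"].ss == pytest.approx(0.0, abs=1e-10)
        assert res.strata["subjects_within_groups"].ss == pytest.approx(32.0, abs=1e-10)
        assert res.strata["residual"].ss == pytest.approx(0.0, abs=1e-10)
        assert res.effects["between"].F == pytest.approx(12.5)
        # parallel profiles: zero interaction F
        assert res.effects["interaction"].F == 0.0

    def test_agrees_with_pingouin_on_random_table(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        rows = []
        for gi, g in enumerate(["x", "y", "z"]):
            for s in range(5 + gi):  # unbalanced
                subj = f"{g}{s}"
                base = rng.normal()
                for t in range(4):
                    rows.append(
                        dict(subject_id=subj, grp=g, time_min=float(t), measure="m",
                             genotype="WT", treatment="VEH",
                             value=base + 0.5 * t + rng.normal())
                    )
        df = pd.DataFrame(rows)
        res = rs.mixed_anova(df, "m", between="grp")
        pg = pingouin.mixed_anova(
            df, dv="value", within="time_min", subject="subject_id", between="grp"
        ).set_index("Source")
        assert res.effects["between"].F == pytest.approx(pg.loc["grp", "F"], rel=1e-6)
        assert res.effects["time"].F == pytest.approx(pg.loc["time_min", "F"], rel=1e-6)
        assert res.effects["interaction"].F == pytest.approx(pg.loc["Interaction", "F"], rel=1e-6)
        assert res.effects["interaction"].p == pytest.approx(pg.loc["Interaction", "p_unc"], rel=1e-6)

    def test_ss_additivity_holds_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n1, n2, k = rng.integers(2, 6), rng.integers(2, 6), rng.integers(2, 5)
            y = rng.normal(size=(n1 + n2, k))
            labels = ["a"] * n1 + ["b"] * n2
            res = rs.mixed_anova_wide(y, labels)  # invariant asserted internally
            total = sum(e.ss for e in res.effects.values()) + sum(
                e.ss for e in res.strata.values()
            )
            assert total == pytest.approx(res.ss_total, rel=1e-9)

    def test_incomplete_subject_listwise_deleted(self):
        rng = np.random.default_rng(2)
        rows = []
        for g in ("g1", "g2"):
            for s in range(3):
                for t in (0.0, 30.0):
                    rows.append(
                        dict(subject_id=f"{g}{s}", grp=g, genotype="WT", treatment="VEH",
                             time_min=t, measure="m", value=rng.normal())
                    )
        df = pd.DataFrame(rows)
        df = df.drop(df[(df.subject_id == "g10") & (df.time_min == 30.0)].index)
        with pytest.warns(UserWarning, match="listwise"):
            res = rs.mixed_anova(df, "m", between="grp")
        assert res.n_obs == 10  # five complete subjects x two timepoints

    def test_single_subject_cell_rejected(self, hand_table):
        t = hand_table[hand_table.subject_id != "A"]
        with pytest.raises(ValueError, match="fewer than 2"):
            rs.mixed_anova(t, "m", between="grp")


class TestPosthoc:
    def test_hand_computed_t_statistic(self, hand_table):
        # MS_subj=16 (df 2), MS_res=0, k=2 -> var_cell=(16+0)/2=8;
        # diff at each time = -10; se = sqrt(8*(1/2+1/2)) = sqrt(8)
        post = rs.posthoc_by_time(hand_table, "m", pairs=[("g1", "g2")], between="grp")
        assert len(post) == 2
        expect_t = -10.0 / np.sqrt(8.0)
        assert post["t"].to_numpy() == pytest.approx([expect_t, expect_t])

    def test_family_of_one_adjusted_equals_raw(self, hand_table):
        post = rs.posthoc_by_time(hand_table, "m", pairs=[("g1", "g2")], between="grp", m=1)
        assert post["sidak_p"].to_numpy() == pytest.approx(post["raw_p"].to_numpy())

    def test_adjusted_monotone_in_family_size(self, hand_table):
        p1 = rs.posthoc_by_time(hand_table, "m", pairs=[("g1", "g2")], between="grp", m=1)
        p4 = rs.posthoc_by_time(hand_table, "m", pairs=[("g1", "g2")], between="grp", m=4)
        assert (p4["sidak_p"].to_numpy() >= p1["sidak_p"].to_numpy() - 1e-12).all()

    def test_unknown_contrast_rejected(self, hand_table):
        with pytest.raises(ValueError, match="undefined contrast"):
            rs.posthoc_by_time(hand_table, "m", pairs=[("g1", "nope")], between="grp")


class TestSummarize:
    def test_mean_and_sem(self):
        t = pd.DataFrame(
            dict(subject_id=["a", "b"], genotype=["WT"] * 2, treatment=["VEH"] * 2,
                 time_min=[0.0] * 2, measure=["m"] * 2, value=[100.0, 120.0])
        )
        s = rs.summarize_groups(t, "m")
        assert s["mean"].iloc[0] == 110.0
        assert s["sem"].iloc[0] == pytest.approx(10.0)

    def test_single_subject_cell_flagged(self):
        t = pd.DataFrame(
            dict(subject_id=["a"], genotype=["WT"], treatment=["VEH"],
                 time_min=[0.0], measure=["m"], value=[100.0])
        )
        s = rs.summarize_groups(t, "m")
        assert s["single_subject"].iloc[0]
        assert np.isnan(s["sem"].iloc[0])
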