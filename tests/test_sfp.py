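import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from probekit.affyio import ProbeMatrix, extract_pm
from probekit.errors import ProbekitError
from probekit.sfp import (
    QuadDesign,
    ScreenConfig,
    bh_adjust,
    candidate_strategy,
    d_value,
    dfc_screen,
    euler_partition,
    fcd,
    ma_value,
    post_between,
    post_within,
    screen,
    small_sample_scale,
    symmetric_fc,
    trimmed_mean,
    twin_volcano_filter,
    volcano_filter,
    winsorized_variance,
)


def _design(values, set_size=None):
    """Quad design from a probes x 4 array; one set unless set_size given."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    size = set_size or n
    ids = [f"s{i // size:04d}_at_{i}_{0}" for i in range(n)]
    return QuadDesign(ProbeMatrix(ids, ["B1", "B2", "B3", "B4"], values))


class TestElementary:
    def test_symmetric_fc_worked_example(self):
        assert round(symmetric_fc(564 / 288), 2) == 1.96

    def test_symmetric_fc_reciprocal(self):
        assert symmetric_fc(0.5) == -2.0

    def test_symmetric_fc_unity(self):
        assert symmetric_fc(1.0) == 1.0

    def test_symmetric_fc_nonpositive_fails(self):
        with pytest.raises(ProbekitError):
            symmetric_fc(0.0)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_fc_sign_and_magnitude(self, q):
        fc = symmetric_fc(q)
        assert abs(fc) >= 1.0
        assert (fc >= 1) == (q >= 1)

    def test_ma_zero_for_equal_pairs(self):
        assert ma_value(7.0, 7.0, 3.0, 3.0) == 0.0

    def test_ma_direct_evaluation(self):
        assert ma_value(4.0, 1.0, 4.0, 1.0) == 2.0

    def test_ma_antisymmetric_under_swap(self):
        a = ma_value(5.0, 2.0, 7.0, 3.0)
        b = ma_value(2.0, 5.0, 3.0, 7.0)
        assert a == pytest.approx(-b)

    def test_ma_nonpositive_fails(self):
        with pytest.raises(ProbekitError):
            ma_value(0.0, 1.0, 1.0, 1.0)

    def test_d_zero_for_equal_pairs(self):
        assert d_value(9.0, 9.0, 2.0, 2.0) == 0.0

    def test_d_direct_evaluation(self):
        assert d_value(100.0, 36.0, 100.0, 36.0) == 64.0

    def test_d_antisymmetric(self):
        assert d_value(10.0, 4.0, 8.0, 2.0) == -d_value(4.0, 10.0, 2.0, 8.0)

    def test_fcd_sqrt(self):
        assert fcd(64.0) == 8.0

    def test_fcd_zero(self):
        assert fcd(0.0) == 0.0

    def test_fcd_odd_function(self):
        assert fcd(-64.0) == -8.0


class TestDfcScreen:
    TH = 93.04

    def test_probe_just_below_parental_cut(self):
        # parental fold-change 1.96 (564/288) misses the cut of 2
        design = _design([[564.0, 288.0, 450.0, 290.0]])
        assert not dfc_screen(design, self.TH, 2.0, 1.5)[0]

    def test_hand_flagged_probe(self):
        design = _design([[600.0, 100.0, 450.0, 150.0]])
        assert dfc_screen(design, self.TH, 2.0, 1.5)[0]

    def test_intensity_floor_dominates(self):
        design = _design([[600.0, 90.0, 450.0, 150.0]])  # b2 <= th
        assert not dfc_screen(design, self.TH, 2.0, 1.5)[0]

    def test_direction_consistency_required(self):
        # strong parental up, strong bulk DOWN -> inconsistent, no flag
        design = _design([[600.0, 150.0, 150.0, 600.0]])
        assert not dfc_screen(design, self.TH, 2.0, 1.5)[0]

    def test_th_tightening_shrinks_flags(self, quad_sim_sfp):
        layout, arrays, _ = quad_sim_sfp
        design = QuadDesign(extract_pm(layout, arrays))
        loose = dfc_screen(design, 0.0)
        tight = dfc_screen(design, 200.0)
        assert np.all(tight <= loose)


class TestRobustPrimitives:
    def test_trimmed_mean_hand(self):
        assert trimmed_mean(np.arange(1.0, 11.0), 0.1) == 5.5

    def test_trimmed_mean_h0_is_mean(self):
        vals = np.array([3.0, 1.0, 2.0])
        assert trimmed_mean(vals, 0.2) == pytest.approx(2.0)

    def test_trimmed_mean_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(17)
        assert trimmed_mean(vals, 0.2) == pytest.approx(
            trimmed_mean(rng.permutation(vals), 0.2)
        )

    def test_trimmed_mean_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            vals = rng.standard_normal(n)
            g = float(rng.uniform(0.05, 0.45))
            if 2 * int(g * n) >= n:
                continue
            assert trimmed_mean(vals, g) == pytest.approx(
                float(stats.trim_mean(vals, g))
            )

    def test_winsorized_variance_constant_zero(self):
        assert winsorized_variance(np.full(9, 3.3), 0.2) == 0.0

    def test_winsorized_variance_hand(self):
        # [1..10], h=1 -> [2,2,3,...,9,9]; sample variance 66.5/9
        assert winsorized_variance(np.arange(1.0, 11.0), 0.1) == pytest.approx(
            66.5 / 9
        )

    def test_winsorized_variance_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            vals = rng.standard_normal(int(rng.integers(5, 20)))
            assert winsorized_variance(vals, 0.1) >= 0.0

    def test_winsorized_matches_scipy_mstats(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            vals = rng.standard_normal(n)
            g = float(rng.uniform(0.05, 0.45))
            h = int(g * n)
            if 2 * h >= n:
                continue
            wins = stats.mstats.winsorize(
                np.sort(vals), limits=(h / n, h / n)
            )
            assert winsorized_variance(vals, g) == pytest.approx(
                float(np.var(np.asarray(wins), ddof=1))
            )

    def test_small_sample_scale_printed_formula(self):
        assert small_sample_scale(11, 1) == pytest.approx(
            1 + 16 * np.exp(-9)
        )


class TestBhAdjust:
    def test_hand_case(self):
        out = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(out, [0.03, 0.03, 0.04])

    def test_all_equal_unchanged(self):
        out = bh_adjust([0.2, 0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        assert not np.isnan(out[0])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 100)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestPostBetween:
    def test_equal_mas_give_p_one(self):
        vals = np.tile([80.0, 40.0, 160.0, 80.0], (5, 1))  # identical MA
        res = post_between(_design(vals))
        assert np.allclose(res["p"], 1.0)

    def test_outlier_probe_has_smallest_p(self):
        # MA = 0 for four probes, 3 for the fifth
        vals = np.array(
            [[100.0, 100.0, 50.0, 50.0]] * 4 + [[400.0, 50.0, 200.0, 25.0]]
        )
        res = post_between(_design(vals))
        assert res["p"].to_numpy().argmin() == 4

    def test_matches_brute_force_t(self):
        rng = np.random.default_rng(6)
        vals = np.exp(rng.normal(5, 0.3, size=(9, 4)))
        design = _design(vals)
        res = post_between(design)
        ma = ma_value(*design.b)
        for k in range(9):
            rest = np.delete(ma, k)
            n = rest.size
            T = (ma[k] - rest.mean()) / (
                rest.std(ddof=1) * np.sqrt(1 + 1 / n)
            )
            p = 2 * stats.t.sf(abs(T), n - 1)
            assert res["t"].iloc[k] == pytest.approx(T)
            assert res["p"].iloc[k] == pytest.approx(p)

    def test_small_set_skipped_with_reason(self):
        vals = np.exp(np.random.default_rng(7).normal(5, 0.3, (2, 4)))
        res = post_between(_design(vals))
        assert res["p"].isna().all()
        assert (res["reason"] != "").all()


class TestPostWithin:
    def test_h0_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(8)
        vals = np.exp(rng.normal(5, 0.3, size=(8, 4)))
        design = _design(vals)
        res = post_within(design, "G1", gamma=0.1,
                          use_small_sample_scale=False)
        delta = design.b[0] - design.b[1]
        # n = 7, h = 0: plain one-sample t of probe k vs the rest
        for k in range(8):
            rest = np.delete(delta, k)
            n = rest.size
            T = (delta[k] - rest.mean()) / (rest.std(ddof=1) / np.sqrt(n))
            assert res["t"].iloc[k] == pytest.approx(T)
            assert res["df"].iloc[k] == n - 1

    def test_small_sample_scale_applied(self):
        rng = np.random.default_rng(9)
        vals = np.exp(rng.normal(5, 0.3, size=(12, 4)))  # n=11, h=1
        design = _design(vals)
        off = post_within(design, "G1", 0.1, use_small_sample_scale=False)
        on = post_within(design, "G1", 0.1, use_small_sample_scale=True)
        ratio = on["t"].to_numpy() / off["t"].to_numpy()
        assert np.allclose(ratio, small_sample_scale(11, 1))

    def test_planted_outlier_gets_min_p(self):
        rng = np.random.default_rng(10)
        base = np.exp(rng.normal(5, 0.05, size=12))
        vals = np.column_stack([base, base * 1.01, base, base * 0.99])
        vals[3, 0] *= 6.0  # one strongly deviant G1 difference
        res = post_within(_design(vals), "G1", 0.1)
        assert res["p"].to_numpy().argmin() == 3

    def test_df_guard_skips_small_sets(self):
        # 4 probes -> n = 3, h = floor(0.45*3) = 1 -> df = 0 -> skip
        vals = np.exp(np.random.default_rng(11).normal(5, 0.3, (4, 4)))
        res = post_within(_design(vals), "G1", 0.45)
        assert res["p"].isna().all()
        assert (res["reason"] != "").all()

    def test_invalid_group_fails(self):
        vals = np.ones((5, 4))
        with pytest.raises(ProbekitError):
            post_within(_design(vals), "G3")


class TestFilters:
    def _records(self):
        return pd.DataFrame(
            {
                "ma": [1.0, 1.0, 0.2, -1.5, 1.0, 1.0],
                "fc1": [3.0, 3.0, 3.0, -3.0, 1.2, 3.0],
                "fc2": [2.0, 2.0, 2.0, -2.0, 2.0, 1.1],
                "fcd_g1": [9.0, 9.0, 9.0, -9.0, 9.0, 2.0],
                "fcd_g2": [9.0, 2.0, 9.0, -9.0, 9.0, 2.0],
                "min_intensity": [100.0, 100.0, 100.0, 100.0, 100.0, 50.0],
                "p_between_adj": [0.01, 0.01, 0.01, 0.01, 0.2, 0.01],
                "p_within_g1_adj": [0.01, 0.01, 0.2, 0.01, 0.01, 0.01],
                "p_within_g2_adj": [0.2, 0.2, 0.01, 0.01, 0.2, 0.2],
            }
        )

    def test_volcano_hand_evaluated(self):
        cfg = ScreenConfig(th=93.04)
        flags = volcano_filter(self._records(), cfg)
        # r0/r1/r3 pass all; r2 fails |ma|; r4 fails p; r5 fails th+fc2
        assert flags.tolist() == [True, True, False, True, False, False]

    def test_volcano_th_failure_unflags(self):
        cfg = ScreenConfig(th=200.0)
        assert not volcano_filter(self._records(), cfg).any()

    def test_volcano_anti_monotone_in_cuts(self):
        recs = self._records()
        base = volcano_filter(recs, ScreenConfig(th=93.04))
        for tighter in (
            ScreenConfig(th=93.04, ma_cut=1.2),
            ScreenConfig(th=93.04, alpha=0.005),
            ScreenConfig(th=120.0),
        ):
            assert np.all(volcano_filter(recs, tighter) <= base)

    def test_twin_volcano_group_colour(self):
        cfg = ScreenConfig(fcp_cut=None)
        flags, groups = twin_volcano_filter(self._records(), cfg)
        assert flags.tolist() == [True, True, True, True, True, False]
        assert groups[1] == "G1"  # significant in G1 only
        assert groups[3] == "both"

    def test_twin_volcano_null_unflagged(self):
        recs = self._records()
        recs["p_within_g1_adj"] = 0.9
        recs["p_within_g2_adj"] = 0.9
        flags, groups = twin_volcano_filter(recs, ScreenConfig())
        assert not flags.any()
        assert (groups == "").all()

    def test_twin_volcano_anti_monotone(self):
        recs = self._records()
        base, _ = twin_volcano_filter(recs, ScreenConfig(fcp_cut=None))
        for tighter in (
            ScreenConfig(fcp_cut=None, fcd_cut=12.0),
            ScreenConfig(fcp_cut=None, alpha=0.001),
            ScreenConfig(fcp_cut=2.0),
        ):
            tf, _ = twin_volcano_filter(recs, tighter)
            assert np.all(tf <= base)


class TestEulerPartition:
    # region composition: VP4={a,b,d,e}, DFC2={d,e}, TVP2={b,c,e,f}, TVP4={e,f}
    LETTERS = {"a": "vp4", "b": None}  # documentation only

    def _expected(self, vp4, dfc2, tvp2, tvp4):
        if tvp4 and not tvp2:
            return "error"
        if dfc2:
            return "e" if tvp2 else "d"
        if vp4:
            if tvp4:
                return "e"
            return "b" if tvp2 else "a"
        if tvp2:
            return "f" if tvp4 else "c"
        return "none"

    def test_exhaustive_truth_table(self):
        for combo in itertools.product([False, True], repeat=4):
            vp4, dfc2, tvp2, tvp4 = combo
            expected = self._expected(vp4, dfc2, tvp2, tvp4)
            args = tuple(np.array([v]) for v in combo)
            if expected == "error":
                with pytest.raises(ProbekitError):
                    euler_partition(*args)
            else:
                assert euler_partition(*args)[0] == expected, combo

    def test_all_four_sets_is_e(self):
        t = np.array([True])
        assert euler_partition(t, t, t, t)[0] == "e"

    def test_vp4_only_is_a(self):
        t, f = np.array([True]), np.array([False])
        assert euler_partition(t, f, f, f)[0] == "a"

    def test_unflagged_none(self):
        f = np.array([False])
        assert euler_partition(f, f, f, f)[0] == "none"


class TestCandidateStrategy:
    def _records(self, label, fc1=3.0, fcd_val=12.0, min_b=200.0):
        return pd.DataFrame(
            {
                "euler_label": [label],
                "fc1": [fc1],
                "fcd": [fcd_val],
                "min_intensity": [min_b],
            }
        )

    def test_e_kept_when_fcd_clearly_above_cut(self):
        cfg = ScreenConfig(th=93.04)
        assert candidate_strategy(self._records("e", fcd_val=12.0), cfg)[0]

    def test_e_dropped_when_fcd_barely_above_cut(self):
        cfg = ScreenConfig(th=93.04)
        assert not candidate_strategy(self._records("e", fcd_val=8.2), cfg)[0]

    def test_b_near_cut_probe_retained(self):
        # fc1 = 1.96 vs cut 2 within tolerance 0.1, strong hybridisation
        cfg = ScreenConfig(th=93.04)
        assert candidate_strategy(
            self._records("b", fc1=1.96, min_b=288.0), cfg
        )[0]

    def test_f_poor_hybridisation_rejected(self):
        # intensity 42 vs threshold 93.04 -> discarded
        cfg = ScreenConfig(th=93.04)
        assert not candidate_strategy(self._records("f", min_b=42.0), cfg)[0]

    def test_f_slightly_below_threshold_kept(self):
        cfg = ScreenConfig(th=93.04)
        assert candidate_strategy(self._records("f", min_b=85.0), cfg)[0]

    def test_c_and_d_never_candidates(self):
        cfg = ScreenConfig(th=93.04)
        for label in ("c", "d", "none"):
            assert not candidate_strategy(self._records(label), cfg)[0]


class TestScreenPipeline:
    def test_invariants_on_simulation(self, quad_sim_sfp):
        layout, arrays, truth = quad_sim_sfp
        design = QuadDesign(extract_pm(layout, arrays))
        cfg = ScreenConfig(th=150.0)
        records = screen(design, cfg)
        # fc sign/magnitude invariant
        assert np.all(np.abs(records["fc1"]) >= 1.0)
        assert np.all(
            np.sign(records["fcd"]) == np.sign(records["d"])
        )
        # adjusted >= raw
        ok = ~records["p_between"].isna()
        assert np.all(
            records["p_between_adj"][ok] >= records["p_between"][ok] - 1e-12
        )
        # every flagged probe has a label; unflagged probes are 'none'
        tvp2_or_more = (
            records["vp"] | records["dfc"] | records["tvp"]
        )
        labelled = records["euler_label"] != "none"
        assert np.all(tvp2_or_more <= labelled)

    def test_quad_design_needs_four_chips(self):
        pm = ProbeMatrix(["a_0_0"], ["c1", "c2"], np.ones((1, 2)))
        with pytest.raises(ProbekitError):
            QuadDesign(pm)

    def test_quad_design_rejects_nonpositive(self):
        pm = ProbeMatrix(
            ["a_0_0"], ["B1", "B2", "B3", "B4"],
            np.array([[1.0, 2.0, 0.0, 3.0]])
        )
        with pytest.raises(ProbekitError):
            QuadDesign(pm)
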