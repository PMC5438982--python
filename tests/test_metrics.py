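"""Preference Index, shock counting, windowed speeds and exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apisim.arena import ChamberSpec, ShockSpec, SideAssignment, DARK, light, shock_pulse_times
from apisim.metrics import (
    EXCLUSION_THRESHOLD_CM_S,
    StructuralError,
    TrialSlice,
    apply_exclusion,
    bee_summary_table,
    count_shocks,
    delta_speed,
    preference_index,
    pre_post_speed,
    segment_trials,
    summarize_cohort,
    trial_metrics_table,
    window_speed,
)

FS = 16.0
CH = ChamberSpec()


def make_slice(positions, onset=3.0, focal="left", shocked=None, duration=14.0):
    """Hand-built slice: positions sampled at 16 Hz from t=0 (onset at 3 s)."""
    positions = np.asarray(positions, dtype=float)
    assignment = SideAssignment(
        trial_index=0,
        bee_side=focal,
        left_stimulus=light("B") if focal == "left" else light("G"),
        right_stimulus=light("G") if focal == "left" else light("B"),
        focal_side=focal,
        shocked_side=shocked,
    )
    return TrialSlice(
        bee_id="hand",
        trial_index=0,
        phase="training",
        onset_t_s=onset,
        stimulus_duration_s=duration,
        assignment=assignment,
        times_s=np.arange(len(positions)) / FS,
        positions_cm=positions,
        chamber=CH,
        shock=ShockSpec(),
        armed=shocked is not None,
    )


def occupancy_positions(t_focal_s, t_safe_s, focal="left", onset=3.0):
    """Trace spending t_focal_s on the focal half then t_safe_s opposite."""
    n_pre = int(onset * FS)
    n_f = int(t_focal_s * FS)
    n_s = int(t_safe_s * FS)
    focal_pos, safe_pos = (5.0, 20.0) if focal == "left" else (20.0, 5.0)
    return [focal_pos] * (n_pre + n_f) + [safe_pos] * (n_s + 1)


class TestPreferenceIndex:
    def test_hand_built_10s_4s(self):
        """10 s safe / 4 s on the danger side gives PI = 6/14."""
        s = make_slice(occupancy_positions(4.0, 10.0))
        pi, t_safe, t_focal = preference_index(s)
        assert t_safe == pytest.approx(10.0)
        assert t_focal == pytest.approx(4.0)
        assert pi == pytest.approx(6.0 / 14.0)

    def test_equal_occupancy_is_zero(self):
        pi, *_ = preference_index(make_slice(occupancy_positions(7.0, 7.0)))
        assert pi == pytest.approx(0.0)

    def test_full_avoidance_hits_bound(self):
        pi, *_ = preference_index(make_slice(occupancy_positions(0.0, 14.0)))
        assert pi == 1.0

    @given(st.integers(min_value=0, max_value=224))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry_under_side_swap_and_bounds(self, n_focal):
        t_f = n_focal / FS
        t_s = 14.0 - t_f
        a = make_slice(occupancy_positions(t_f, t_s, focal="left"), focal="left")
        # mirror the trace about the midline and swap the focal side
        mirrored = CH.length_cm - a.positions_cm
        b = make_slice(mirrored, focal="left")
        pi_a, *_ = preference_index(a)
        pi_b, *_ = preference_index(b)
        assert pi_a == pytest.approx(-pi_b)
        assert -1.0 <= pi_a <= 1.0

    def test_occupancy_conservation(self):
        s = make_slice(occupancy_positions(5.3, 8.7))
        _, t_safe, t_focal = preference_index(s)
        assert t_safe + t_focal == pytest.approx(14.0, abs=1.0 / FS)

    def test_midline_counts_left(self):
        # a bee parked exactly on the midline is on the left half
        pos = [13.0] * (3 * 16 + 14 * 16 + 1)
        pi, t_safe, t_focal = preference_index(make_slice(pos, focal="left"))
        assert t_focal == pytest.approx(14.0)
        assert pi == -1.0


class TestCountShocks:
    def test_full_occupancy_gets_all_44(self):
        s = make_slice(occupancy_positions(14.0, 0.0), shocked="left")
        assert count_shocks(s, mode="fictive") == 44

    def test_leaves_before_shock_onset_gets_zero(self):
        s = make_slice(occupancy_positions(2.5, 11.5), shocked="left")
        assert count_shocks(s, mode="fictive") == 0

    def test_crossing_at_8_5s_gets_22(self):
        """Pulses at 3 + k/4 with k such that time < 8.5 s: exactly 22."""
        s = make_slice(occupancy_positions(8.5, 5.5), shocked="left")
        expected = sum(1 for t in shock_pulse_times(ShockSpec()) if t < 8.5)
        assert expected == 22
        assert count_shocks(s, mode="fictive") == 22

    @given(st.floats(min_value=0.0, max_value=14.0), st.floats(min_value=0.0, max_value=14.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_focal_occupancy(self, stay1, stay2):
        stay1, stay2 = sorted(
            (round(stay1 * FS) / FS, round(stay2 * FS) / FS)
        )
        c1 = count_shocks(
            make_slice(occupancy_positions(stay1, 14.0 - stay1), shocked="left"),
            mode="fictive",
        )
        c2 = count_shocks(
            make_slice(occupancy_positions(stay2, 14.0 - stay2), shocked="left"),
            mode="fictive",
        )
        assert 0 <= c1 <= c2 <= 44


class TestSpeeds:
    def test_stationary_is_zero(self):
        t = np.arange(0, 100) / FS
        assert window_speed(t, np.full_like(t, 5.0), 0.0, 3.0) == 0.0

    def test_constant_speed_identity(self):
        t = np.arange(0, 49) / FS
        p = 4.0 * t  # 4 cm/s straight walk
        assert window_speed(t, p, 0.0, 3.0) == pytest.approx(4.0)

    def test_back_and_forth_matches_brute_force(self):
        rng = np.random.default_rng(5)
        steps = rng.uniform(-0.4, 0.4, size=48)
        p = np.concatenate([[10.0], 10.0 + np.cumsum(steps)])
        t = np.arange(len(p)) / FS
        assert window_speed(t, p, 0.0, 3.0) == pytest.approx(
            np.abs(steps).sum() / 3.0
        )

    def test_speed_invariant_under_midline_reflection(self):
        rng = np.random.default_rng(6)
        p = np.clip(13 + np.cumsum(rng.uniform(-0.5, 0.5, 60)), 0, 26)
        t = np.arange(len(p)) / FS
        assert window_speed(t, p, 0.0, 3.0) == pytest.approx(
            window_speed(t, 26.0 - p, 0.0, 3.0)
        )

    def test_window_outside_coverage_raises(self):
        t = np.arange(0, 10) / FS
        with pytest.raises(StructuralError):
            window_speed(t, np.zeros_like(t), 5.0, 8.0)

    def test_pre_post_windows(self):
        # unchanged walk: pre ~ post
        t = np.arange(0, int(17 * FS) + 1) / FS
        p = 13.0 + 2.0 * np.sin(2 * np.pi * t / 5)
        s = make_slice(p)
        pre, post = pre_post_speed(s)
        assert pre == pytest.approx(post, rel=0.35)


class TestDeltaSpeed:
    def _table(self, train_pre, train_post, test_pre, test_post):
        return pd.DataFrame(
            [
                {"phase": "training", "trial_index": 0,
                 "speed_pre_cm_s": train_pre, "speed_post_cm_s": train_post},
                {"phase": "test", "trial_index": 9,
                 "speed_pre_cm_s": test_pre, "speed_post_cm_s": test_post},
            ]
        )

    def test_identical_speeds_give_zero(self):
        d = delta_speed(self._table(4.0, 4.0, 4.0, 4.0))
        assert d["delta_speed_post_cm_s"] == 0.0
        assert d["delta_speed_post_pct"] == 0.0

    def test_printed_group_level_example(self):
        """Post speeds 3.8 -> 5.2 cm/s: Δ = 1.4, ~+36.8%."""
        d = delta_speed(self._table(4.0, 3.8, 4.0, 5.2))
        assert d["delta_speed_post_cm_s"] == pytest.approx(1.4)
        assert d["delta_speed_post_pct"] == pytest.approx(36.84, abs=0.01)

    def test_missing_phase_is_an_error(self):
        df = self._table(4, 4, 4, 4)
        with pytest.raises(StructuralError):
            delta_speed(df[df["phase"] == "training"])


class TestExclusion:
    def _metrics(self, speeds_by_bee):
        rows = []
        for bee, speeds in speeds_by_bee.items():
            for i, v in enumerate(speeds):
                rows.append(
                    {"bee_id": bee, "phase": "test", "trial_index": 9 + i,
                     "speed_trial_cm_s": v}
                )
        return pd.DataFrame(rows)

    def test_slow_bee_excluded_threshold_strict(self):
        flags = apply_exclusion(
            self._metrics({"slow": [1.0, 1.5], "edge": [2.0, 2.0], "fast": [4.0, 4.0]})
        )
        assert bool(flags["slow"])
        assert not bool(flags["edge"])  # "lower than 2 cm/s" is strict
        assert not bool(flags["fast"])

    def test_cohort_exclusion_rate(self):
        """34 slow bees out of 279 is a 12% exclusion rate."""
        speeds = {f"b{i}": [1.0] if i < 34 else [4.0] for i in range(279)}
        flags = apply_exclusion(self._metrics(speeds))
        rate = 100.0 * flags.sum() / len(flags)
        assert flags.sum() == 34
        assert round(rate) == 12

    def test_no_assessment_trials_is_an_error(self):
        df = pd.DataFrame(
            [{"bee_id": "x", "phase": "training", "trial_index": 0,
              "speed_trial_cm_s": 3.0}]
        )
        with pytest.raises(StructuralError):
            apply_exclusion(df)


class TestSummaries:
    def test_two_bee_mean_and_sem(self):
        df = pd.DataFrame(
            [
                {"bee_id": "a", "paradigm": "reinforced", "protocol": "p",
                 "phase": "test", "trial_index": 9, "pi": 0.2, "shocks": 0,
                 "speed_pre_cm_s": 4, "speed_post_cm_s": 4, "speed_trial_cm_s": 4},
                {"bee_id": "b", "paradigm": "reinforced", "protocol": "p",
                 "phase": "test", "trial_index": 9, "pi": 0.4, "shocks": 2,
                 "speed_pre_cm_s": 4, "speed_post_cm_s": 4, "speed_trial_cm_s": 4},
            ]
        )
        out = summarize_cohort(df)
        assert out["pi_mean"].iloc[0] == pytest.approx(0.3)
        assert out["pi_sem"].iloc[0] == pytest.approx(0.1)

    def test_singleton_group_flagged(self):
        df = pd.DataFrame(
            [{"bee_id": "a", "paradigm": "x", "protocol": "p", "phase": "test",
              "trial_index": 9, "pi": 0.2, "shocks": 0, "speed_pre_cm_s": 4,
              "speed_post_cm_s": 4, "speed_trial_cm_s": 4}]
        )
        out = summarize_cohort(df)
        assert out["pi_mean"].iloc[0] == 0.2
        assert np.isnan(out["pi_sem"].iloc[0])


class TestSegmentation:
    def test_expI_log_yields_13_slices(self, bg_reinforced):
        proto, traces, events, records, _ = bg_reinforced
        slices = segment_trials(traces[0], events, proto)
        assert len(slices) == 13
        phases = [s.phase for s in slices]
        assert phases.count("training") == 9 and phases.count("test") == 4

    def test_no_light_events_gives_empty(self, bg_reinforced):
        proto, traces, events, records, _ = bg_reinforced
        empty = events[events["kind"] == "shock_pulse"]
        assert segment_trials(traces[0], empty, proto) == []

    def test_recomputed_sides_match_logged(self, bg_reinforced):
        """The side map rebuilt from trace + events equals the simulator's
        own closed-loop resolution (bee side light is λ+ = B)."""
        proto, traces, events, records, _ = bg_reinforced
        for tr in traces[:4]:
            for s in segment_trials(tr, events, proto):
                assert s.assignment.stimulus_on(s.assignment.bee_side).label == "B"
                if s.assignment.shocked_side is not None:
                    assert s.assignment.shocked_side == s.assignment.bee_side

    def test_trial_metrics_table_shapes(self, bg_reinforced):
        proto, traces, events, records, tm = bg_reinforced
        assert set(tm["bee_id"]) == {t.bee_id for t in traces}
        per_bee = tm.groupby("bee_id").size()
        assert (per_bee == 13).all()
        assert tm["pi"].between(-1, 1).all()
        assert tm["shocks"].between(0, 44).all()
        assert (tm.loc[tm["phase"] == "training", "mode"] == "actual").all()
        assert (tm.loc[tm["phase"] == "test", "mode"] == "fictive").all()

    def test_bee_summary_joins_paradigm(self, bg_reinforced):
        proto, traces, events, records, tm = bg_reinforced
        summary = bee_summary_table(tm, records)
        assert (summary["paradigm"] == "reinforced").all()
        assert summary["excluded"].isin([True, False]).all()
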