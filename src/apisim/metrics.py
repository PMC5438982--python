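"""Behavioral metrics: trial segmentation, Preference Index, shock counts,
windowed speeds, ΔSpeed, exclusion filtering and cohort summaries.

Conventions (applied uniformly):

* Occupancy is accumulated per 16 Hz sample (rectangle rule); samples on
  the exact midline count as *left*, matching the chamber tie-break.
* PI = (t_safe − t_focal) / (t_safe + t_focal) where the *focal* side
  carries the λ+ / probed / reference stimulus, so PI > 0 means time away
  from the danger (or probed) light.  The denominator is the summed
  occupancy, which equals the analyzed stimulus duration when no samples
  are dropped.
* Fictive shocks re-run the 4 Hz pulse schedule against the recorded trace:
  a pulse counts if the nearest preceding trace sample lies on the focal
  (λ+) side.
* Speed over a window is the summed absolute displacement between
  consecutive samples divided by the window length.
* Bees averaging < 2 cm/s over the test trials (full 14 s stimulus window)
  are flagged excluded; the threshold is strict, 2.0 cm/s exactly is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .arena import (
    ChamberSpec,
    ProtocolSpec,
    ShockSpec,
    SideAssignment,
    shock_pulse_times,
)
from .io import PositionTrace, BeeRecord

__all__ = [
    "TrialSlice",
    "TrialMetrics",
    "segment_trials",
    "preference_index",
    "count_shocks",
    "window_speed",
    "pre_post_speed",
    "trial_metrics_table",
    "delta_speed",
    "apply_exclusion",
    "bee_summary_table",
    "summarize_cohort",
    "EXCLUSION_THRESHOLD_CM_S",
]

EXCLUSION_THRESHOLD_CM_S = 2.0
PRE_POST_WINDOW_S = 3.0


class StructuralError(ValueError):
    """The data lack the structure an operation requires."""


@dataclass
class TrialSlice:
    """One trial's analysis window: trace segment over [onset−3 s,
    onset+14 s] (endpoint sample included for speed windows; occupancy
    always uses the half-open stimulus window) plus the resolved
    side→stimulus map."""

    bee_id: str
    trial_index: int
    phase: str
    onset_t_s: float
    stimulus_duration_s: float
    assignment: SideAssignment
    times_s: np.ndarray
    positions_cm: np.ndarray
    chamber: ChamberSpec
    shock: Optional[ShockSpec] = None
    armed: bool = False  # shocks were available on the focal side this trial
    tag: str = ""
    partial: bool = False

    @property
    def safe_side(self) -> str:
        return "left" if self.assignment.focal_side == "right" else "right"


@dataclass
class TrialMetrics:
    bee_id: str
    trial_index: int
    phase: str
    tag: str
    t_safe_s: float
    t_focal_s: float
    pi: float
    shocks: int
    mode: Literal["actual", "fictive"]
    speed_pre_cm_s: float
    speed_post_cm_s: float
    speed_trial_cm_s: float


def segment_trials(
    trace: PositionTrace,
    events: pd.DataFrame,
    protocol: Optional[ProtocolSpec] = None,
) -> list[TrialSlice]:
    """Cut the trace into per-trial analysis windows from the event log.

    Onsets come from ``light_on`` events; the side assignment is rebuilt
    from the logged sides and labels.  When a protocol is supplied it
    provides the focal role and shock spec per trial; otherwise the bee
    side is taken as focal (the λ+ convention of the conditioning trials).
    """
    ev = events[events["bee_id"] == trace.bee_id]
    lights_on = ev[ev["kind"] == "light_on"]
    if lights_on.empty:
        return []
    fs = trace.chamber.sample_rate_hz

    slices: list[TrialSlice] = []
    for trial_i, grp in lights_on.groupby("trial_index"):
        onset = float(grp["t_s"].min())
        trial = protocol.trials[int(trial_i)] if protocol is not None else None
        dur = trial.stimulus_duration_s if trial is not None else 14.0

        k_on = int(np.searchsorted(trace.times_s, onset - 1e-9))
        if k_on >= len(trace) or abs(trace.times_s[k_on] - onset) > 0.5 / fs:
            raise StructuralError(
                f"{trace.bee_id} trial {trial_i}: no trace sample at onset {onset}"
            )
        pos_onset = float(trace.positions_cm[k_on])
        bee_side = trace.chamber.side_of(pos_onset)

        side_src: dict[str, tuple[str, float]] = {}
        for _, row in grp.iterrows():
            side_src[row["side"]] = (row["label"], float(row["intensity_pct"]))
        from .arena import DARK, light as mk_light

        def src_for(side: str):
            if side in side_src:
                lbl, pct = side_src[side]
                return mk_light(lbl, pct) if lbl != "DARK" else DARK
            return DARK

        shocked = ev[
            (ev["kind"] == "shock_pulse") & (ev["trial_index"] == trial_i)
        ]
        shocked_side = str(shocked["side"].iloc[0]) if len(shocked) else None
        focal_role = trial.focal_role if trial is not None else "bee"
        focal = bee_side if focal_role == "bee" else (
            "left" if bee_side == "right" else "right"
        )
        assignment = SideAssignment(
            trial_index=int(trial_i),
            bee_side=bee_side,
            left_stimulus=src_for("left"),
            right_stimulus=src_for("right"),
            focal_side=focal,
            shocked_side=shocked_side,
        )

        # one sample past onset+14 s so speed over [t, t+w] has its full
        # complement of displacement intervals
        t0, t1 = onset - PRE_POST_WINDOW_S, onset + dur
        mask = (trace.times_s >= t0 - 1e-9) & (trace.times_s <= t1 + 1e-9)
        seg_t = trace.times_s[mask]
        seg_p = trace.positions_cm[mask]
        expected = int(round((t1 - t0) * fs)) + 1
        slices.append(
            TrialSlice(
                bee_id=trace.bee_id,
                trial_index=int(trial_i),
                phase=str(grp["phase"].iloc[0]),
                onset_t_s=onset,
                stimulus_duration_s=dur,
                assignment=assignment,
                times_s=seg_t,
                positions_cm=seg_p,
                chamber=trace.chamber,
                shock=trial.shock if trial is not None else (
                    ShockSpec() if shocked_side else None
                ),
                armed=(
                    trial.shock_on_bee_side and trial.shock is not None
                    if trial is not None
                    else shocked_side is not None
                ),
                tag=trial.tag if trial is not None else "",
                partial=len(seg_t) < expected,
            )
        )
    slices.sort(key=lambda s: s.trial_index)
    return slices


def _sides(slice_: TrialSlice, mask: np.ndarray) -> np.ndarray:
    """Boolean array: True where the sample lies on the focal side."""
    left = slice_.positions_cm[mask] <= slice_.chamber.midline_cm
    return left if slice_.assignment.focal_side == "left" else ~left


def preference_index(slice_: TrialSlice) -> tuple[float, float, float]:
    """(pi, t_safe_s, t_focal_s) over the stimulus window.

    PI > 0 = time spent away from the focal (λ+/probed) side.
    """
    fs = slice_.chamber.sample_rate_hz
    t0, t1 = slice_.onset_t_s, slice_.onset_t_s + slice_.stimulus_duration_s
    mask = (slice_.times_s >= t0 - 1e-9) & (slice_.times_s < t1 - 1e-9)
    if not mask.any():
        raise StructuralError(
            f"{slice_.bee_id} trial {slice_.trial_index}: empty stimulus window"
        )
    on_focal = _sides(slice_, mask)
    t_focal = float(on_focal.sum()) / fs
    t_safe = float((~on_focal).sum()) / fs
    return (t_safe - t_focal) / (t_safe + t_focal), t_safe, t_focal


def count_shocks(
    slice_: TrialSlice,
    events: Optional[pd.DataFrame] = None,
    mode: Literal["actual", "fictive"] = "fictive",
) -> int:
    """Delivered (actual) or would-have-been-delivered (fictive) pulses.

    Fictive counting replays the pulse schedule over seconds 3–14 of the
    trial: a pulse counts when the nearest preceding trace sample sits on
    the focal (λ+) side.
    """
    if mode == "actual":
        if events is None:
            raise StructuralError("actual mode needs the event log")
        ev = events[
            (events["bee_id"] == slice_.bee_id)
            & (events["kind"] == "shock_pulse")
            & (events["trial_index"] == slice_.trial_index)
        ]
        return int(len(ev))

    shock = slice_.shock or ShockSpec()
    pulse_t = np.asarray(shock_pulse_times(shock)) + slice_.onset_t_s
    if len(slice_.times_s) == 0:
        raise StructuralError("empty slice")
    # nearest preceding sample (causal)
    idx = np.searchsorted(slice_.times_s, pulse_t + 1e-9) - 1
    valid = idx >= 0
    idx = idx[valid]
    left = slice_.positions_cm[idx] <= slice_.chamber.midline_cm
    on_focal = left if slice_.assignment.focal_side == "left" else ~left
    return int(on_focal.sum())


def window_speed(trace_t: np.ndarray, trace_p: np.ndarray, t0: float, t1: float) -> float:
    """Absolute distance covered between t0 and t1 divided by the window
    length (samples at both endpoints included, so a constant-speed walk
    returns its speed exactly)."""
    if t0 >= t1:
        raise StructuralError("window must have t0 < t1")
    mask = (trace_t >= t0 - 1e-9) & (trace_t <= t1 + 1e-9)
    if mask.sum() < 2:
        raise StructuralError(f"trace does not cover window [{t0}, {t1}]")
    p = trace_p[mask]
    return float(np.abs(np.diff(p)).sum()) / (t1 - t0)


def pre_post_speed(slice_: TrialSlice) -> tuple[float, float]:
    """Speeds over the 3 s windows just before and just after light onset."""
    on = slice_.onset_t_s
    w = PRE_POST_WINDOW_S
    pre = window_speed(slice_.times_s, slice_.positions_cm, on - w, on)
    post = window_speed(slice_.times_s, slice_.positions_cm, on, on + w)
    return pre, post


def trial_metrics_table(
    trace: PositionTrace,
    events: pd.DataFrame,
    protocol: Optional[ProtocolSpec] = None,
) -> pd.DataFrame:
    """Tidy per-trial metrics for one bee (one row per trial)."""
    rows = []
    for s in segment_trials(trace, events, protocol):
        pi, t_safe, t_focal = preference_index(s)
        mode = "actual" if s.armed else "fictive"
        shocks = (
            count_shocks(s, events, "actual")
            if s.armed
            else count_shocks(s, mode="fictive")
        )
        pre, post = pre_post_speed(s)
        trial_speed = window_speed(
            s.times_s, s.positions_cm, s.onset_t_s, s.onset_t_s + s.stimulus_duration_s
        )
        rows.append(
            {
                "bee_id": s.bee_id,
                "trial_index": s.trial_index,
                "phase": s.phase,
                "tag": s.tag,
                "t_safe_s": t_safe,
                "t_focal_s": t_focal,
                "pi": pi,
                "shocks": shocks,
                "mode": mode,
                "speed_pre_cm_s": pre,
                "speed_post_cm_s": post,
                "speed_trial_cm_s": trial_speed,
            }
        )
    return pd.DataFrame(rows)


def delta_speed(bee_trials: pd.DataFrame) -> dict[str, float]:
    """ΔSpeed: first test trial minus first training trial, pre and post.

    Returns Δpre, Δpost (cm/s) and each as a percentage of the first
    training trial's value.
    """
    needed = {"phase", "trial_index", "speed_pre_cm_s", "speed_post_cm_s"}
    if not needed <= set(bee_trials.columns):
        raise StructuralError(f"trial table missing columns {needed - set(bee_trials.columns)}")
    train = bee_trials[bee_trials["phase"] == "training"].sort_values("trial_index")
    test = bee_trials[bee_trials["phase"] == "test"].sort_values("trial_index")
    if train.empty or test.empty:
        raise StructuralError("ΔSpeed needs at least one training and one test trial")
    first_train = train.iloc[0]
    first_test = test.iloc[0]
    d_pre = float(first_test["speed_pre_cm_s"] - first_train["speed_pre_cm_s"])
    d_post = float(first_test["speed_post_cm_s"] - first_train["speed_post_cm_s"])
    pct = lambda d, v0: float("nan") if v0 == 0 else 100.0 * d / v0
    return {
        "delta_speed_pre_cm_s": d_pre,
        "delta_speed_post_cm_s": d_post,
        "delta_speed_pre_pct": pct(d_pre, float(first_train["speed_pre_cm_s"])),
        "delta_speed_post_pct": pct(d_post, float(first_train["speed_post_cm_s"])),
    }


def _assessment_trials(trial_metrics: pd.DataFrame) -> pd.DataFrame:
    """Trials the slow-bee criterion is evaluated on: the test phase, or the
    preference trials for pure preference protocols (where they are the
    assessment)."""
    for phase in ("test", "preference"):
        sel = trial_metrics[trial_metrics["phase"] == phase]
        if not sel.empty:
            return sel
    raise StructuralError("no test or preference trials to assess speed on")


def apply_exclusion(
    trial_metrics: pd.DataFrame,
    threshold_cm_s: float = EXCLUSION_THRESHOLD_CM_S,
) -> pd.Series:
    """Exclusion flags (index bee_id): mean full-trial speed over the test
    trials strictly below the threshold.  Excluded bees stay in the raw
    data; only the flag is recorded."""
    sel = _assessment_trials(trial_metrics)
    mean_speed = sel.groupby("bee_id")["speed_trial_cm_s"].mean()
    return mean_speed < threshold_cm_s


def bee_summary_table(
    trial_metrics: pd.DataFrame,
    records: Optional[Iterable[BeeRecord]] = None,
    threshold_cm_s: float = EXCLUSION_THRESHOLD_CM_S,
) -> pd.DataFrame:
    """Per-bee summary: ΔSpeed (pre/post, cm/s and %), mean test speed and
    the exclusion flag; paradigm/protocol joined from the records."""
    flags = apply_exclusion(trial_metrics, threshold_cm_s)
    mean_speed = _assessment_trials(trial_metrics).groupby("bee_id")[
        "speed_trial_cm_s"
    ].mean()
    meta = {}
    if records is not None:
        meta = {r.bee_id: (r.paradigm, r.protocol_name) for r in records}
    rows = []
    for bee_id, grp in trial_metrics.groupby("bee_id"):
        try:
            ds = delta_speed(grp)
        except StructuralError:
            ds = {
                "delta_speed_pre_cm_s": np.nan,
                "delta_speed_post_cm_s": np.nan,
                "delta_speed_pre_pct": np.nan,
                "delta_speed_post_pct": np.nan,
            }
        paradigm, proto = meta.get(bee_id, ("", ""))
        rows.append(
            {
                "bee_id": bee_id,
                "paradigm": paradigm,
                "protocol": proto,
                **ds,
                "mean_test_speed_cm_s": float(mean_speed.get(bee_id, np.nan)),
                "excluded": bool(flags.get(bee_id, False)),
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(
    trial_metrics: pd.DataFrame,
    bee_summary: Optional[pd.DataFrame] = None,
    drop_excluded: bool = True,
) -> pd.DataFrame:
    """Per-(paradigm, protocol, phase, trial) mean ± SEM of PI, shocks and
    speeds over non-excluded bees.  SEM is NaN for singleton groups."""
    df = trial_metrics.copy()
    if bee_summary is not None:
        df = df.merge(
            bee_summary[["bee_id", "paradigm", "protocol", "excluded"]],
            on="bee_id",
            how="left",
        )
        if drop_excluded:
            df = df[~df["excluded"].fillna(False)]
    else:
        for col in ("paradigm", "protocol"):
            if col not in df.columns:
                df[col] = ""
    if df.empty:
        raise StructuralError("no analyzable bees after exclusion")
    value_cols = ["pi", "shocks", "speed_pre_cm_s", "speed_post_cm_s", "speed_trial_cm_s"]
    grouped = df.groupby(["paradigm", "protocol", "phase", "trial_index"])
    out = grouped[value_cols].agg(["mean", "sem", "count"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
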