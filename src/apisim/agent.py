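"""Agent-based walking-bee simulator under the closed-loop protocol.

The agent is a persistent random walker on the 1-D chamber whose direction
is biased by a side-utility signal:

    U(side) = a(λ, I) − max(0, V(λ) − s(λ))

where ``a`` is a saturating phototactic attractiveness of the light on that
side, ``V`` the aversion acquired for the light's wavelength (a
Rescorla–Wagner-style update driven by each delivered shock pulse), and
``s`` a wavelength-specific *safety prior* subtracted before the aversion is
expressed as place avoidance.  A large green safety prior reproduces the
asymmetry at the heart of the assay: shocks paired with green raise ``V``
(so the bee still speeds up in anticipation) but never produce avoidance.

Delivered pulses also boost walking speed for the rest of the pulse train
(shock-driven escape), and acquired aversion scales an anticipatory speed
increase at light onset.  Positions are quantized to the sensor pitch before
logging, and all side decisions use the quantized value, so re-deriving
shock delivery from the recorded trace reproduces the logged events exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .arena import (
    ChamberSpec,
    ProtocolSpec,
    SideAssignment,
    resolve_sides,
    shock_pulse_times,
)
from .io import BeeRecord, EVENT_COLUMNS, PositionTrace

__all__ = ["AgentParams", "AgentState", "step_agent", "simulate_bee", "simulate_cohort"]

#: Relative phototactic strength of each LED at full intensity.  Green is
#: the innately preferred light; the ordering and the 40% half-saturation
#: put the intensity-balance points for green near 62% (vs blue) and 46%
#: (vs yellow).
DEFAULT_ATTRACTIVENESS = {"B": 0.85, "G": 1.0, "Y": 0.75}

#: Safety prior per wavelength: subtracted from acquired aversion before it
#: is expressed as place avoidance.  Green's exceeds the aversion asymptote,
#: so aversion of green is acquired (driving shock anticipation) but never
#: expressed as avoidance; the small blue/yellow floor keeps late-training
#: avoidance at the moderate levels walking bees actually show.
DEFAULT_SAFETY_PRIOR = {"B": 0.55, "G": 1.2, "Y": 0.55}


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of the simulated bee (speeds in cm/s)."""

    base_speed_cm_s: float = 4.0
    speed_sd: float = 1.0
    persistence: float = 0.995
    attractiveness: dict = field(
        default_factory=lambda: dict(DEFAULT_ATTRACTIVENESS)
    )
    intensity_half_sat_pct: float = 40.0
    learning_rate_alpha: float = 0.03
    aversion_max: float = 1.0
    safety_prior: dict = field(default_factory=lambda: dict(DEFAULT_SAFETY_PRIOR))
    shock_speed_factor: float = 1.5
    shock_pain_drive: float = 2.0
    anticipation_gain: float = 0.35
    crossing_gain: float = 0.015
    quantize_positions: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must be in [0, 1]")
        if not (0.0 <= self.learning_rate_alpha <= 1.0):
            raise ValueError("learning rate must be in [0, 1]")
        if self.base_speed_cm_s <= 0 or self.shock_speed_factor <= 0:
            raise ValueError("speeds must be positive")

    def attraction(self, label: str, intensity_pct: float) -> float:
        """Saturating phototactic drive a(λ, I) = A_λ · I / (I + h)."""
        if label == "DARK" or intensity_pct <= 0:
            return 0.0
        A = self.attractiveness.get(label, 0.0)
        return A * intensity_pct / (intensity_pct + self.intensity_half_sat_pct)


@dataclass
class AgentState:
    position_cm: float
    direction: int = 1
    learned_aversion: dict = field(default_factory=dict)
    trial_index: int = -1
    time_s: float = 0.0

    def expressed_aversion(self, label: str, params: AgentParams) -> float:
        v = self.learned_aversion.get(label, 0.0)
        return max(0.0, v - params.safety_prior.get(label, 0.0))


def _utility(state: AgentState, src, params: AgentParams) -> float:
    return params.attraction(src.label, src.intensity_pct) - state.expressed_aversion(
        src.label, params
    )


def step_agent(
    state: AgentState,
    side_stimuli: Optional[SideAssignment],
    pulse_active: bool,
    params: AgentParams,
    rng: np.random.Generator,
    chamber: ChamberSpec = ChamberSpec(),
) -> AgentState:
    """Advance the agent one sample (1/sample_rate s).

    ``side_stimuli`` is None in darkness (between trials).  ``pulse_active``
    marks a shock pulse delivered to the bee at this sample; it both boosts
    speed and drives the per-pulse aversion update for the light on the
    bee's current side.
    """
    dt = 1.0 / chamber.sample_rate_hz
    V = dict(state.learned_aversion)
    new = AgentState(
        position_cm=state.position_cm,
        direction=state.direction,
        learned_aversion=V,
        trial_index=state.trial_index,
        time_s=state.time_s + dt,
    )

    if side_stimuli is not None:
        here = chamber.side_of(state.position_cm)
        ahead = "right" if state.direction > 0 else "left"
        behind = "left" if ahead == "right" else "right"
        u_ahead = _utility(state, side_stimuli.stimulus_on(ahead), params)
        u_behind = _utility(state, side_stimuli.stimulus_on(behind), params)
        if pulse_active and here == side_stimuli.shocked_side:
            # acute escape drive off the electrified side
            if ahead == here:
                u_ahead -= params.shock_pain_drive
            else:
                u_behind -= params.shock_pain_drive
        p_flip = (1.0 - params.persistence) + params.crossing_gain * (u_behind - u_ahead)
        anticipation = 1.0 + params.anticipation_gain * max(
            V.get(side_stimuli.left_stimulus.label, 0.0),
            V.get(side_stimuli.right_stimulus.label, 0.0),
        )
        if pulse_active:
            lbl = side_stimuli.stimulus_on(here).label
            v = V.get(lbl, 0.0)
            V[lbl] = v + params.learning_rate_alpha * (params.aversion_max - v)
    else:
        p_flip = 1.0 - params.persistence
        anticipation = 1.0

    if rng.random() < min(1.0, max(0.0, p_flip)):
        new.direction = -new.direction

    speed = abs(rng.normal(params.base_speed_cm_s, params.speed_sd)) * anticipation
    if pulse_active:
        speed *= params.shock_speed_factor
    pos = new.position_cm + new.direction * speed * dt
    if pos < 0.0:
        pos, new.direction = -pos, 1
    elif pos > chamber.length_cm:
        pos, new.direction = 2 * chamber.length_cm - pos, -1
    new.position_cm = min(max(pos, 0.0), chamber.length_cm)
    return new


def simulate_bee(
    protocol: ProtocolSpec,
    params: AgentParams,
    seed,
    bee_id: str = "bee0",
) -> tuple[PositionTrace, pd.DataFrame]:
    """Run one bee through a protocol; returns (trace, event log).

    The loop mirrors the closed-loop controller: at each trial onset the
    side assignment is resolved from the bee's (sensor-quantized) position,
    lights are switched, and — in reinforced trials — pulses are delivered
    only while the bee occupies the shocked side.  Events are emitted for
    phase marks, every light on/off per illuminated side, and every
    delivered pulse.

    The hot loop is written with pre-drawn random arrays and scalar float
    arithmetic (an inlined :func:`step_agent`) so cohorts stay cheap; the
    two paths are kept equivalent by a regression test.
    """
    rng = np.random.default_rng(seed)
    chamber = protocol.chamber
    fs = chamber.sample_rate_hz
    dt = 1.0 / fs
    n = int(round(protocol.duration_s * fs))
    quantize = params.quantize_positions

    # trial schedule in sample indices
    onsets = [protocol.trial_onset_s(i) for i in range(protocol.n_trials)]
    trial_at = np.full(n, -1, dtype=np.int64)  # active (lit) trial per sample
    for i, t0 in enumerate(onsets):
        k0 = int(round(t0 * fs))
        k1 = int(round((t0 + protocol.trials[i].stimulus_duration_s) * fs))
        trial_at[k0:min(k1, n)] = i
    pulse_offsets = {
        i: {int(round(t * fs)) for t in shock_pulse_times(tr.shock)}
        for i, tr in enumerate(protocol.trials)
        if tr.shock is not None and tr.shock_on_bee_side
    }

    flips = rng.random(n)
    speeds = np.abs(rng.normal(params.base_speed_cm_s, params.speed_sd, size=n))
    pos = float(rng.uniform(0.0, chamber.length_cm))
    direction = 1 if rng.random() < 0.5 else -1

    length = chamber.length_cm
    midline = chamber.midline_cm
    pitch = chamber.sensor_pitch_cm
    n_sensors = chamber.n_sensors
    base_flip = 1.0 - params.persistence
    gain = params.crossing_gain
    ant_gain = params.anticipation_gain
    boost = params.shock_speed_factor
    pain = params.shock_pain_drive
    alpha = params.learning_rate_alpha
    v_max = params.aversion_max
    safety = params.safety_prior

    V: dict[str, float] = {}
    positions = np.empty(n)
    events: list[tuple] = [
        (bee_id, 0.0, "phase_mark", "none", "", 0.0, -1, "habituation")
    ]
    assignment: Optional[SideAssignment] = None
    assignments: dict[int, SideAssignment] = {}
    u_left = u_right = 0.0
    boost_until = -1.0
    active_trial = -1

    def q(x: float) -> tuple[float, int]:
        idx = min(int(x / pitch), n_sensors - 1)
        return (idx + 0.5) * pitch, idx

    for k in range(n):
        t = k * dt
        qpos = q(pos)[0] if quantize else pos
        positions[k] = qpos
        trial_i = int(trial_at[k])

        if trial_i != active_trial:
            if active_trial >= 0:  # light offset of the trial just ended
                tr = protocol.trials[active_trial]
                a = assignments[active_trial]
                for side in ("left", "right"):
                    src = a.stimulus_on(side)
                    if not src.is_dark:
                        events.append(
                            (bee_id, t, "light_off", side, src.label,
                             src.intensity_pct, active_trial, tr.phase)
                        )
                assignment = None
            if trial_i >= 0:  # light onset: resolve the closed loop
                tr = protocol.trials[trial_i]
                assignment = resolve_sides(qpos, chamber, tr)
                assignments[trial_i] = assignment
                for side in ("left", "right"):
                    src = assignment.stimulus_on(side)
                    if not src.is_dark:
                        events.append(
                            (bee_id, t, "light_on", side, src.label,
                             src.intensity_pct, trial_i, tr.phase)
                        )
                la, ra = assignment.left_stimulus, assignment.right_stimulus
                boost_until = -1.0
            active_trial = trial_i

        pulse = False
        if assignment is not None:
            # per-sample expressed utilities (V may change within the trial)
            def util(src) -> float:
                if src.is_dark:
                    a_drive = 0.0
                else:
                    a_drive = params.attraction(src.label, src.intensity_pct)
                v = V.get(src.label, 0.0)
                return a_drive - max(0.0, v - safety.get(src.label, 0.0))

            u_left, u_right = util(la), util(ra)
            onset_k = int(round(onsets[trial_i] * fs))
            if trial_i in pulse_offsets and (k - onset_k) in pulse_offsets[trial_i]:
                side_here = "left" if qpos <= midline else "right"
                if side_here == assignment.shocked_side:
                    pulse = True
                    tr = protocol.trials[trial_i]
                    events.append(
                        (bee_id, t, "shock_pulse", side_here,
                         assignment.stimulus_on(side_here).label,
                         assignment.stimulus_on(side_here).intensity_pct,
                         trial_i, tr.phase)
                    )
                    lbl = assignment.stimulus_on(side_here).label
                    v = V.get(lbl, 0.0)
                    V[lbl] = v + alpha * (v_max - v)
                    boost_until = onsets[trial_i] + tr.stimulus_duration_s
            if boost_until > t and assignment.shocked_side is not None:
                # acute escape drive while standing on the electrified side;
                # off it, only learned aversion deters returning
                side_here = "left" if qpos <= midline else "right"
                if side_here == assignment.shocked_side:
                    if side_here == "left":
                        u_left -= pain
                    else:
                        u_right -= pain
            u_ahead = u_right if direction > 0 else u_left
            u_behind = u_left if direction > 0 else u_right
            p_flip = base_flip + gain * (u_behind - u_ahead)
            anticipation = 1.0 + ant_gain * max(
                V.get(la.label, 0.0), V.get(ra.label, 0.0)
            )
        else:
            p_flip = base_flip
            anticipation = 1.0

        if flips[k] < p_flip:
            direction = -direction
        speed = speeds[k] * anticipation
        if boost_until > t:
            speed *= boost
        pos = pos + direction * speed * dt
        if pos < 0.0:
            pos, direction = -pos, 1
        elif pos > length:
            pos, direction = 2 * length - pos, -1
        pos = min(max(pos, 0.0), length)

    times = np.arange(n) / fs
    trace = PositionTrace(
        bee_id=bee_id, times_s=times, positions_cm=positions, chamber=chamber
    )
    event_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return trace, event_df


def simulate_cohort(
    protocol_family,
    n_bees: int,
    params: AgentParams,
    seed,
) -> tuple[list[PositionTrace], pd.DataFrame, list[BeeRecord]]:
    """Simulate ``n_bees`` independent bees.

    ``protocol_family`` is either a :class:`ProtocolSpec` shared by every
    bee or a callable ``(bee_index, rng) -> ProtocolSpec`` for protocols
    with per-bee pseudorandomization (the six-probe test battery).  Per-bee
    seeds are spawned deterministically from ``seed``.
    """
    if n_bees < 1:
        raise ValueError("n_bees must be >= 1")
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_bees)
    traces: list[PositionTrace] = []
    records: list[BeeRecord] = []
    frames: list[pd.DataFrame] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if callable(protocol_family) and not isinstance(protocol_family, ProtocolSpec):
            protocol = protocol_family(i, rng)
        else:
            protocol = protocol_family
        bee_id = f"bee{i:03d}"
        trace, events = simulate_bee(protocol, params, child.spawn(1)[0], bee_id)
        traces.append(trace)
        frames.append(events)
        records.append(
            BeeRecord(
                bee_id=bee_id,
                paradigm="reinforced" if protocol.reinforced else "unreinforced",
                protocol_name=protocol.name,
            )
        )
    events = pd.concat(frames, ignore_index=True)
    return traces, events, records
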