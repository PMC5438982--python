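"""Chamber geometry, light stimuli, and closed-loop trial/shock scheduling.

The conditioning chamber is a linear walking arena whose two halves can be
lit independently by narrow-band LEDs (blue 465 nm, green 525 nm, yellow
590 nm).  A bee's position along the chamber is tracked by a row of infrared
sensors at 16 Hz.  In reinforced protocols the half containing the bee at
stimulus onset (the "bee side") is lit with the danger light λ+ and
electrified 3 s later with a 4 Hz pulse train that lasts until light offset;
the opposite half carries the safety light λ− (or darkness).

This module encodes that scheduling logic as plain data plus a handful of
pure functions; it drives both the simulator and the analysis pipeline and
never touches hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import yaml

__all__ = [
    "ChamberSpec",
    "LightSource",
    "ShockSpec",
    "TrialSpec",
    "SideAssignment",
    "ProtocolSpec",
    "LED_CATALOG",
    "DARK",
    "light",
    "resolve_sides",
    "shock_pulse_times",
    "build_protocol",
    "protocol_to_yaml",
    "protocol_from_yaml",
]

Side = Literal["left", "right"]
Label = Literal["B", "G", "Y", "DARK"]


class ConfigurationError(ValueError):
    """Raised for invalid protocol / stimulus configuration."""


class CoordinateError(ValueError):
    """Raised for positions outside the chamber."""


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and sampling of the linear walking chamber.

    The chamber length is configurable; the default of 26 cm gives one
    infrared sensor per centimetre for the 26-sensor row and puts walking
    speeds in the observed 2–5 cm/s range.
    """

    length_cm: float = 26.0
    n_sensors: int = 26
    sample_rate_hz: float = 16.0

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ConfigurationError("chamber length must be positive")
        if self.n_sensors < 2:
            raise ConfigurationError("need at least 2 sensors")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample rate must be positive")

    @property
    def midline_cm(self) -> float:
        return self.length_cm / 2.0

    @property
    def sensor_pitch_cm(self) -> float:
        return self.length_cm / self.n_sensors

    def side_of(self, position_cm: float) -> Side:
        """Chamber half containing ``position_cm``.

        The midline itself counts as *left* (documented tie-break, applied
        consistently by the simulator and every metric).
        """
        if not (0.0 <= position_cm <= self.length_cm):
            raise CoordinateError(
                f"position {position_cm} cm outside chamber [0, {self.length_cm}]"
            )
        return "left" if position_cm <= self.midline_cm else "right"

    def quantize(self, position_cm: float) -> tuple[float, int]:
        """Snap a position to the centre of its sensor cell.

        Returns (quantized position, sensor index).  Mirrors the spatial
        discretization the real sensor row imposes on recorded traces.
        """
        pitch = self.sensor_pitch_cm
        idx = min(int(position_cm / pitch), self.n_sensors - 1)
        return (idx + 0.5) * pitch, idx


#: Peak wavelength (nm), bandwidth (nm) and maximum luminous intensity (mcd)
#: of the three LED arrays.
LED_CATALOG: dict[str, tuple[float, float, float]] = {
    "B": (465.0, 45.0, 105.0),
    "G": (525.0, 45.0, 310.0),
    "Y": (590.0, 25.0, 330.0),
}


@dataclass(frozen=True)
class LightSource:
    label: Label
    intensity_pct: float = 100.0
    peak_nm: Optional[float] = None
    bandwidth_nm: Optional[float] = None
    max_luminous_intensity_mcd: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.intensity_pct <= 100.0):
            raise ConfigurationError("intensity_pct must be in [0, 100]")
        if self.label == "DARK":
            if self.intensity_pct != 0.0:
                raise ConfigurationError("DARK implies intensity 0")
        elif self.label not in LED_CATALOG:
            raise ConfigurationError(f"unknown light label {self.label!r}")

    @property
    def is_dark(self) -> bool:
        return self.label == "DARK" or self.intensity_pct == 0.0


DARK = LightSource("DARK", 0.0)


def light(label: str, intensity_pct: float = 100.0) -> LightSource:
    """LED from the catalog at the given relative intensity (percent)."""
    if label == "DARK" or intensity_pct == 0.0 and label == "DARK":
        return DARK
    peak, bw, mcd = LED_CATALOG[label]
    return LightSource(label, intensity_pct, peak, bw, mcd)


@dataclass(frozen=True)
class ShockSpec:
    """Pulse-train parameters: 10 V, 100 ms pulses at 4 Hz, starting 3 s
    after light onset and sharing its offset at 14 s (44 pulses total)."""

    onset_delay_s: float = 3.0
    rate_hz: float = 4.0
    pulse_width_s: float = 0.1
    end_s: float = 14.0
    voltage_v: float = 10.0  # informational only

    def __post_init__(self) -> None:
        if self.onset_delay_s >= self.end_s:
            raise ConfigurationError("shock delay must precede shock end")
        if self.rate_hz <= 0:
            raise ConfigurationError("pulse rate must be positive")

    @property
    def n_pulses(self) -> int:
        return math.floor((self.end_s - self.onset_delay_s) * self.rate_hz)


def shock_pulse_times(shock: ShockSpec) -> list[float]:
    """Onset-relative times of every scheduled pulse: delay + k/rate."""
    return [shock.onset_delay_s + k / shock.rate_hz for k in range(shock.n_pulses)]


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the closed-loop schedule.

    ``bee_side_light`` is presented on whichever half the bee occupies at
    onset; ``opposite_side_light`` on the other half (darkness is an explicit
    DARK source, never a missing field).  ``focal_role`` names the stimulus
    whose side anchors the Preference Index sign: "bee" (the λ+ / probed
    light, the default) or "opposite" (used for the reciprocal presentations
    of the intensity series, where the reference light stays focal even when
    delivered away from the bee).
    """

    index: int
    phase: Literal["habituation", "training", "test", "preference"]
    bee_side_light: LightSource = DARK
    opposite_side_light: LightSource = DARK
    shock_on_bee_side: bool = False
    shock: Optional[ShockSpec] = None
    stimulus_duration_s: float = 14.0
    onset_to_onset_s: float = 44.0
    focal_role: Literal["bee", "opposite"] = "bee"
    tag: str = ""

    def __post_init__(self) -> None:
        if self.stimulus_duration_s > self.onset_to_onset_s:
            raise ConfigurationError("stimulus cannot outlast the trial interval")
        if self.phase == "habituation" and (
            not self.bee_side_light.is_dark
            or not self.opposite_side_light.is_dark
            or self.shock is not None
        ):
            raise ConfigurationError("habituation trials carry no lights or shocks")
        if self.shock_on_bee_side and self.shock is None:
            raise ConfigurationError("shock_on_bee_side requires a ShockSpec")


@dataclass(frozen=True)
class SideAssignment:
    """Resolved side → stimulus map for one trial onset."""

    trial_index: int
    bee_side: Side
    left_stimulus: LightSource
    right_stimulus: LightSource
    focal_side: Side
    shocked_side: Optional[Side]

    def stimulus_on(self, side: Side) -> LightSource:
        return self.left_stimulus if side == "left" else self.right_stimulus


def _other(side: Side) -> Side:
    return "right" if side == "left" else "left"


def resolve_sides(
    position_at_onset_cm: float, chamber: ChamberSpec, trial: TrialSpec
) -> SideAssignment:
    """Resolve the closed loop: the bee side gets ``bee_side_light``.

    Shock (when armed) is restricted to the bee side; the focal side follows
    ``trial.focal_role``.
    """
    bee_side = chamber.side_of(position_at_onset_cm)
    stimuli = {bee_side: trial.bee_side_light, _other(bee_side): trial.opposite_side_light}
    shocked = bee_side if (trial.shock_on_bee_side and trial.shock is not None) else None
    focal = bee_side if trial.focal_role == "bee" else _other(bee_side)
    return SideAssignment(
        trial_index=trial.index,
        bee_side=bee_side,
        left_stimulus=stimuli["left"],
        right_stimulus=stimuli["right"],
        focal_side=focal,
        shocked_side=shocked,
    )


@dataclass(frozen=True)
class ProtocolSpec:
    name: str
    trials: tuple[TrialSpec, ...]
    habituation_s: float = 120.0
    reinforced: bool = False
    experiment: str = ""
    chamber: ChamberSpec = field(default_factory=ChamberSpec)
    meta: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials):
            if t.index != i:
                raise ConfigurationError("trial indices must be consecutive from 0")
        if self.reinforced and not any(t.shock is not None for t in self.trials):
            raise ConfigurationError("reinforced protocol has no armed shocks")
        if not self.reinforced and any(t.shock is not None for t in self.trials):
            raise ConfigurationError("unreinforced protocol must not arm shocks")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_onset_s(self, index: int) -> float:
        """Session time of trial ``index``'s light onset (44 s spacing)."""
        # summed explicitly so non-uniform schedules stay correct
        return self.habituation_s + sum(
            tr.onset_to_onset_s for tr in self.trials[:index]
        )

    @property
    def duration_s(self) -> float:
        return self.habituation_s + sum(t.onset_to_onset_s for t in self.trials)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.phase] = out.get(t.phase, 0) + 1
        return out


_PAIRS = ("BG", "GB", "BY", "YB", "YG", "GY")

#: Green intensity (percent) that cancels the innate preference bias when
#: paired against B or Y at 100% (measured zero-preference intensities).
GREEN_BALANCED_PCT = {"B": 62.0, "Y": 46.0}


def _training_trials(
    plus: str, minus: str, start: int, reinforced: bool, n: int = 9,
    plus_pct: float = 100.0, minus_pct: float = 100.0,
) -> list[TrialSpec]:
    shock = ShockSpec() if reinforced else None
    return [
        TrialSpec(
            index=start + k,
            phase="training",
            bee_side_light=light(plus, plus_pct),
            opposite_side_light=light(minus, minus_pct),
            shock_on_bee_side=reinforced,
            shock=shock,
            tag=f"{plus}{minus}",
        )
        for k in range(n)
    ]


def _expII_test_trials(plus: str, minus: str, start: int, rng) -> list[TrialSpec]:
    """Six-probe test battery: one passive-avoidance trial (λ− on the bee
    side, λ+ opposite), the two trained lights each against the untrained
    λ0 = Y, and all three lights singly against darkness; delivered as a
    single-color triplet and a dual-color triplet, triplet order and order
    within each triplet pseudorandomized per bee."""
    neutral = "Y"
    dual = [
        TrialSpec(start, "test", light(minus), light(plus), tag=f"{minus}{plus}"),
        TrialSpec(start, "test", light(plus), light(neutral), tag=f"{plus}{neutral}"),
        TrialSpec(start, "test", light(minus), light(neutral), tag=f"{minus}{neutral}"),
    ]
    single = [
        TrialSpec(start, "test", light(lbl), DARK, tag=f"{lbl}0")
        for lbl in ("B", "G", "Y")
    ]
    rng.shuffle(dual)
    rng.shuffle(single)
    triplets = [single, dual] if rng.random() < 0.5 else [dual, single]
    ordered = [t for trip in triplets for t in trip]
    return [replace(t, index=start + k) for k, t in enumerate(ordered)]


def _expIII_trials(ref: str, test: str, start_series: str) -> list[TrialSpec]:
    """Intensity-preference series: the reference light fixed at 100%
    against the test light swept 0–100% in 10% steps, one descending and one
    ascending series, each level presented twice — first with the reference
    on the bee side, then on the opposite side (reciprocal)."""
    levels = list(range(0, 101, 10))
    series = [list(reversed(levels)), levels]
    if start_series == "increasing":
        series.reverse()
    trials: list[TrialSpec] = []
    idx = 0
    for s_i, seq in enumerate(series):
        for pct in seq:
            test_src = light(test, float(pct)) if pct > 0 else DARK
            for presentation, (bee, opp, role) in enumerate(
                [
                    (light(ref), test_src, "bee"),
                    (test_src, light(ref), "opposite"),
                ]
            ):
                trials.append(
                    TrialSpec(
                        index=idx,
                        phase="preference",
                        bee_side_light=bee,
                        opposite_side_light=opp,
                        focal_role=role,  # reference stays focal on both presentations
                        tag=f"{ref}{test}:{pct}:s{s_i}:p{presentation}",
                    )
                )
                idx += 1
    return trials


def build_protocol(
    experiment: str,
    pair: str | None = None,
    *,
    reinforced: bool = False,
    ref: str | None = None,
    test: str | None = None,
    start_series: str = "decreasing",
    rng=None,
    chamber: ChamberSpec | None = None,
) -> ProtocolSpec:
    """Construct the trial schedule for experiments I–IV.

    I   — 9 reinforced (or sham) training trials + 4 test trials, one of the
          six color pairs at 100% intensity; ``pair`` like "BG" reads λ+λ−.
    II  — as I but with the six-probe test battery (requires ``rng`` for the
          per-bee pseudorandomization; a fresh default is used if omitted).
    III — unreinforced intensity-preference series (``ref``/``test`` labels).
    IV  — a single unreinforced preference trial, then 9 training + 4 test
          trials with the green intensity rebalanced (62% vs B, 46% vs Y).
    """
    import numpy as np

    chamber = chamber or ChamberSpec()
    experiment = experiment.upper().removeprefix("EXP")

    if experiment in ("I", "II", "IV"):
        if pair is None or pair not in _PAIRS:
            raise ConfigurationError(f"pair must be one of {_PAIRS}, got {pair!r}")
        plus, minus = pair[0], pair[1]

    if experiment == "I":
        trials = _training_trials(plus, minus, 0, reinforced)
        trials += [
            TrialSpec(9 + k, "test", light(plus), light(minus), tag=pair)
            for k in range(4)
        ]
        name = f"expI-{pair}"
    elif experiment == "II":
        rng = rng if rng is not None else np.random.default_rng()
        trials = _training_trials(plus, minus, 0, reinforced)
        trials += _expII_test_trials(plus, minus, 9, rng)
        name = f"expII-{pair}"
    elif experiment == "III":
        if reinforced:
            raise ConfigurationError("the intensity series is never reinforced")
        if ref is None or test is None or ref == test or {ref, test} - set("BGY"):
            raise ConfigurationError("experiment III needs distinct ref/test in BGY")
        trials = _expIII_trials(ref, test, start_series)
        name = f"expIII-ref{ref}-test{test}"
    elif experiment == "IV":
        if "G" not in pair:
            raise ConfigurationError("experiment IV pairs always include G")
        other = plus if plus != "G" else minus
        g_pct = GREEN_BALANCED_PCT[other]
        pcts = {lbl: (g_pct if lbl == "G" else 100.0) for lbl in (plus, minus)}
        trials = [
            TrialSpec(
                0,
                "preference",
                light(plus, pcts[plus]),
                light(minus, pcts[minus]),
                tag=pair,
            )
        ]
        trials += _training_trials(
            plus, minus, 1, reinforced, plus_pct=pcts[plus], minus_pct=pcts[minus]
        )
        trials += [
            TrialSpec(
                10 + k,
                "test",
                light(plus, pcts[plus]),
                light(minus, pcts[minus]),
                tag=pair,
            )
            for k in range(4)
        ]
        name = f"expIV-{pair}"
    else:
        raise ConfigurationError(f"unknown experiment {experiment!r}")

    return ProtocolSpec(
        name=name,
        trials=tuple(trials),
        reinforced=reinforced,
        experiment=experiment,
        chamber=chamber,
    )


# ---------------------------------------------------------------------------
# serialization

def _light_to_dict(src: LightSource) -> dict:
    return {"label": src.label, "intensity_pct": src.intensity_pct}


def _light_from_dict(d: dict) -> LightSource:
    if d["label"] == "DARK":
        return DARK
    return light(d["label"], d["intensity_pct"])


def protocol_to_dict(p: ProtocolSpec) -> dict:
    return {
        "schema": "apisim-protocol/1",
        "name": p.name,
        "experiment": p.experiment,
        "reinforced": p.reinforced,
        "habituation_s": p.habituation_s,
        "chamber": {
            "length_cm": p.chamber.length_cm,
            "n_sensors": p.chamber.n_sensors,
            "sample_rate_hz": p.chamber.sample_rate_hz,
        },
        "trials": [
            {
                "index": t.index,
                "phase": t.phase,
                "bee_side_light": _light_to_dict(t.bee_side_light),
                "opposite_side_light": _light_to_dict(t.opposite_side_light),
                "shock_on_bee_side": t.shock_on_bee_side,
                "shock": (
                    None
                    if t.shock is None
                    else {
                        "onset_delay_s": t.shock.onset_delay_s,
                        "rate_hz": t.shock.rate_hz,
                        "pulse_width_s": t.shock.pulse_width_s,
                        "end_s": t.shock.end_s,
                        "voltage_v": t.shock.voltage_v,
                    }
                ),
                "stimulus_duration_s": t.stimulus_duration_s,
                "onset_to_onset_s": t.onset_to_onset_s,
                "focal_role": t.focal_role,
                "tag": t.tag,
            }
            for t in p.trials
        ],
    }


def protocol_from_dict(d: dict) -> ProtocolSpec:
    if d.get("schema") != "apisim-protocol/1":
        raise ConfigurationError("unrecognized protocol schema")
    trials = tuple(
        TrialSpec(
            index=t["index"],
            phase=t["phase"],
            bee_side_light=_light_from_dict(t["bee_side_light"]),
            opposite_side_light=_light_from_dict(t["opposite_side_light"]),
            shock_on_bee_side=t["shock_on_bee_side"],
            shock=None if t["shock"] is None else ShockSpec(**t["shock"]),
            stimulus_duration_s=t["stimulus_duration_s"],
            onset_to_onset_s=t["onset_to_onset_s"],
            focal_role=t["focal_role"],
            tag=t["tag"],
        )
        for t in d["trials"]
    )
    return ProtocolSpec(
        name=d["name"],
        trials=trials,
        habituation_s=d["habituation_s"],
        reinforced=d["reinforced"],
        experiment=d["experiment"],
        chamber=ChamberSpec(**d["chamber"]),
    )


def protocol_to_yaml(p: ProtocolSpec) -> str:
    return yaml.safe_dump(protocol_to_dict(p), sort_keys=False)


def protocol_from_yaml(text: str) -> ProtocolSpec:
    return protocol_from_dict(yaml.safe_load(text))
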