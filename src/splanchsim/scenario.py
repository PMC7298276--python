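"""Quasi-static time-course simulation of stenosis/aneurysm scenarios.

The circuit is purely resistive, so the flow at any instant is the
steady-state solution for the potentiometer resistances at that instant;
a "scenario" is just a pair of piecewise-linear resistance signals plus
labelled clinical zones on the timeline.

Two built-in 7-second scenarios mirror the two chronologies of concurrent
celiac stenosis and pancreaticoduodenal aneurysm, each manipulation taking
one second:

* scenario 1 (stenosis-first): normal -> stenosis develops -> aneurysm/
  collaterals form (preop: total steal, CA flow 0) -> aneurysm corrected
  (postop: CA reconstituted at 44 mL/min, stenosis left in situ);
* scenario 2 (aneurysm-first): normal -> aneurysm forms (steal without
  any stenosis) -> stenosis develops -> aneurysm corrected (same postop).

Because steady flows depend only on the instantaneous state, both
scenarios reach identical normal / preoperative / postoperative flows —
the bidirectional-causality argument stated testably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import FlowPair, ModelState, SplanchnicParameters, steady_flows
from .units import ConversionFactors, DEFAULT_FACTORS, current_to_flow

__all__ = [
    "PiecewiseLinearSignal",
    "Zone",
    "Scenario",
    "FlowTrace",
    "ZoneSummary",
    "ScenarioSummary",
    "builtin_scenario",
    "combined_scenario",
    "run_scenario",
    "summarize",
    "scenario_equivalence",
    "detect_reconstitution",
    "classify_brightness",
]

ZoneLabel = Literal["normal", "stenosis_only", "aneurysm_only",
                    "preop", "postop", "transition"]
ZONE_LABELS = {"normal", "stenosis_only", "aneurysm_only",
               "preop", "postop", "transition"}

#: currents below this round to 0.000 mA at reporting precision and are
#: treated as "no flow" (steal); presentation heuristic, not a model value
STEAL_THRESHOLD_MA = 0.0005

TRACE_COLUMNS = ["time_s", "r_stenosis_ohm", "r_aneurysm_ohm",
                 "i_ca_mA", "i_pda_mA", "q_ca_mL_min", "q_pda_mL_min",
                 "zone"]


@dataclass(frozen=True)
class PiecewiseLinearSignal:
    """Resistance signal defined by (time, ohms) breakpoints.

    Values interpolate linearly between breakpoints and hold constant
    beyond the endpoints; times must be strictly increasing.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __init__(self, breakpoints: Sequence[tuple[float, float]]):
        bps = tuple((float(t), float(r)) for t, r in breakpoints)
        if not bps:
            raise ValueError("signal needs at least one breakpoint")
        times = [t for t, _ in bps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        object.__setattr__(self, "breakpoints", bps)

    def value(self, t):
        """Resistance at time(s) ``t`` (scalar or array)."""
        times = np.array([p[0] for p in self.breakpoints])
        vals = np.array([p[1] for p in self.breakpoints])
        return np.interp(t, times, vals)

    def shifted(self, dt: float) -> "PiecewiseLinearSignal":
        return PiecewiseLinearSignal(
            [(t + dt, r) for t, r in self.breakpoints])


@dataclass(frozen=True)
class Zone:
    """Half-open labelled interval [start, end) of the timeline."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("zone end must exceed start")
        if self.label not in ZONE_LABELS:
            raise ValueError(f"unknown zone label {self.label!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class Scenario:
    name: str
    duration: float
    stenosis_signal: PiecewiseLinearSignal
    aneurysm_signal: PiecewiseLinearSignal
    zones: tuple[Zone, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        zones = tuple(self.zones)
        object.__setattr__(self, "zones", zones)
        t = 0.0
        for z in zones:
            if abs(z.start - t) > 1e-12:
                raise ValueError("zones must tile [0, duration] contiguously")
            t = z.end
        if zones and abs(t - self.duration) > 1e-12:
            raise ValueError("zones must end at the scenario duration")

    def state_at(self, t: float) -> ModelState:
        return ModelState(float(self.stenosis_signal.value(t)),
                          float(self.aneurysm_signal.value(t)))

    def zone_at(self, t: float) -> Zone:
        for z in self.zones:
            if z.start <= t < z.end:
                return z
        if self.zones and t >= self.zones[-1].end - 1e-12:
            return self.zones[-1]  # final sample belongs to the last zone
        raise ValueError(f"time {t} outside zoned timeline")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "duration": self.duration,
            "stenosis_signal": [list(p) for p in
                                self.stenosis_signal.breakpoints],
            "aneurysm_signal": [list(p) for p in
                                self.aneurysm_signal.breakpoints],
            "zones": [[z.start, z.end, z.label] for z in self.zones],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            name=d["name"],
            duration=float(d["duration"]),
            stenosis_signal=PiecewiseLinearSignal(d["stenosis_signal"]),
            aneurysm_signal=PiecewiseLinearSignal(d["aneurysm_signal"]),
            zones=tuple(Zone(float(s), float(e), lbl)
                        for s, e, lbl in d.get("zones", [])),
        )


def builtin_scenario(which: int,
                     params: SplanchnicParameters | None = None) -> Scenario:
    """The two built-in 7 s chronologies (1: stenosis-first,
    2: aneurysm-first).  Both start at the normal state
    (stenosis 0 Ω, aneurysm at pot maximum) and end at the postoperative
    state (stenosis at maximum, aneurysm corrected back to maximum)."""
    p = params or SplanchnicParameters()
    lo, hi = p.pot_min, p.pot_max
    if which == 1:
        sten = [(0, lo), (1, lo), (2, hi), (7, hi)]
        aneu = [(0, hi), (3, hi), (4, lo), (5, lo), (6, hi), (7, hi)]
        mid_label = "stenosis_only"
    elif which == 2:
        sten = [(0, lo), (3, lo), (4, hi), (7, hi)]
        aneu = [(0, hi), (1, hi), (2, lo), (5, lo), (6, hi), (7, hi)]
        mid_label = "aneurysm_only"
    else:
        raise ValueError(f"scenario must be 1 or 2, got {which!r}")
    zones = (Zone(0, 1, "normal"), Zone(1, 2, "transition"),
             Zone(2, 3, mid_label), Zone(3, 4, "transition"),
             Zone(4, 5, "preop"), Zone(5, 6, "transition"),
             Zone(6, 7, "postop"))
    return Scenario(name=f"scenario {which}", duration=7.0,
                    stenosis_signal=PiecewiseLinearSignal(sten),
                    aneurysm_signal=PiecewiseLinearSignal(aneu),
                    zones=zones)


def combined_scenario(params: SplanchnicParameters | None = None) -> Scenario:
    """Scenarios 1 and 2 concatenated on a 14 s timeline (scenario 2
    offset by +7 s), matching the published side-by-side presentation."""
    s1 = builtin_scenario(1, params)
    s2 = builtin_scenario(2, params)
    # scenario 2 restarts from the normal state at t = 7 s; the reset is a
    # step, modelled as a near-instant ramp ending exactly at t = 7
    eps = 1e-9

    def _concat(a: PiecewiseLinearSignal,
                b: PiecewiseLinearSignal) -> PiecewiseLinearSignal:
        bps = [(t if t < 7.0 else 7.0 - eps, r) for t, r in a.breakpoints]
        bps += [(t + 7.0, r) for t, r in b.breakpoints]
        return PiecewiseLinearSignal(bps)

    sten = _concat(s1.stenosis_signal, s2.stenosis_signal)
    aneu = _concat(s1.aneurysm_signal, s2.aneurysm_signal)
    zones = tuple(list(s1.zones)
                  + [Zone(z.start + 7.0, z.end + 7.0, z.label)
                     for z in s2.zones])
    return Scenario(name="combined", duration=14.0,
                    stenosis_signal=sten, aneurysm_signal=aneu,
                    zones=zones)


@dataclass
class FlowTrace:
    """Sampled tracings on a uniform time grid."""

    times: np.ndarray
    r_stenosis: np.ndarray
    r_aneurysm: np.ndarray
    i_ca: np.ndarray
    i_pda: np.ndarray
    q_ca: np.ndarray
    q_pda: np.ndarray
    zone: list[str]

    def at(self, t: float) -> FlowPair:
        """Flow pair at the grid sample nearest ``t``."""
        k = int(np.argmin(np.abs(self.times - t)))
        return FlowPair(float(self.i_ca[k]), float(self.i_pda[k]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "r_stenosis_ohm": self.r_stenosis,
            "r_aneurysm_ohm": self.r_aneurysm,
            "i_ca_mA": self.i_ca,
            "i_pda_mA": self.i_pda,
            "q_ca_mL_min": self.q_ca,
            "q_pda_mL_min": self.q_pda,
            "zone": self.zone,
        })

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        for col in ("time_s", "i_ca_mA", "i_pda_mA",
                    "q_ca_mL_min", "q_pda_mL_min"):
            df[col] = df[col].map(lambda v: f"{v:.6g}")
        for col in ("r_stenosis_ohm", "r_aneurysm_ohm"):
            df[col] = df[col].map(lambda v: f"{v:.10g}")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FlowTrace":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(float),
                   r_stenosis=df["r_stenosis_ohm"].to_numpy(float),
                   r_aneurysm=df["r_aneurysm_ohm"].to_numpy(float),
                   i_ca=df["i_ca_mA"].to_numpy(float),
                   i_pda=df["i_pda_mA"].to_numpy(float),
                   q_ca=df["q_ca_mL_min"].to_numpy(float),
                   q_pda=df["q_pda_mL_min"].to_numpy(float),
                   zone=df["zone"].astype(str).tolist())


def _vector_flows(params: SplanchnicParameters, r_s: np.ndarray,
                  r_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized closed-form divider; mirrors model.steady_flows."""
    r_branch = params.r_ca + r_s
    with np.errstate(divide="ignore", invalid="ignore"):
        r_block = np.where(r_a == 0, 0.0,
                           params.r_pda * r_a / (params.r_pda + r_a))
        r_par = np.where((r_branch == 0) | (r_block == 0), 0.0,
                         r_branch * r_block / (r_branch + r_block))
    i_total = params.source_voltage / (params.r_pancreas_liver + r_par)
    i_ca = i_total * r_block / (r_branch + r_block)
    return i_ca * 1e3, (i_total - i_ca) * 1e3


def run_scenario(scenario: Scenario,
                 params: SplanchnicParameters | None = None,
                 dt: float = 0.001,
                 f: ConversionFactors = DEFAULT_FACTORS) -> FlowTrace:
    """Sample the scenario on a uniform grid of step ``dt`` seconds.

    Each sample is an independent steady-state evaluation (quasi-static:
    the network has no reactive elements, so flows respond instantly to
    resistance changes).
    """
    if not 0 < dt <= 0.1:
        raise ValueError("dt must be in (0, 0.1] s")
    p = params or SplanchnicParameters()
    n = int(round(scenario.duration / dt))
    times = np.linspace(0.0, scenario.duration, n + 1)
    r_s = np.asarray(scenario.stenosis_signal.value(times), dtype=float)
    r_a = np.asarray(scenario.aneurysm_signal.value(times), dtype=float)
    i_ca, i_pda = _vector_flows(p, r_s, r_a)
    to_ml_min = 1000.0 / f.milliamps_per_liter_min
    zones = ([scenario.zone_at(t).label for t in times] if scenario.zones
             else [""] * len(times))
    return FlowTrace(times=times, r_stenosis=r_s, r_aneurysm=r_a,
                     i_ca=i_ca, i_pda=i_pda,
                     q_ca=i_ca * to_ml_min, q_pda=i_pda * to_ml_min,
                     zone=zones)


@dataclass(frozen=True)
class ZoneSummary:
    label: str
    start: float
    end: float
    i_ca_ma: float
    i_pda_ma: float

    @property
    def q_ca_ml_min(self) -> float:
        return self.i_ca_ma * 1000.0

    @property
    def q_pda_ml_min(self) -> float:
        return self.i_pda_ma * 1000.0

    def to_dict(self, ndigits: int = 3) -> dict:
        return {"label": self.label, "start": self.start, "end": self.end,
                "i_ca_mA": round(self.i_ca_ma, ndigits),
                "i_pda_mA": round(self.i_pda_ma, ndigits),
                "q_ca_mL_min": round(self.q_ca_ml_min, ndigits - 3),
                "q_pda_mL_min": round(self.q_pda_ml_min, ndigits - 3)}


@dataclass(frozen=True)
class ScenarioSummary:
    """Per-zone flows (taken at zone midpoints) plus clinical flags."""

    scenario_name: str
    zones: tuple[ZoneSummary, ...]
    steal_flag: bool
    reconstitution_flag: bool

    def zone(self, label: str) -> ZoneSummary:
        """First zone with the given label (raises if absent)."""
        for z in self.zones:
            if z.label == label:
                return z
        raise KeyError(f"summary has no zone labelled {label!r}")

    def to_dict(self) -> dict:
        return {"scenario": self.scenario_name,
                "zones": [z.to_dict() for z in self.zones],
                "steal_flag": self.steal_flag,
                "reconstitution_flag": self.reconstitution_flag}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def summarize(trace: FlowTrace, scenario: Scenario) -> ScenarioSummary:
    """Zone-by-zone flows at zone midpoints, with steal/reconstitution
    flags.

    Raises if the trace grid does not cover the scenario's zones.
    """
    if not scenario.zones:
        raise ValueError("scenario has no zones to summarize")
    t_max = float(trace.times[-1])
    if scenario.zones[-1].end > t_max + 1e-9:
        raise ValueError("trace does not cover the scenario timeline")
    zones = []
    for z in scenario.zones:
        fp = trace.at(z.midpoint)
        zones.append(ZoneSummary(z.label, z.start, z.end, fp.i_ca, fp.i_pda))
    hold = [z for z in zones if z.label != "transition"]
    steal = any(z.i_ca_ma < STEAL_THRESHOLD_MA for z in hold)
    summary = ScenarioSummary(scenario.name, tuple(zones), steal, False)
    object.__setattr__(summary, "reconstitution_flag",
                       detect_reconstitution(summary))
    return summary


def detect_reconstitution(summary: ScenarioSummary) -> bool:
    """True iff the CA flow reappears postoperatively (above the steal
    threshold) after a preoperative total steal, while remaining below the
    normal flow — i.e. the artery is reconstituted, not normalised."""
    try:
        normal = summary.zone("normal")
        preop = summary.zone("preop")
        postop = summary.zone("postop")
    except KeyError:
        return False
    return (preop.i_ca_ma <= STEAL_THRESHOLD_MA
            and postop.i_ca_ma > STEAL_THRESHOLD_MA
            and postop.i_ca_ma < normal.i_ca_ma)


def scenario_equivalence(s1: ScenarioSummary, s2: ScenarioSummary,
                         tol_ma: float = 1e-6) -> bool:
    """True iff the normal, preoperative and postoperative flows of the
    two summaries agree to within ``tol_ma`` mA — the path-independence
    claim that either chronology reaches the same clinical states."""
    for label in ("normal", "preop", "postop"):
        try:
            a, b = s1.zone(label), s2.zone(label)
        except KeyError as exc:
            raise ValueError(f"both summaries need a {label!r} zone") from exc
        if (abs(a.i_ca_ma - b.i_ca_ma) >= tol_ma
                or abs(a.i_pda_ma - b.i_pda_ma) >= tol_ma):
            return False
    return True


def classify_brightness(i_ma: float, i_normal_ma: float) -> str:
    """Qualitative LED-brightness class for a branch current relative to
    its normal-state value: off / dim / normal / bright.

    Thresholds (ratio to normal: <0.02 off, <0.5 dim, <=1.1 normal,
    else bright) are presentation heuristics for the breadboard analogue,
    not model quantities.
    """
    if i_normal_ma <= 0:
        raise ValueError("normal current must be positive")
    if i_ma < 0:
        raise ValueError("current magnitude cannot be negative")
    r = i_ma / i_normal_ma
    if r < 0.02:
        return "off"
    if r < 0.5:
        return "dim"
    if r <= 1.1:
        return "normal"
    return "bright"
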