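"""End-to-end measurement stream and irrigation-dynamics experiments.

Frames arrive at 25 fps; every frame is scored by the bubble detector and
read at the setup-time ROI; block-wise majority decisions over 8 frames
gate validity; the hemoglobin value is produced by Beer-Lambert inversion
under the frame's exposure; and records are emitted at a fixed 10 Hz,
repeating the latest validated value between updates (latest-value
semantics, mirroring a double-buffered hand-off to the consumer).

Gating is fail-safe: a record formed from a bubble-positive window, a
frame captured while the exposure switched, or an out-of-range count
never updates the reported hemoglobin — the last trusted value is carried
with a reason code instead.

The module also provides a first-order model of the irrigation mixing
dynamics (exponential relaxation toward the current bladder inflow
target, with separate rise and fall time constants) for step-response
experiments, plus the log-linear estimator that recovers the time
constants from a measured trace.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from . import roi as roi_mod
from .bubblenet import (
    DECISION_THRESHOLD,
    SMOOTHING_WINDOW,
    BubbleDetector,
    score_frames,
    smooth_decisions,
)
from .exposure import ExposureState
from .optics import CalibrationModel, GlassOffsets, invert_count
from .roi import ROISpec
from .simulate import FrameSequence

__all__ = [
    "MeasurementRecord",
    "FirstOrderDynamics",
    "StreamConfig",
    "run_stream",
    "simulate_cbi",
    "trajectory_from_events",
    "estimate_tau",
    "settling_time",
    "write_records_jsonl",
    "write_records_csv",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One timestamped output sample of the sensor.

    Invalid records (``valid=False``) carry the last trusted hemoglobin
    value together with the reason the current reading was rejected.
    """

    timestamp: float
    hb_gdl: float
    blood_pct: float
    exposure_mode: str
    valid: bool
    reason: Literal["ok", "bubble", "switching", "out_of_range"]


@dataclass(frozen=True)
class FirstOrderDynamics:
    """First-order irrigation mixing: time constants in seconds for
    rising (bleeding onset) and falling (washed out) concentration."""

    tau_rise: float = 33.0
    tau_fall: float = 119.0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_fall <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class StreamConfig:
    """Input/output rates of the measurement pipeline."""

    fps: float = 25.0
    output_rate: float = 10.0
    window: int = SMOOTHING_WINDOW

    def __post_init__(self) -> None:
        if self.output_rate > self.fps:
            raise ValueError("output rate must not exceed the frame rate")


def run_stream(
    sequence: FrameSequence,
    roi: ROISpec,
    calib: CalibrationModel,
    controller: ExposureState | None = None,
    detector: BubbleDetector | None = None,
    config: StreamConfig | None = None,
    glass: GlassOffsets | None = None,
) -> list[MeasurementRecord]:
    """Process a frame sequence into the fixed-rate measurement stream.

    Exposure handling: frames carry the exposure they were captured
    under. If a ``controller`` is given it is stepped with each frame's
    ROI reading and the frames on which it fires are invalidated
    (``reason="switching"``); otherwise the switch frames recorded during
    simulation are used.

    Without a ``detector`` no bubble gating is applied (all windows pass).
    """
    config = config or StreamConfig(fps=sequence.fps)
    if abs(config.fps - sequence.fps) > 1e-9:
        raise ValueError("config fps does not match the sequence")
    frames = sequence.frames
    n = len(frames)
    if n == 0:
        raise ValueError("empty sequence")
    for f in frames:
        if roi.col_stop > f.pixels.shape[1] or roi.row_stop > f.pixels.shape[0]:
            raise ValueError("ROI does not fit the sequence frames")

    readings = np.array([roi_mod.roi_reading(f, roi) for f in frames])

    switch_set: set[int] = set()
    if controller is not None:
        for i, r in enumerate(readings):
            if controller.step(float(r)):
                switch_set.add(i)
    else:
        switch_set = set(sequence.switch_frames)

    if detector is not None:
        probs = score_frames(detector, frames)
        window_bubble = smooth_decisions(probs, window=config.window,
                                         threshold=DECISION_THRESHOLD)
    else:
        window_bubble = np.zeros(int(np.ceil(n / config.window)), dtype=bool)

    # per-frame state: rejection reason (priority: a switch invalidates
    # outright, then bubble windows, then untrusted counts)
    frame_state: list[tuple[str, float, float, str]] = []
    for i, frame in enumerate(frames):
        mode = frame.exposure_mode
        m = invert_count(float(readings[i]), mode, calib, glass)
        if i in switch_set:
            reason = "switching"
        elif window_bubble[i // config.window]:
            reason = "bubble"
        elif not m.in_range:
            reason = "out_of_range"
        else:
            reason = "ok"
        frame_state.append((reason, m.hb_gdl, m.blood_pct, mode))

    # Each 10 Hz record summarizes the frames captured since the previous
    # tick (latest-value semantics): the held hemoglobin advances on every
    # valid frame, and any rejected frame in the interval marks the record
    # invalid with its reason, so no switch or bubble frame can slip
    # through unreported between output ticks.
    duration = n / sequence.fps
    n_records = int(round(duration * config.output_rate))
    records: list[MeasurementRecord] = []
    last_hb, last_pct = 0.0, 0.0
    prev_i = -1
    for k in range(n_records):
        t = (k + 1) / config.output_rate
        i = min(int(t * sequence.fps + 1e-9), n - 1)  # latest frame at or before t
        reason = "ok"
        mode = frame_state[i][3]
        for j in range(prev_i + 1, i + 1):
            f_reason, hb, pct, _ = frame_state[j]
            if f_reason == "ok":
                last_hb, last_pct = hb, pct
            elif reason == "ok":
                reason = f_reason
        prev_i = i
        records.append(
            MeasurementRecord(
                timestamp=round(t, 9),
                hb_gdl=round(last_hb, 3),
                blood_pct=last_pct,
                exposure_mode=mode,
                valid=reason == "ok",
                reason=reason,
            )
        )
    return records


# ---------------------------------------------------------------------------
# irrigation dynamics
# ---------------------------------------------------------------------------

def simulate_cbi(
    dynamics: FirstOrderDynamics,
    events: Sequence[tuple[float, float]],
    duration: float,
    dt: float = 0.04,
    c0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration trace under piecewise first-order mixing.

    ``events`` are (time, target concentration) pairs, ordered in time:
    at each event the bladder's effective inflow target changes, and the
    measured concentration relaxes exponentially toward the current
    target — with ``tau_rise`` while rising and ``tau_fall`` while
    falling. The trace is continuous.

    Returns (times, concentrations).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    times_ev = [e[0] for e in events]
    if times_ev != sorted(times_ev):
        raise ValueError("events must be ordered in time")
    times = np.arange(0.0, duration + dt / 2, dt)
    c = np.empty_like(times)
    cur = float(c0)
    target = float(c0)
    ev = list(events)
    for i, t in enumerate(times):
        while ev and ev[0][0] <= t:
            target = float(ev.pop(0)[1])
        c[i] = cur
        tau = dynamics.tau_rise if target > cur else dynamics.tau_fall
        cur += (target - cur) * (1.0 - np.exp(-dt / tau))
    return times, c


def trajectory_from_events(
    dynamics: FirstOrderDynamics,
    events: Sequence[tuple[float, float]],
    duration: float,
    dt: float = 0.04,
    c0: float = 0.0,
) -> Callable[[float], float]:
    """A c(t) callable (for :class:`ScenarioSpec`) interpolating the
    first-order trace."""
    times, c = simulate_cbi(dynamics, events, duration, dt=dt, c0=c0)
    return lambda t: float(np.interp(t, times, c))


def estimate_tau(
    times: np.ndarray,
    values: np.ndarray,
    segment: Literal["rise", "fall"],
) -> float:
    """Estimate the first-order time constant of a monotone step segment.

    Log-linear least squares on the residual to the asymptote (taken as
    the segment's final value): ``log |c_inf - c(t)|`` is linear in ``t``
    with slope ``-1/tau``. Samples with residual below 5% of the step
    amplitude are excluded (the tail is dominated by the asymptote
    estimate and, in measured traces, by noise).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values) or len(times) < 3:
        raise ValueError("need at least 3 samples")
    amplitude = values[-1] - values[0]
    if abs(amplitude) < 1e-12:
        raise ValueError("flat trace: no step to fit")
    if segment == "rise" and amplitude < 0:
        raise ValueError("segment labeled rise but trace falls")
    if segment == "fall" and amplitude > 0:
        raise ValueError("segment labeled fall but trace rises")
    asymptote = values[-1]
    resid = asymptote - values
    mask = np.abs(resid) > 0.05 * abs(amplitude)
    if mask.sum() < 3:
        raise ValueError("too few samples above the residual cutoff")
    y = np.log(np.abs(resid[mask]))
    t = times[mask]
    slope, _ = np.polyfit(t, y, 1)
    if slope >= 0:
        raise ValueError("segment is not relaxing toward the asymptote")
    return float(-1.0 / slope)


def settling_time(tau: float, n_tau: float = 5.0) -> float:
    """Response (settling) time in minutes: ``n_tau`` time constants,
    reported to one decimal."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return round(n_tau * tau / 60.0, 1)


# ---------------------------------------------------------------------------
# record output
# ---------------------------------------------------------------------------

def write_records_jsonl(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(asdict(r)) + "\n")


def write_records_csv(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["timestamp", "hb_gdl", "blood_pct", "exposure_mode", "valid", "reason"],
        )
        writer.writeheader()
        for r in records:
            writer.writerow(asdict(r))
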