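"""Dual-exposure hysteresis controller.

A single exposure cannot cover the whole clinically relevant hemoglobin
interval on a 10-bit sensor: the low exposure (chosen to just saturate on
clear irrigation fluid) runs out of signal near 0.6 g/dL, while an 8x
longer exposure overexposes below ~0.1 g/dL. The controller switches
between the two exposures on the raw count reading, with a hysteresis
dead band so small fluctuations never cause oscillation:

* in low mode, a reading at or below 80 counts switches to high exposure;
* in high mode, a reading at or above 800 counts switches to low.

Since 800 / 80 = 10 exceeds the exposure ratio of 8, the equivalent
reading immediately after any switch lands strictly inside the dead band
— the controller can never switch on two consecutive frames.

The count thresholds are the canonical controller constants; their
concentration equivalents (0.6 and 0.2 g/dL) are informative metadata.
"""

from __future__ import annotations

from dataclasses import dataclass


from .optics import ExposureMode

__all__ = ["ExposureState", "SwitchEvent", "step", "sweep_switch_count"]


@dataclass
class ExposureState:
    """Current exposure mode plus the count-domain hysteresis thresholds.

    Startup is in low exposure: irrigation begins with clear fluid, for
    which the low exposure is the correct operating point.
    """

    mode: ExposureMode = "low"
    switch_to_high_count: float = 80.0
    switch_to_low_count: float = 800.0
    exposure_ratio: float = 8.0
    hb_equivalents: tuple[float, float] = (0.6, 0.2)  # informative, g/dL

    def __post_init__(self) -> None:
        if not (0 < self.switch_to_high_count < self.switch_to_low_count):
            raise ValueError("thresholds must satisfy 0 < T_high < T_low")
        if self.switch_to_low_count / self.switch_to_high_count <= self.exposure_ratio:
            raise ValueError(
                "no-chatter condition violated: T_low/T_high must exceed "
                "the exposure ratio"
            )

    def step(self, reading: float) -> bool:
        """Advance the state machine on one reading; True iff a switch
        fired (the triggering frame's measurement is then invalid and the
        *next* frame is captured under the new exposure)."""
        if reading < 0:
            raise ValueError("reading must be non-negative")
        if self.mode == "low" and reading <= self.switch_to_high_count:
            self.mode = "high"
            return True
        if self.mode == "high" and reading >= self.switch_to_low_count:
            self.mode = "low"
            return True
        return False


def step(state: ExposureState, reading: float) -> tuple[ExposureState, bool]:
    """Functional wrapper around :meth:`ExposureState.step`."""
    switched = state.step(reading)
    return state, switched


@dataclass(frozen=True)
class SwitchEvent:
    """One exposure switch observed while walking a scenario."""

    frame_index: int
    timestamp: float
    reading: float  # the ROI reading that triggered the switch
    concentration: float
    from_mode: ExposureMode
    to_mode: ExposureMode


def sweep_switch_count(
    scenario,
    state: ExposureState | None = None,
) -> list[SwitchEvent]:
    """Walk a scenario frame by frame through the controller and collect
    every switch with its triggering reading and true concentration.

    Frames are rendered one at a time and discarded, so arbitrarily long
    scenarios stay memory-flat.
    """
    from . import roi as roi_mod
    from .simulate import render_frame

    state = state if state is not None else ExposureState()
    events: list[SwitchEvent] = []
    the_roi = roi_mod.setup_roi(scenario)
    n = scenario.n_frames()
    for i in range(n):
        t = i / scenario.fps
        frame = render_frame(scenario, t, state.mode, frame_index=i)
        reading = roi_mod.roi_reading(frame, the_roi)
        from_mode = state.mode
        if state.step(reading):
            events.append(
                SwitchEvent(
                    frame_index=i,
                    timestamp=t,
                    reading=reading,
                    concentration=frame.truth["c"],
                    from_mode=from_mode,
                    to_mode=state.mode,
                )
            )
    return events
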