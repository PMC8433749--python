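"""Physics-based synthetic sensor-frame generator.

Stands in for the sensor hardware: renders 10-bit monochrome frames of the
illuminated tube cross-section, with the optical phenomenology the real
device exhibits —

* transmitted intensity per the (glass-modified) Beer-Lambert law,
* static vertical shadow artifacts from the tube's reinforcement ribs
  (which act as plano-convex lenses),
* air bubbles rendered as local optical-path displacement: a bubble of
  diameter fraction ``s`` of the tube shortens the absorbing path, so the
  affected pixels brighten by ``10 ** (epsilon_dz * c * s)``; a thin
  refraction rim slightly lengthens the path and darkens. At c = 0 a
  bubble is optically invisible, as in reality.
* Gaussian read + shot noise, clipping and 10-bit quantization.

Every frame carries its ground truth (concentration, bubble-in-view), so
simulator output doubles as labeled training data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from . import optics
from .optics import CalibrationModel, GlassOffsets, ExposureMode

__all__ = [
    "IlluminationGeometry",
    "RibSpec",
    "BubbleEvent",
    "NoiseModel",
    "ScenarioSpec",
    "SensorFrame",
    "FrameSequence",
    "Specimen",
    "render_frame",
    "simulate_sequence",
    "make_specimen_series",
    "write_sequence",
    "read_sequence",
]

#: Background (unilluminated) pixel level, counts. Nonzero so that
#: profile-segmentation thresholds are exercised against a real floor.
DARK_LEVEL = 8.0


@dataclass(frozen=True)
class IlluminationGeometry:
    """Fixed column layout of the sensor image.

    The LED illuminates a central band of columns; the flanking
    transitional zones are partially lit, the outermost columns are dark.
    The sizes are constant for a given sensor assembly (they depend only
    on camera and LED placement), so they are configuration, not inference.
    Intervals are half-open and 0-based.
    """

    width: int = 160
    height: int = 120
    background_cols: tuple[tuple[int, int], tuple[int, int]] = ((0, 20), (140, 160))
    transitional_cols: tuple[tuple[int, int], tuple[int, int]] = ((20, 30), (130, 140))

    def __post_init__(self) -> None:
        (b0, b1), (b2, b3) = self.background_cols
        (t0, t1), (t2, t3) = self.transitional_cols
        # intervals must be ordered, disjoint, and tile [0, width)
        bounds = [b0, b1, t0, t1, t2, t3, b2, b3]
        if b0 != 0 or b3 != self.width:
            raise ValueError("background intervals must start at 0 and end at width")
        if bounds != sorted(bounds) or b1 != t0 or t3 != b2:
            raise ValueError("regions must abut: background|transitional|illuminated|transitional|background")
        if t1 >= t2:
            raise ValueError("illuminated interval is empty")

    @property
    def illuminated_cols(self) -> tuple[int, int]:
        return (self.transitional_cols[0][1], self.transitional_cols[1][0])


@dataclass(frozen=True)
class RibSpec:
    """A reinforcement-rib artifact: a static vertical intensity dip
    (or, for ribs focusing light, a slight spike) with a smooth
    lens-like Gaussian profile."""

    center_col: int
    width: int = 6
    attenuation: float = 0.6  # multiplicative factor at the rib center

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("rib width must be positive")
        if not (0.0 < self.attenuation <= 1.2) or self.attenuation == 1.0:
            raise ValueError("attenuation must be in (0, 1.2] and != 1")

    def factor(self, cols: np.ndarray) -> np.ndarray:
        sigma = self.width / 4.0
        bump = np.exp(-0.5 * ((cols - self.center_col) / sigma) ** 2)
        return 1.0 - (1.0 - self.attenuation) * bump


@dataclass(frozen=True)
class BubbleEvent:
    """One bubble transiting (or parked in) the optical path.

    ``depth_mode`` selects the qualitative appearance: a bubble close to
    the LED casts a small sharp bright disc with a dark rim; close to the
    camera it is defocused into a brightening of the whole view; near the
    tube center it looks like a bright lens core with curved dark edges.
    ``size`` is the bubble diameter as a fraction of the tube diameter.
    ``motion`` scales the traversal distance (0 = bubble remains static
    in the light path, 1 = full transit across the illuminated span).
    """

    t_enter: float
    t_exit: float
    depth_mode: Literal["near_led", "near_camera", "center"] = "center"
    size: float = 0.5
    direction: int = 1
    motion: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_enter < self.t_exit:
            raise ValueError("t_enter must precede t_exit")
        if not (0.0 < self.size <= 1.0):
            raise ValueError("size must be in (0, 1]")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if not (0.0 <= self.motion <= 1.0):
            raise ValueError("motion must be in [0, 1]")

    def in_view(self, t: float) -> bool:
        return self.t_enter <= t <= self.t_exit


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian sensor noise: variance = read_noise_sd**2 +
    shot_noise_scale * signal. The seed fully determines every frame."""

    read_noise_sd: float = 2.0
    shot_noise_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.shot_noise_scale < 0:
            raise ValueError("noise parameters must be non-negative")


#: Noise model producing bit-exact noiseless frames.
NOISELESS = NoiseModel(read_noise_sd=0.0, shot_noise_scale=0.0, seed=0)


@dataclass
class ScenarioSpec:
    """Complete description of a simulated acquisition."""

    concentration: Callable[[float], float]
    duration: float = 10.0
    fps: float = 25.0
    geometry: IlluminationGeometry = field(default_factory=IlluminationGeometry)
    ribs: Sequence[RibSpec] = ()
    bubbles: Sequence[BubbleEvent] = ()
    noise: NoiseModel = NOISELESS
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    glass: GlassOffsets | None = None
    vignette_amp: float = 0.02  # fractional intensity falloff at frame edge rows
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclass
class SensorFrame:
    """One exposure: a 10-bit monochrome image plus acquisition metadata
    and (for simulated frames) attached ground truth."""

    pixels: np.ndarray
    exposure_mode: ExposureMode
    timestamp: float
    truth: dict | None = None


@dataclass
class FrameSequence:
    """An ordered frame stream with per-frame truth labels and the
    exposure-controller trace recorded during simulation."""

    frames: list[SensorFrame]
    fps: float
    labels: np.ndarray  # per-frame bubble-in-view ground truth
    readings: np.ndarray | None = None  # ROI medians recorded during simulation
    switch_frames: list[int] = field(default_factory=list)
    roi: object | None = None

    def __len__(self) -> int:
        return len(self.frames)


def _bubble_maps(
    geometry: IlluminationGeometry,
    bubbles: Sequence[BubbleEvent],
    t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel path-shortening fraction and rim path-lengthening for the
    illuminated band. Shapes are (height, illuminated_width)."""
    lo, hi = geometry.illuminated_cols
    w = hi - lo
    h = geometry.height
    shorten = np.zeros((h, w))
    lengthen = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for b in bubbles:
        if not b.in_view(t):
            continue
        progress = (t - b.t_enter) / (b.t_exit - b.t_enter)
        if b.direction < 0:
            progress = 1.0 - progress
        # travel from 10% to 90% of the span, scaled by `motion`
        center_frac = 0.5 + b.motion * (progress - 0.5) * 0.8
        cx = center_frac * (w - 1)
        cy = (h - 1) / 2.0
        if b.depth_mode == "near_camera":
            # fully defocused: uniform path displacement over the view
            shorten += b.size
            continue
        if b.depth_mode == "near_led":
            radius = 0.25 * b.size * h
            rim = 1.5
        else:  # center
            radius = 0.45 * b.size * h
            rim = 2.5
        r = np.hypot(xx - cx, yy - cy)
        core = r <= radius
        # spherical-cap chord profile: path displacement largest on-axis
        prof = np.zeros_like(r)
        prof[core] = np.sqrt(np.clip(1.0 - (r[core] / max(radius, 1e-9)) ** 2, 0, 1))
        shorten += b.size * prof
        ring = (r > radius) & (r <= radius + rim)
        lengthen[ring] += 0.35  # refraction rim: slightly longer path
    return np.clip(shorten, 0.0, 1.0), lengthen


def render_frame(
    scenario: ScenarioSpec,
    t: float,
    mode: ExposureMode,
    frame_index: int | None = None,
) -> SensorFrame:
    """Render the sensor frame at time ``t`` under the given exposure.

    The illuminated band carries the Beer-Lambert transmission for the
    scenario's concentration ``c(t)``, modulated by bubbles (path
    displacement), rib artifacts and vertical vignetting; transitional
    columns ramp linearly to the dark background level; read+shot noise
    is added and the result is clipped to [0, 1023] and quantized
    (unless the scenario disables quantization).
    """
    if not (0.0 <= t <= scenario.duration):
        raise ValueError(f"t={t} outside scenario duration {scenario.duration}")
    geo = scenario.geometry
    calib = scenario.calibration
    c = float(scenario.concentration(t))
    if c < 0:
        raise ValueError("concentration trajectory must be non-negative")
    lo, hi = geo.illuminated_cols
    w_ill = hi - lo
    img = np.full((geo.height, geo.width), DARK_LEVEL, dtype=float)

    # Beer-Lambert field with bubbles as local effective-concentration change
    shorten, lengthen = _bubble_maps(geo, scenario.bubbles, t)
    c_eff = c * (1.0 - shorten + lengthen)
    g = scenario.glass or optics.NO_GLASS
    i0 = calib.incident(mode) - g.delta_incident
    ill = i0 * np.power(10.0, -calib.epsilon_dz * c_eff) + g.delta_transmitted

    # static rib artifacts (multiplicative, full column height)
    cols = np.arange(lo, hi, dtype=float)
    rib_factor = np.ones(w_ill)
    for rib in scenario.ribs:
        rib_factor *= rib.factor(cols)
    ill *= rib_factor[None, :]

    # smooth vertical vignetting, symmetric about the center row
    if scenario.vignette_amp > 0:
        rows = np.arange(geo.height, dtype=float)
        rel = (rows - (geo.height - 1) / 2.0) / (geo.height / 2.0)
        ill *= (1.0 - scenario.vignette_amp * rel**2)[:, None]

    img[:, lo:hi] = ill

    # transitional ramps between dark level and the mean illuminated level
    base = float(np.mean(ill))
    (tl0, tl1), (tr0, tr1) = geo.transitional_cols
    nl = tl1 - tl0
    ramp_l = DARK_LEVEL + (base - DARK_LEVEL) * (np.arange(1, nl + 1) / (nl + 1))
    img[:, tl0:tl1] = ramp_l[None, :]
    nr = tr1 - tr0
    ramp_r = DARK_LEVEL + (base - DARK_LEVEL) * (np.arange(nr, 0, -1) / (nr + 1))
    img[:, tr0:tr1] = ramp_r[None, :]

    noise = scenario.noise
    if noise.read_noise_sd > 0 or noise.shot_noise_scale > 0:
        key = frame_index if frame_index is not None else int(round(t * 1e6))
        rng = np.random.default_rng([noise.seed, key])
        sd = np.sqrt(noise.read_noise_sd**2 + noise.shot_noise_scale * np.clip(img, 0, None))
        img = img + rng.standard_normal(img.shape) * sd

    sat = calib.saturation if np.isfinite(calib.saturation) else 1023
    img = np.clip(img, 0.0, sat)
    if scenario.quantize:
        img = np.rint(img).astype(np.uint16)

    bubble_in_view = any(b.in_view(t) for b in scenario.bubbles)
    return SensorFrame(
        pixels=img,
        exposure_mode=mode,
        timestamp=t,
        truth={"c": c, "bubble": bubble_in_view},
    )


def simulate_sequence(
    scenario: ScenarioSpec,
    controller=None,
    roi=None,
) -> FrameSequence:
    """Simulate a full acquisition at the scenario's frame rate.

    If an exposure ``controller`` (:class:`hbsense.exposure.ExposureState`)
    is given, each frame is captured under the controller's current mode
    and the controller is stepped with that frame's ROI reading; the frame
    on which a switch fires is recorded in ``switch_frames`` (its
    measurement is invalidated downstream). Without a controller all
    frames use the low exposure.

    The ROI is selected once, on the first frame, unless one is supplied —
    mirroring the setup-time ROI selection of the real device.
    """
    from . import roi as roi_mod

    n = scenario.n_frames()
    frames: list[SensorFrame] = []
    labels = np.zeros(n, dtype=bool)
    readings = np.zeros(n, dtype=float)
    switch_frames: list[int] = []

    mode: ExposureMode = controller.mode if controller is not None else "low"
    the_roi = roi if roi is not None else roi_mod.setup_roi(scenario)
    for i in range(n):
        t = i / scenario.fps
        frame = render_frame(scenario, t, mode, frame_index=i)
        reading = roi_mod.roi_reading(frame, the_roi)
        frames.append(frame)
        labels[i] = frame.truth["bubble"]
        readings[i] = reading
        if controller is not None:
            switched = controller.step(reading)
            if switched:
                switch_frames.append(i)
            mode = controller.mode
    return FrameSequence(
        frames=frames,
        fps=scenario.fps,
        labels=labels,
        readings=readings,
        switch_frames=switch_frames,
        roi=the_roi,
    )


@dataclass(frozen=True)
class Specimen:
    """One calibration specimen: a sealed tube segment of diluted blood."""

    blood_pct: float
    hb_gdl: float
    frames: dict  # exposure mode -> SensorFrame


def make_specimen_series(
    lo: float = 0.0,
    hi: float = 22.0,
    step: float = 2.0,
    whole_blood_hb: float = optics.WHOLE_BLOOD_HB_GDL,
    scenario: ScenarioSpec | None = None,
) -> list[Specimen]:
    """Generate the blood-dilution calibration series.

    An inclusive arithmetic series of blood percentages (defaults: 0-22%
    in 2% steps, i.e. 12 specimens), each rendered as one static frame per
    exposure mode with its ground-truth hemoglobin attached
    (``hb = blood% / 100 * whole_blood_hb``).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    template = scenario or ScenarioSpec(concentration=lambda t: 0.0, duration=1.0)
    specimens = []
    for k in range(n):
        pct = lo + k * step
        hb = pct / 100.0 * whole_blood_hb
        spec_k = dataclasses.replace(template, concentration=lambda t, hb=hb: hb)
        frames = {
            m: render_frame(spec_k, 0.0, m, frame_index=k) for m in ("low", "high")
        }
        specimens.append(Specimen(blood_pct=pct, hb_gdl=hb, frames=frames))
    return specimens


# ---------------------------------------------------------------------------
# sequence I/O: numbered 16-bit grayscale TIFFs + a JSON manifest
# ---------------------------------------------------------------------------

def write_sequence(seq: FrameSequence, directory: str | Path) -> Path:
    """Write frames as numbered 16-bit grayscale TIFFs (10-bit data in the
    low bits) plus a JSON manifest with fps, per-frame exposure and truth
    labels. Returns the manifest path."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, frame in enumerate(seq.frames):
        name = f"frame_{i:05d}.tiff"
        tifffile.imwrite(directory / name, np.asarray(frame.pixels, dtype=np.uint16))
        entries.append(
            {
                "file": name,
                "timestamp": frame.timestamp,
                "exposure_mode": frame.exposure_mode,
                "truth": frame.truth,
            }
        )
    manifest = {
        "fps": seq.fps,
        "frames": entries,
        "labels": [bool(x) for x in seq.labels],
        "switch_frames": list(map(int, seq.switch_frames)),
    }
    if seq.roi is not None:
        manifest["roi"] = {
            "col_start": int(seq.roi.col_start),
            "col_stop": int(seq.roi.col_stop),
            "row_start": int(seq.roi.row_start),
            "row_stop": int(seq.roi.row_stop),
        }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_sequence(directory: str | Path) -> FrameSequence:
    """Load a sequence written by :func:`write_sequence`."""
    import tifffile

    from .roi import ROISpec

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    frames = []
    for entry in manifest["frames"]:
        pixels = tifffile.imread(directory / entry["file"])
        frames.append(
            SensorFrame(
                pixels=pixels,
                exposure_mode=entry["exposure_mode"],
                timestamp=entry["timestamp"],
                truth=entry.get("truth"),
            )
        )
    roi = None
    if "roi" in manifest:
        r = manifest["roi"]
        roi = ROISpec(r["col_start"], r["col_stop"], r["row_start"], r["row_stop"])
    return FrameSequence(
        frames=frames,
        fps=manifest["fps"],
        labels=np.array(manifest["labels"], dtype=bool),
        switch_frames=manifest.get("switch_frames", []),
        roi=roi,
    )
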