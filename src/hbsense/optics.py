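"""Beer-Lambert forward/inverse model for hemoglobin quantification.

The sensor measures the light transmitted through an irrigation drain tube
at 800 nm (an isobestic wavelength for Hb/HbO2, so oxygenation does not
matter). With incident intensity ``I0``, molar absorptivity ``eps`` and
optical path ``dz`` through the fluid, the transmitted intensity follows

    It = I0 * 10 ** (-eps * dz * c)

for hemoglobin concentration ``c`` (g/dL). Because the geometry is rigid,
``eps * dz`` is a single effective constant (``epsilon_dz``) and ``c`` can
be inferred from ``It`` alone.

When the optics are sealed behind thin glass slips, both the exerted and
the captured intensities are attenuated by constant offsets:

    It - dIt = (I0 - dI0) * 10 ** (-eps * dz * c)

A dual-exposure scheme extends the dynamic range of the 10-bit sensor: the
high exposure collects ``exposure_ratio`` times more light than the low
exposure, which just saturates the sensor on clear irrigation fluid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal

import numpy as np

from .errors import CalibrationError, CorruptFrameError

__all__ = [
    "HB_RANGE_GDL",
    "BLOOD_PCT_MAX",
    "WHOLE_BLOOD_HB_GDL",
    "ExposureMode",
    "CalibrationModel",
    "GlassOffsets",
    "HbMeasurement",
    "predict_count",
    "invert_count",
    "hb_to_blood_pct",
    "relative_error",
    "fit_calibration",
    "round_sig",
]

ExposureMode = Literal["low", "high"]

#: Specified measurement interval of the sensor, g/dL hemoglobin.
HB_RANGE_GDL: tuple[float, float] = (0.0, 3.23)
#: Equivalent blood-volume interval at average whole-blood hemoglobin.
BLOOD_PCT_MAX: float = 21.5
#: Average hemoglobin concentration of human whole blood, g/dL.
WHOLE_BLOOD_HB_GDL: float = 15.0


@dataclass(frozen=True)
class GlassOffsets:
    """Constant intensity offsets introduced by the glass sealing slips.

    Attributes
    ----------
    delta_incident:
        Attenuation of the exerted (LED-side) intensity, in counts.
    delta_transmitted:
        Attenuation of the captured (camera-side) intensity, in counts.
    """

    delta_incident: float = 0.0
    delta_transmitted: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_incident < 0 or self.delta_transmitted < 0:
            raise ValueError("glass offsets must be non-negative")


#: Convenience instance meaning "no glass in the optical path".
NO_GLASS = GlassOffsets()


@dataclass
class CalibrationModel:
    """Per-sensor calibration of the count <-> concentration mapping.

    Attributes
    ----------
    incident_low:
        Expected count at zero concentration under the low exposure
        (chosen during assembly to just saturate the sensor on clear
        irrigation fluid).
    exposure_ratio:
        High/low exposure-time factor; the high exposure's incident count
        is ``exposure_ratio * incident_low`` before clipping.
    epsilon_dz:
        Effective molar absorptivity times optical path length, per (g/dL).
    saturation:
        Maximum representable count (10-bit sensor: 1023). May be
        ``math.inf`` when range gating is deliberately disabled.
    noise_floor:
        Minimum count that can be distinguished from background noise.
    wavelength_nm:
        Metadata only; the isobestic measurement wavelength.
    """

    incident_low: float = 1020.0
    exposure_ratio: float = 8.0
    epsilon_dz: float = 2.5
    saturation: float = 1023
    noise_floor: float = 32.0
    wavelength_nm: float = 800.0
    diagnostics: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.epsilon_dz <= 0:
            raise CalibrationError("epsilon_dz must be positive")
        if self.exposure_ratio <= 1:
            raise CalibrationError("exposure_ratio must exceed 1")
        # incident_low is the pre-clipping expectation at c = 0; a noisy
        # calibration fit may place it marginally above the representable
        # maximum ("just saturates"), so allow a small overshoot.
        if self.incident_low > 1.05 * self.saturation:
            raise CalibrationError("incident_low must not exceed saturation")
        if self.noise_floor >= self.incident_low:
            raise CalibrationError("noise_floor must lie below incident_low")
        if self.noise_floor < 0:
            raise CalibrationError("noise_floor must be non-negative")

    def incident(self, mode: ExposureMode) -> float:
        """Incident (zero-concentration) count for an exposure mode."""
        if mode == "low":
            return self.incident_low
        if mode == "high":
            return self.exposure_ratio * self.incident_low
        raise ValueError(f"unknown exposure mode: {mode!r}")

    # -- serialization -------------------------------------------------

    def to_json(self, glass: GlassOffsets | None = None) -> str:
        doc = {k: v for k, v in asdict(self).items() if k != "diagnostics"}
        if not math.isfinite(doc["saturation"]):
            doc["saturation"] = None
        if glass is not None:
            doc["glass"] = asdict(glass)
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> tuple["CalibrationModel", GlassOffsets | None]:
        doc = json.loads(text)
        glass = doc.pop("glass", None)
        if doc.get("saturation") is None:
            doc["saturation"] = math.inf
        calib = cls(**doc)
        return calib, (GlassOffsets(**glass) if glass else None)


@dataclass(frozen=True)
class HbMeasurement:
    """A single hemoglobin reading derived from a sensor count.

    ``in_range`` is False for counts the sensor cannot trust: at/below the
    noise floor ``hb_gdl`` is pinned to the range maximum (the true value
    is at least that high), at/above saturation it is pinned to zero
    (overexposure looks like clear fluid).
    """

    hb_gdl: float
    blood_pct: float
    exposure_mode: ExposureMode
    in_range: bool


def predict_count(
    c: float | np.ndarray,
    mode: ExposureMode,
    calib: CalibrationModel,
    glass: GlassOffsets | None = None,
) -> float | np.ndarray:
    """Transmitted count predicted by the (glass-modified) Beer-Lambert law.

    Returns the pre-quantization real-valued count

        (I0_mode - dI0) * 10 ** (-epsilon_dz * c) + dIt

    which is strictly decreasing in ``c``. Values above the saturation
    count are *not* clipped here; clipping is a sensor property applied
    by the frame simulator.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    g = glass or NO_GLASS
    i0 = calib.incident(mode) - g.delta_incident
    if i0 <= 0:
        raise CalibrationError("glass offset exceeds incident intensity")
    out = i0 * np.power(10.0, -calib.epsilon_dz * c) + g.delta_transmitted
    return float(out) if out.ndim == 0 else out


def invert_count(
    count: float,
    mode: ExposureMode,
    calib: CalibrationModel,
    glass: GlassOffsets | None = None,
    whole_blood_hb: float = WHOLE_BLOOD_HB_GDL,
) -> HbMeasurement:
    """Invert a sensor count to a hemoglobin measurement.

    Counts inside ``(noise_floor, saturation)`` are inverted algebraically
    (the exact inverse of :func:`predict_count`). Out-of-range counts
    return flagged measurements rather than raising, because the
    measurement stream must keep running.

    Raises
    ------
    CorruptFrameError
        If the offset-corrected count is non-positive, which no physical
        transmission can produce.
    """
    g = glass or NO_GLASS
    if count >= calib.saturation:
        # Overexposed: indistinguishable from clear fluid.
        return HbMeasurement(0.0, hb_to_blood_pct(0.0, whole_blood_hb), mode, False)
    if count <= calib.noise_floor:
        # Darker than the sensor can resolve: at least the range maximum.
        hb = HB_RANGE_GDL[1]
        return HbMeasurement(hb, hb_to_blood_pct(hb, whole_blood_hb), mode, False)
    corrected = count - g.delta_transmitted
    if corrected <= 0:
        # a trusted-range count below the glass offset is impossible
        raise CorruptFrameError(
            f"count {count} is not physical after glass correction ({corrected})"
        )
    i0 = calib.incident(mode) - g.delta_incident
    c = -math.log10(corrected / i0) / calib.epsilon_dz
    c = max(c, 0.0)  # counts slightly above incident (noise) clamp to clear fluid
    in_range = c <= HB_RANGE_GDL[1]
    return HbMeasurement(c, hb_to_blood_pct(c, whole_blood_hb), mode, in_range)


def hb_to_blood_pct(
    hb_gdl: float, whole_blood_hb: float = WHOLE_BLOOD_HB_GDL
) -> float:
    """Convert hemoglobin concentration to blood-volume percent.

    Uses the average whole-blood hemoglobin of 15 g/dL by default, so
    3 g/dL reads as 20.0% blood. Reported to one decimal
    (round-half-to-even, the float default).
    """
    if whole_blood_hb <= 0:
        raise ValueError("whole_blood_hb must be positive")
    if hb_gdl < 0:
        raise ValueError("hb_gdl must be non-negative")
    return round(hb_gdl / whole_blood_hb * 100.0, 1)


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def relative_error(
    abs_err: float, conc: float, sig_figs: int | None = 3
) -> float:
    """Relative measurement error, percent, from an absolute error.

    ``abs_err`` and ``conc`` are both in blood-percentage points; the
    result is ``abs_err / conc * 100``. ``sig_figs`` controls display
    rounding (None returns the exact quotient).
    """
    if conc <= 0:
        raise ValueError("concentration must be positive")
    if abs_err < 0:
        raise ValueError("absolute error must be non-negative")
    val = abs_err / conc * 100.0
    return val if sig_figs is None else round_sig(val, sig_figs)


def fit_calibration(
    pairs: Iterable[tuple[float, float, ExposureMode]],
    glass: GlassOffsets | None = None,
    exposure_ratio: float | None = None,
    saturation: float = 1023,
    noise_floor: float = 32.0,
) -> CalibrationModel:
    """Fit a calibration from (concentration, mean count, mode) triples.

    Log-linear least squares: after subtracting the camera-side glass
    offset, ``log10(count - dIt)`` is linear in ``c`` with slope
    ``-epsilon_dz`` (shared across exposure modes, since exposure time
    scales collected light, not absorptivity) and a per-mode intercept
    ``log10(I0_mode - dI0)``.

    If both modes are represented the exposure ratio is estimated from
    the two intercepts; otherwise ``exposure_ratio`` (default 8) is used.
    Residual diagnostics are attached to the returned model.
    """
    g = glass or NO_GLASS
    pairs = list(pairs)
    if not pairs:
        raise CalibrationError("no calibration pairs given")
    concs = np.array([p[0] for p in pairs], dtype=float)
    counts = np.array([p[1] for p in pairs], dtype=float)
    modes = [p[2] for p in pairs]
    for m in modes:
        if m not in ("low", "high"):
            raise CalibrationError(f"unknown exposure mode: {m!r}")
    corrected = counts - g.delta_transmitted
    if np.any(corrected <= 0):
        raise CalibrationError("non-positive offset-corrected counts")
    present = sorted(set(modes), key=lambda m: 0 if m == "low" else 1)
    for m in present:
        if len({c for c, mm in zip(concs, modes) if mm == m}) < 2:
            raise CalibrationError(
                f"need >= 2 distinct concentrations in mode {m!r}"
            )

    # Design matrix: one intercept column per represented mode, shared slope.
    y = np.log10(corrected)
    X = np.zeros((len(pairs), len(present) + 1))
    for i, m in enumerate(modes):
        X[i, present.index(m)] = 1.0
    X[:, -1] = -concs
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    eps = float(beta[-1])
    if eps <= 0:
        raise CalibrationError("fitted epsilon_dz is non-positive")
    intercepts = {m: float(beta[j]) for j, m in enumerate(present)}

    if "low" in intercepts:
        incident_low = 10.0 ** intercepts["low"] + g.delta_incident
    else:  # high-only data: back out via the supplied ratio
        ratio = exposure_ratio or 8.0
        incident_low = (10.0 ** intercepts["high"] + g.delta_incident) / ratio
    if "low" in intercepts and "high" in intercepts:
        ratio = (10.0 ** intercepts["high"] + g.delta_incident) / incident_low
    else:
        ratio = exposure_ratio or 8.0

    resid = y - X @ beta
    diagnostics = {
        "residual_rms_log10": float(np.sqrt(np.mean(resid**2))),
        "residual_max_log10": float(np.max(np.abs(resid))),
        "n_pairs": len(pairs),
        "modes": present,
    }
    return CalibrationModel(
        incident_low=float(incident_low),
        exposure_ratio=float(ratio),
        epsilon_dz=eps,
        saturation=saturation,
        noise_floor=noise_floor,
        diagnostics=diagnostics,
    )
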