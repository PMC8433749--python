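# hbsense

Software implementation of an absorption-based hemoglobin (Hb) monitor for
continuous bladder irrigation (CBI), developed and validated against a
physics-based synthetic sensor simulator.

After transurethral bladder or prostate surgery, the bladder is flushed
continuously to prevent clot formation, and nurses judge the blood content of
the outflow by eye — an error-prone task (beeturia and many drugs discolor
urine). An optical sensor on the outflow tube solves this: an 800 nm LED (an
isobestic wavelength, so oxygenated and deoxygenated Hb absorb identically)
shines through the tube onto a 10-bit monochrome camera, and the hemoglobin
concentration follows from the Beer–Lambert law

    I_t = I_0 · 10^(−ε·Δz·c)

where `I_t`/`I_0` are transmitted/incident intensities, `ε` the molar
absorptivity, `Δz` the optical path through the fluid and `c` the Hb
concentration (g/dL). With glass slips sealing the optics the law gains two
constant offsets, `I_t − ΔI_t = (I_0 − ΔI_0)·10^(−εΔz·c)`.

The package implements the full measurement chain plus the simulator that
stands in for the hardware:

| module | role |
| --- | --- |
| `hbsense.optics` | Beer–Lambert forward/inverse model, glass offsets, calibration fitting, Hb ↔ blood-% conversion |
| `hbsense.simulate` | synthetic 10-bit sensor frames: rib shadow artifacts, depth-dependent bubbles, read+shot noise, quantization |
| `hbsense.roi` | intensity-profile segmentation (background / transitional / artifact / measurement) and one-time ROI selection |
| `hbsense.exposure` | dual-exposure hysteresis controller (switch to high exposure at ≤ 80 counts, back to low at ≥ 800) |
| `hbsense.bubblenet` | conv+LSTM bubble detector trained on simulator sequences, majority-of-8 decision smoothing |
| `hbsense.stream` | gated 10 Hz measurement stream; first-order irrigation dynamics and time-constant estimation |
| `hbsense.cli` | `hbsense` command with `simulate`, `specimen-set`, `calibrate`, `select-roi`, `train`, `evaluate`, `measure`, `scenario` |

Air bubbles are the safety-critical failure mode: a bubble displaces absorbing
fluid, brightens the image and mimics *low* hemoglobin. A bubble that parks in
the light path is indistinguishable in a single frame from clear fluid at a
lower concentration, so detection must be temporal — convolution layers extract
optical features and an LSTM carries the sequence context. Decisions over
blocks of 8 frames use a majority vote with ties counted as "bubble", so one
misclassified frame can never flip a window, and flagged windows never update
the reported value.

## Worked example

```python
import numpy as np
from hbsense import optics, simulate, stream
from hbsense.exposure import ExposureState
from hbsense.simulate import ScenarioSpec, simulate_sequence
from hbsense.stream import StreamConfig, run_stream

# a noiseless ramp from clear fluid to 0.9 g/dL over 30 s
scen = ScenarioSpec(concentration=lambda t: 0.9 * t / 30.0,
                    duration=30.0, fps=25.0)
seq = simulate_sequence(scen, controller=ExposureState())
records = run_stream(seq, seq.roi, optics.CalibrationModel(),
                     config=StreamConfig(fps=25.0))

print(len(records), "records,", len(seq.switch_frames), "exposure switch")
worst = max(abs(r.hb_gdl - scen.concentration(r.timestamp))
            for r in records if r.valid)
print("worst valid error: %.4f g/dL" % worst)
print(records[150])
```

prints

```
300 records, 1 exposure switch
worst valid error: 0.0020 g/dL
MeasurementRecord(timestamp=15.1, hb_gdl=0.453, blood_pct=3.0,
                  exposure_mode='high', valid=True, reason='ok')
```

i.e. 30 s at the fixed 10 Hz output rate gives 300 records; the controller
switched from low to high exposure exactly once on the way up (near 0.44 g/dL
under the default calibration); every valid record tracks the true
concentration to within two thousandths of a g/dL (the 10-bit quantization
limit); and a record carries the
Hb value, its blood-volume equivalent (3.0% at 15 g/dL whole-blood Hb), the
exposure it was measured under and a validity reason code.

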