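# Methods

## Optical model

Hemoglobin concentration is inferred from transmitted light at 800 nm, an
isobestic wavelength of Hb/HbO2 so the measurement is insensitive to blood
oxygenation. Transmission follows the Beer–Lambert law; because the sensor
geometry is rigid, absorptivity and path length collapse into one effective
constant `epsilon_dz` (per g/dL), and a calibration is fully described by
four numbers: the incident count at zero concentration under the low
exposure (`incident_low`), the high/low exposure-time ratio, `epsilon_dz`,
and the trust bounds of the count domain (noise floor, saturation).

Glass slips sealing the optics attenuate the exerted and the captured light
by constant offsets (`delta_incident`, `delta_transmitted`). Applying the
offsets consistently in the forward and inverse direction cancels exactly;
this glass invariance is asserted in the tests.

Out-of-range counts are returned as *flagged* measurements rather than
errors, because the monitor must keep streaming: counts at or below the
noise floor pin the value to the range maximum of 3.23 g/dL (the true value
is at least that high — the safe direction), counts at or above saturation
pin it to zero with an overexposure flag. A count below the camera-side
glass offset is physically impossible and raises a corrupt-frame error.

Calibration fitting is ordinary least squares on `log10(count − ΔI_t)`
versus concentration, with one intercept per exposure mode and a shared
slope. The slope is shared because exposure time scales the collected
light, not the absorptivity. On noiseless synthetic specimen data the fit
is exact to machine precision; with 1% multiplicative count noise it
recovers the slope well within 5%.

### Simulator ground truth and the count thresholds

The default simulator calibration is `incident_low = 1020` (the low
exposure just saturates the 10-bit sensor on clear fluid),
`epsilon_dz = 2.5`, exposure ratio 8, noise floor 32. Under these values
the low-exposure regime runs out of signal near 0.60 g/dL, matching the
sensor's design point. The published controller thresholds — switch to
high exposure at a reading of 80 counts, back to low at 800 — are treated
as canonical controller constants; their concentration equivalents are
informative only, because no single Beer curve reproduces both the count
thresholds and their quoted g/dL equivalents simultaneously. Consequently
the full clinical range up to 3.23 g/dL is not resolvable above the noise
floor under this simulator calibration; the stream flags such readings
out-of-range, and exactness of the inversion algebra over the whole range
is verified with the count gates disabled.

## Frame simulator

Frames are 160×120, 10-bit monochrome. The column layout is fixed by the
assembly: dark background columns [0,20) and [140,160), partially lit
transitional bands [20,30) and [130,140), illuminated interval [30,130).
The background sits at a dark level of 8 counts so segmentation thresholds
are exercised against a real floor. Rendering steps:

1. illuminated columns carry the Beer–Lambert count for the scenario's
   concentration `c(t)`;
2. bubbles modify the *effective* concentration: a bubble of diameter
   fraction `s` of the tube displaces absorbing fluid, so affected pixels
   brighten by `10^(epsilon_dz·c·s·profile)`; a thin refraction rim
   slightly lengthens the path and darkens. At `c = 0` a bubble is
   invisible, as in reality. The three depth appearances: near the LED a
   small sharp disc (spherical-cap profile) with a dark rim; near the
   camera a fully defocused uniform brightening of the whole view; at
   the tube center a larger lens-like core with a curved dark edge;
3. reinforcement-rib artifacts multiply their columns by a Gaussian dip
   (or mild spike) of configured width and attenuation — static across a
   scenario, since the tube never moves during an irrigation;
4. a symmetric quadratic vertical vignette (default 2% at the frame edge
   rows) emulates uneven illumination;
5. Gaussian noise with variance `read_sd² + shot_scale·signal` (defaults
   2 counts and 0.05 — standard camera noise shape), then clipping to
   [0, 1023] and integer quantization.

Everything is keyed on explicit seeds; identical seeds give bit-identical
frames. Quantization can be disabled for algebra-level tests; with it
enabled, concentration recovery is quantization-limited (about 2·10⁻³ g/dL
near the switching thresholds), which the full-loop tests reflect with
their 0.01 g/dL budget.

What the simulator does *not* model: ray-traced tube optics, physically
derived rib refraction, bubble deformation and foam clusters, sensor
nonlinearity, temperature drift, and real fluid inhomogeneity. Passing
tests therefore demonstrate the correctness and robustness of the
*processing chain* under the stated phenomenology, not hardware-grade
performance.

## ROI selection

A horizontal intensity profile (per-column median over the central 50% of
rows, avoiding tube-wall curvature) is segmented relative to its own
baseline — the median of the illuminated columns — so segmentation is
independent of the current concentration. Columns deviating more than 5%
from baseline are artifacts (rib shadows in the rendered scenes are far
deeper than the 2% vignette and the default noise); maximal clean runs
are measurement intervals. The ROI is the widest measurement interval,
shrunk by a 2-column guard on each side, ties broken leftmost; if fewer
than 8 columns survive, ROI selection fails and the sensor must be
repositioned. Selection happens once per setup on a clear-fluid reference
frame and is reused for the whole acquisition (the artifacts are static).
All readings are medians, for robustness to hot pixels.

## Exposure control

A two-state hysteresis machine in the count domain: in low exposure a ROI
reading ≤ 80 switches to high; in high exposure ≥ 800 switches back
(inclusive comparisons, so the published threshold values are themselves
the triggering readings). Since 800/80 = 10 exceeds the exposure ratio 8,
the re-scaled reading after any switch lands strictly inside the dead
band: two consecutive frames can never both switch. This is asserted
exhaustively on random reading sequences. The frame on which a switch
fires is discarded rather than corrected. Startup is in low exposure,
matching the clear fluid at the beginning of an irrigation.

## Bubble detector

Architecture: three 3×3 conv blocks (8/16/32 channels, ReLU, stride-2 max
pooling), a 64-unit dense bottleneck, one LSTM layer (hidden 64) and a
sigmoid head — ~137k parameters, trained fully supervised with per-frame
binary cross-entropy, Adam (lr 3·10⁻³, halved every 20 epochs), gradient
clipping at global norm 5, up to 50 epochs with early stopping on
validation loss. Inputs are frames downscaled to 64×48 and normalized to
[0, 1]. The engine is plain numpy with hand-written backward passes,
verified against numerical differentiation; compute runs in float32.
Max pooling (rather than mean) is load-bearing: the smallest near-LED
bubble discs survive the downscaling stack only as few-pixel bright
spots.

The default benchmark is 120 simulator scenarios — 60 bubble transits
covering all three depth modes, both travel directions and sizes
0.25–0.7; 20 static (parked) bubbles; 40 bubble-free scenarios spanning
the low-exposure concentration range, all at default noise — split
70/15/15 by scenario with no leakage. Labels follow the enter/leave
convention: a frame is positive while any bubble is in view.

The static-bubble ambiguity is operationalized with matched pairs: a
fully defocused bubble of size `s` parked at concentration `c` settles
into frames statistically identical to clear fluid at `c·(1−s)`. A
per-frame-only baseline (same conv stack, no recurrence) sits at chance
on these pairs, while the recurrent detector — which sees the entry
transient and remembers it — exceeds 90% per-frame accuracy on them.
Per-window accuracy on benchmark scenarios unseen in training or model
selection exceeds 95%.

Decision smoothing: non-overlapping blocks of 8 consecutive frames,
majority vote of frames thresholded at 0.5, ties counting as "bubble".
Discarding a measurement is always safer than reporting a spuriously low
hemoglobin value, so every ambiguity resolves toward invalidation. The
window rule is verified exhaustively over all 256 patterns against a
brute-force vote count.

## Measurement stream

Frames arrive at 25 fps; output is fixed at 10 records/s. Each record
summarizes the frames captured since the previous output tick with
latest-value semantics: valid frames advance the held hemoglobin value,
and any rejected frame in the interval (bubble window, exposure switch,
untrusted count) marks the record invalid with its reason while the held
value is carried unchanged. Gating is therefore fail-safe — no
bubble-positive window or switch frame ever updates the reported value,
and none passes unreported between ticks. One residual error mode is
inherent to block-majority smoothing: at a bubble's entry or exit, the
few transition frames that fall into a mostly-clean window are outvoted,
so a reading within one window (≤ 0.32 s) of the boundary can briefly
reflect the bubble — the same single-frame tolerance that protects
against spurious detections works in both directions. 25 fps with 8-frame blocks
yields decisions at 3.125 Hz; the 10 Hz output simply repeats the latest
validated value, mirroring a double-buffered hand-off.

## Irrigation dynamics

Washout/wash-in of blood in the bladder-tube system is modeled as
first-order relaxation toward the current inflow target with separate
time constants: 33 s for rising concentration (bleeding onset) and 119 s
for falling (washed out), the defaults. `estimate_tau` fits the
log-residual to the asymptote (taken as the segment's final value) by
least squares, excluding samples within 5% of the step amplitude of the
asymptote where the tail bias and noise dominate; it recovers configured
constants within ~2% on noiseless traces and within 10% through the full
measured pipeline at default noise. The settling (response) time is
reported as 5 time constants: 5·119/60 = 9.9 min for fall, while
5·33/60 = 2.75 min prints as 2.8 at one decimal.

## Problem sizes

Defaults were chosen for single-CPU desk scale: 160×120 frames, 1.92 s
(48-frame) benchmark sequences, 120-scenario training corpus (~5 min
rendering + training), 300 s ramps for the switch-threshold measurements,
and 200–700 s noiseless traces for time-constant recovery.
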