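"""Synthetic frame generator: rendering physics, determinism, series."""

import dataclasses

import numpy as np
import pytest

from hbsense import optics, roi, simulate
from hbsense.simulate import (
    BubbleEvent,
    IlluminationGeometry,
    NoiseModel,
    RibSpec,
    ScenarioSpec,
    make_specimen_series,
    render_frame,
    simulate_sequence,
)


def constant(c):
    return lambda t: c


@pytest.fixture
def clean_scenario():
    """Noiseless, artifact-free, vignette-free, unquantized."""
    return ScenarioSpec(
        concentration=constant(0.0),
        duration=1.0,
        vignette_amp=0.0,
        quantize=False,
    )


class TestGeometry:
    def test_default_tiles_width(self):
        geo = IlluminationGeometry()
        assert geo.illuminated_cols == (30, 130)

    def test_non_abutting_regions_rejected(self):
        with pytest.raises(ValueError):
            IlluminationGeometry(background_cols=((0, 18), (140, 160)))


class TestRenderFrame:
    def test_uniform_field_at_zero_concentration(self, clean_scenario):
        frame = render_frame(clean_scenario, 0.0, "low")
        lo, hi = clean_scenario.geometry.illuminated_cols
        assert np.allclose(frame.pixels[:, lo:hi], 1020.0)
        assert np.allclose(frame.pixels[:, :20], simulate.DARK_LEVEL)

    def test_illuminated_level_follows_beer_lambert(self, clean_scenario):
        scen = dataclasses.replace(clean_scenario, concentration=constant(0.35))
        frame = render_frame(scen, 0.0, "low")
        lo, hi = scen.geometry.illuminated_cols
        expected = optics.predict_count(0.35, "low", scen.calibration)
        assert np.allclose(frame.pixels[:, lo:hi], expected)

    def test_rib_attenuates_its_columns(self, clean_scenario):
        scen = dataclasses.replace(
            clean_scenario,
            concentration=constant(0.1),
            ribs=[RibSpec(center_col=60, width=6, attenuation=0.6)],
        )
        frame = render_frame(scen, 0.0, "low")
        row = frame.pixels[60]
        assert row[60] == pytest.approx(0.6 * row[100], rel=1e-9)
        assert row[100] == pytest.approx(row[120], rel=1e-9)  # far columns untouched

    @pytest.mark.parametrize("depth_mode", ["near_led", "near_camera", "center"])
    def test_bubble_raises_mean_illuminated_intensity(self, clean_scenario, depth_mode):
        scen_b = dataclasses.replace(
            clean_scenario,
            concentration=constant(0.3),
            bubbles=[BubbleEvent(0.0, 1.0, depth_mode=depth_mode, size=0.5)],
        )
        scen_n = dataclasses.replace(clean_scenario, concentration=constant(0.3))
        lo, hi = scen_b.geometry.illuminated_cols
        for t in (0.2, 0.5, 0.8):
            with_bubble = render_frame(scen_b, t, "low").pixels[:, lo:hi].mean()
            without = render_frame(scen_n, t, "low").pixels[:, lo:hi].mean()
            assert with_bubble > without

    def test_quantized_frames_are_10bit_integers(self):
        scen = ScenarioSpec(
            concentration=constant(0.1), duration=1.0, noise=NoiseModel(seed=3)
        )
        frame = render_frame(scen, 0.5, "high")
        assert frame.pixels.dtype == np.uint16
        assert frame.pixels.min() >= 0 and frame.pixels.max() <= 1023

    def test_time_outside_duration_rejected(self, clean_scenario):
        with pytest.raises(ValueError):
            render_frame(clean_scenario, 2.0, "low")

    def test_truth_attached(self, clean_scenario):
        scen = dataclasses.replace(
            clean_scenario,
            concentration=constant(0.2),
            bubbles=[BubbleEvent(0.2, 0.6, size=0.4)],
        )
        assert render_frame(scen, 0.4, "low").truth == {"c": 0.2, "bubble": True}
        assert render_frame(scen, 0.8, "low").truth == {"c": 0.2, "bubble": False}


class TestDeterminism:
    def test_identical_seeds_give_bit_identical_sequences(self):
        def make():
            scen = ScenarioSpec(
                concentration=constant(0.2),
                duration=0.4,
                noise=NoiseModel(seed=7),
                bubbles=[BubbleEvent(0.1, 0.3, size=0.5)],
            )
            return simulate_sequence(scen)

        a, b = make(), make()
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.pixels, fb.pixels)

    def test_different_seeds_differ(self):
        def make(seed):
            scen = ScenarioSpec(
                concentration=constant(0.2), duration=0.2, noise=NoiseModel(seed=seed)
            )
            return simulate_sequence(scen).frames[0].pixels

        assert not np.array_equal(make(1), make(2))


class TestSimulateSequence:
    def test_single_bubble_yields_one_contiguous_label_block(self):
        scen = ScenarioSpec(
            concentration=constant(0.1),
            duration=2.0,
            bubbles=[BubbleEvent(0.5, 1.2, size=0.5)],
        )
        seq = simulate_sequence(scen)
        labels = seq.labels.astype(int)
        # exactly one rising and one falling edge
        assert np.sum(np.abs(np.diff(labels))) == 2
        assert labels.any() and not labels.all()

    def test_frame_count_and_timestamps(self):
        scen = ScenarioSpec(concentration=constant(0.1), duration=2.0, fps=25.0)
        seq = simulate_sequence(scen)
        assert len(seq) == 50
        assert seq.frames[1].timestamp == pytest.approx(0.04)

    def test_full_pipeline_recovers_concentration_unquantized(self):
        # noiseless, artifact-free, unquantized: inversion is exact
        scen = ScenarioSpec(
            concentration=lambda t: 0.05 + 0.1 * t,
            duration=1.0,
            vignette_amp=0.0,
            quantize=False,
        )
        seq = simulate_sequence(scen)
        for frame, reading in zip(seq.frames, seq.readings):
            m = optics.invert_count(reading, frame.exposure_mode, scen.calibration)
            assert m.hb_gdl == pytest.approx(frame.truth["c"], abs=1e-6)

    def test_rib_artifacts_static_across_sequence(self):
        scen = ScenarioSpec(
            concentration=constant(0.2),
            duration=0.4,
            ribs=[RibSpec(center_col=70, width=6, attenuation=0.5)],
        )
        seq = simulate_sequence(scen)
        profiles = [roi.extract_profile(f).values for f in seq.frames]
        dips = [int(np.argmin(p[30:130])) for p in profiles]
        assert len(set(dips)) == 1  # the shadow never moves


class TestSpecimenSeries:
    def test_default_series_has_12_specimens(self):
        series = make_specimen_series()
        assert len(series) == 12

    def test_hb_values_follow_dilution_arithmetic(self):
        series = make_specimen_series()
        pcts = [s.blood_pct for s in series]
        hbs = [s.hb_gdl for s in series]
        assert pcts == list(np.arange(0.0, 22.1, 2.0))
        assert hbs == pytest.approx([p / 100 * 15 for p in pcts])

    def test_degenerate_single_specimen(self):
        series = make_specimen_series(lo=0.0, hi=0.0)
        assert len(series) == 1 and series[0].blood_pct == 0.0

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            make_specimen_series(step=0.0)

    def test_each_specimen_has_both_exposures(self):
        series = make_specimen_series(lo=0.0, hi=4.0)
        for sp in series:
            assert set(sp.frames) == {"low", "high"}


class TestSequenceIO:
    def test_write_read_round_trip(self, tmp_path):
        scen = ScenarioSpec(
            concentration=constant(0.15),
            duration=0.4,
            noise=NoiseModel(seed=5),
            bubbles=[BubbleEvent(0.1, 0.3, size=0.4)],
        )
        seq = simulate_sequence(scen)
        simulate.write_sequence(seq, tmp_path / "seq")
        loaded = simulate.read_sequence(tmp_path / "seq")
        assert len(loaded) == len(seq)
        assert np.array_equal(loaded.labels, seq.labels)
        assert loaded.roi == seq.roi
        for fa, fb in zip(seq.frames, loaded.frames):
            assert np.array_equal(fa.pixels, fb.pixels)
            assert fa.exposure_mode == fb.exposure_mode
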