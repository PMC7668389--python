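"""Tests for parameter sampling, record assembly and junction smoothing."""

import numpy as np
import pytest

from ppgsynth import (
    PulseSpec,
    UnsupportedRateError,
    assemble,
    check_constraints,
    get_template,
    insert_premature_groups,
    pulse_waveform,
    regular_schedule,
    sample_params,
    spline_smooth,
)
from ppgsynth.assembler import PPGRecord


class TestSampleParams:
    def test_zero_sd_returns_exact_means(self, rng):
        from ppgsynth.templates import ParamDistribution, TemplateSet

        tpl = TemplateSet(
            name="regular",
            roles={
                "reference": ParamDistribution(
                    means=(0.997, 0.225, 0.641, 0.937, -1.471, 1.019),
                    sds=(0.0,) * 6,
                )
            },
        )
        p = sample_params(tpl, "reference", rng)
        assert p.as_array() == pytest.approx(
            [0.997, 0.225, 0.641, 0.937, -1.471, 1.019], abs=0
        )

    @pytest.mark.parametrize("template_name", ["regular", "compensation", "reset", "interpolation"])
    def test_all_draws_feasible(self, template_name):
        """Rejection sampling guarantees every returned draw satisfies the
        constraint set, for every role of every built-in template."""
        rng = np.random.default_rng(1)
        tpl = get_template(template_name)
        for role in tpl.roles:
            for _ in range(2500):
                assert check_constraints(sample_params(tpl, role, rng)) == []

    def test_identical_seed_gives_identical_draws(self):
        tpl = get_template("compensation")
        p1 = sample_params(tpl, "first", np.random.default_rng(99))
        p2 = sample_params(tpl, "first", np.random.default_rng(99))
        assert p1 == p2


class TestAssemble:
    def test_regular_record_grid_arithmetic(self):
        """5 s at 60 bpm, sd = 0, fs = 125: five 1 s beats -> 625 samples,
        onsets every 125 samples."""
        rng = np.random.default_rng(0)
        sched = regular_schedule(60, 0.0, 5.0, rng)
        rec = assemble(sched, get_template("regular"), 125.0, rng, length_s=5.0)
        assert rec.samples.size == 625
        assert rec.onsets.tolist() == [0, 125, 250, 375, 500]

    def test_labels_match_schedule_order(self):
        rng = np.random.default_rng(3)
        sched = insert_premature_groups(
            regular_schedule(60, 0.0, 20.0, rng), "reset", (0.607, 0.596), 2, rng
        )
        rec = assemble(sched, get_template("reset"), 100.0, rng)
        assert [r for r, _ in rec.beat_labels] == [b.role for b in sched]
        assert [g for _, g in rec.beat_labels] == [b.group_type for b in sched]

    def test_beats_match_standalone_pulse_waveform_bit_exactly(self):
        """Each assembled beat equals pulse_waveform run with the same draw
        on the same grid."""
        rng = np.random.default_rng(8)
        sched = regular_schedule(72, 40.0, 8.0, rng)
        rec = assemble(sched, get_template("regular"), 125.0, rng)
        bounds = list(rec.onsets) + [rec.samples.size]
        for k in range(rec.n_beats):
            n = bounds[k + 1] - bounds[k]
            z = pulse_waveform(rec.beat_params[k], PulseSpec(n / 125.0, 125.0))
            assert np.array_equal(rec.samples[bounds[k] : bounds[k + 1]], z)

    def test_no_cumulative_drift_in_beat_boundaries(self):
        """Sub-sample rounding never drifts: every boundary is within half a
        sample of the exact cumulative schedule time."""
        rng = np.random.default_rng(21)
        sched = regular_schedule(67, 60.0, 120.0, rng)
        rec = assemble(sched, get_template("regular"), 125.0, rng)
        exact = np.concatenate([[0.0], np.cumsum(sched.durations_ms)])[: rec.n_beats]
        assert np.max(np.abs(rec.onsets - exact * 125.0 / 1000.0)) <= 0.5

    def test_low_sampling_rate_rejected(self, rng):
        sched = regular_schedule(60, 0.0, 5.0, rng)
        with pytest.raises(UnsupportedRateError):
            assemble(sched, get_template("regular"), 20.0, rng)

    def test_truncation_to_requested_length(self):
        rng = np.random.default_rng(5)
        sched = regular_schedule(55, 70.0, 12.0, rng)
        rec = assemble(sched, get_template("regular"), 125.0, rng, length_s=12.0)
        assert rec.samples.size == round(12.0 * 125.0)
        assert all(o < rec.samples.size for o in rec.onsets)


class TestSplineSmooth:
    def _record(self, fs=100.0, seed=2, length=6.0):
        rng = np.random.default_rng(seed)
        sched = regular_schedule(60, 60.0, length, rng)
        return assemble(sched, get_template("regular"), fs, rng, length_s=length)

    def test_replaces_exactly_the_middle_window(self):
        """At fs = 100 Hz: 5 fit samples a side, 10 replaced per interior
        onset; everything else bit-identical."""
        rec = self._record(fs=100.0)
        sm = spline_smooth(rec)
        changed = np.flatnonzero(sm.samples != rec.samples)
        n_mid = round(0.1 * 100)
        half = n_mid // 2
        allowed = set()
        for onset in rec.onsets[1:]:
            allowed.update(range(onset - half, onset - half + n_mid))
        assert set(changed) <= allowed
        # every interior onset whose windows fit inside the record was smoothed
        n_fit = round(0.05 * 100)
        for onset in rec.onsets[1:]:
            if onset - half - n_fit < 0 or onset - half + n_mid + n_fit > rec.samples.size:
                continue  # legitimately skipped: window past the record end
            window = set(range(onset - half, onset - half + n_mid))
            assert window & set(changed)

    def test_smooth_input_is_left_nearly_unchanged(self):
        """A record that is already one smooth sinusoid is reproduced by the
        spline to well under 1e-3."""
        fs = 125.0
        n = 625
        t = np.arange(n) / fs
        rec = PPGRecord(
            samples=0.5 + 0.4 * np.sin(2 * np.pi * 1.0 * t),
            fs=fs,
            onsets=np.array([0, 125, 250, 375, 500]),
            beat_labels=tuple(("reference", None) for _ in range(5)),
        )
        sm = spline_smooth(rec)
        assert np.max(np.abs(sm.samples - rec.samples)) < 1e-3

    def test_junction_discontinuity_is_reduced(self):
        rec = self._record(fs=125.0, seed=17)
        sm = spline_smooth(rec)
        n_fit = round(0.05 * 125)
        n_mid = round(0.1 * 125)
        half = n_mid // 2
        for onset in rec.onsets[1:]:
            lo = onset - half
            mid = np.abs(np.diff(sm.samples[lo : lo + n_mid]))
            flank = np.abs(
                np.diff(
                    np.concatenate(
                        [sm.samples[lo - n_fit : lo], sm.samples[lo + n_mid : lo + n_mid + n_fit]]
                    )
                )
            )
            assert mid.max() <= 3 * flank.max() + 1e-12

    def test_first_onset_untouched(self):
        rec = self._record()
        sm = spline_smooth(rec)
        assert np.array_equal(sm.samples[:5], rec.samples[:5])

    def test_window_past_record_end_is_skipped(self, caplog):
        fs = 100.0
        rng = np.random.default_rng(4)
        sched = regular_schedule(60, 0.0, 2.0, rng)
        rec = assemble(sched, get_template("regular"), fs, rng)
        # fake an onset too close to the record end
        import dataclasses

        rec2 = dataclasses.replace(
            rec,
            onsets=np.array([0, 100, rec.samples.size - 3]),
            beat_labels=tuple(("reference", None) for _ in range(3)),
            beat_params=(),
        )
        with caplog.at_level("WARNING"):
            sm = spline_smooth(rec2)
        assert "skipping junction" in caplog.text
        assert np.array_equal(sm.samples[-3:], rec2.samples[-3:])


def test_record_reproducibility_end_to_end():
    def build(seed):
        rng = np.random.default_rng(seed)
        sched = insert_premature_groups(
            regular_schedule(70, 40.0, 20.0, rng), "compensation", (0.83, 1.17), 2, rng
        )
        return spline_smooth(
            assemble(sched, get_template("compensation"), 125.0, rng, length_s=20.0)
        )

    a, b = build(123), build(123)
    assert np.array_equal(a.samples, b.samples)
    assert np.array_equal(a.onsets, b.onsets)
    assert a.beat_labels == b.beat_labels
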