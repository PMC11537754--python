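"""Hemiretina mapping, N2pc construction and the difference-of-differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemiretina.conditions import ConditionLabel, map_hemiretina
from hemiretina.hemiretinal import (
    N2pcWave,
    export_epoch_means,
    hemiretinal_difference,
    n2pc,
    subject_hemiretinal_waves,
)
from hemiretina.synthetic_data import (
    SubjectSpec,
    expected_asymmetry_wave,
    simulate_condition_averages,
)
from hemiretina.timegrid import N_SAMPLES, SRATE_HZ, T0_MS, window_slice


class TestMapHemiretina:
    def test_left_eye_left_field_is_nasal(self):
        assert map_hemiretina("left", "left") == "nasal"

    def test_right_eye_left_field_is_temporal(self):
        assert map_hemiretina("right", "left") == "temporal"

    def test_full_table(self):
        assert map_hemiretina("left", "right") == "temporal"
        assert map_hemiretina("right", "right") == "nasal"

    @given(eye=st.sampled_from(["left", "right"]), field=st.sampled_from(["left", "right"]))
    @settings(max_examples=20, derandomize=True)
    def test_eye_swap_flips_output(self, eye, field):
        other = "right" if eye == "left" else "left"
        assert map_hemiretina(eye, field) != map_hemiretina(other, field)

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            map_hemiretina("both", "left")


def _n2pc_wave(values, hemiretina="nasal", sf="BSF"):
    return N2pcWave(
        values=np.asarray(values, float),
        srate_hz=SRATE_HZ,
        t0_ms=T0_MS,
        hemiretina=hemiretina,
        sf=sf,
        viewing_eye="left",
        stimulus_field="left" if hemiretina == "nasal" else "right",
        n_trials=100,
    )


class TestN2pc:
    def test_left_eye_right_field_is_left_minus_right_temporal(self, rng, wave_factory):
        label = ConditionLabel("left", "BSF", "fear_right")
        left = wave_factory(rng.normal(size=N_SAMPLES), pool="left_parietal", label=label)
        right = wave_factory(rng.normal(size=N_SAMPLES), pool="right_parietal", label=label)
        wave = n2pc(left, right, "right", "left")
        np.testing.assert_allclose(wave.values, left.values - right.values, atol=1e-12)
        assert wave.hemiretina == "temporal"

    def test_identical_pools_give_zero(self, wave_factory):
        v = np.linspace(-1, 1, N_SAMPLES)
        label = ConditionLabel("right", "LSF", "fear_left")
        wave = n2pc(wave_factory(v, "left_parietal", label), wave_factory(v, "right_parietal", label), "left", "right")
        np.testing.assert_allclose(wave.values, 0.0, atol=1e-12)

    def test_field_swap_negates(self, rng, wave_factory):
        label = ConditionLabel("left", "HSF", "fear_left")
        left = wave_factory(rng.normal(size=N_SAMPLES), "left_parietal", label)
        right = wave_factory(rng.normal(size=N_SAMPLES), "right_parietal", label)
        a = n2pc(left, right, "left", "left")
        b = n2pc(left, right, "right", "left")
        np.testing.assert_allclose(a.values, -b.values, atol=1e-12)

    def test_mismatched_axes_rejected(self, rng, wave_factory):
        label = ConditionLabel("left", "BSF", "fear_left")
        left = wave_factory(rng.normal(size=N_SAMPLES), "left_parietal", label)
        short = wave_factory(rng.normal(size=N_SAMPLES - 1), "right_parietal", label)
        with pytest.raises(ValueError):
            n2pc(left, short, "left", "left")


class TestHemiretinalDifference:
    def test_identical_waves_give_zero(self, rng):
        v = rng.normal(size=N_SAMPLES)
        out = hemiretinal_difference(_n2pc_wave(v, "nasal"), _n2pc_wave(v, "temporal"))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_swap_flips_sign_exactly(self, rng):
        nasal = _n2pc_wave(rng.normal(size=N_SAMPLES), "nasal")
        temporal = _n2pc_wave(rng.normal(size=N_SAMPLES), "temporal")
        a = hemiretinal_difference(nasal, temporal)
        b = hemiretinal_difference(temporal, nasal)
        np.testing.assert_array_equal(a.values, -b.values)

    def test_constant_construction(self):
        nasal = _n2pc_wave(np.full(N_SAMPLES, -0.9), "nasal")
        temporal = _n2pc_wave(np.zeros(N_SAMPLES), "temporal")
        out = hemiretinal_difference(nasal, temporal)
        np.testing.assert_allclose(out.values, -0.9, atol=1e-12)

    def test_sf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="SF"):
            hemiretinal_difference(_n2pc_wave(np.zeros(N_SAMPLES), "nasal", "BSF"),
                                   _n2pc_wave(np.zeros(N_SAMPLES), "temporal", "HSF"))

    def test_same_hemiretina_rejected(self):
        with pytest.raises(ValueError):
            hemiretinal_difference(_n2pc_wave(np.zeros(N_SAMPLES), "nasal"),
                                   _n2pc_wave(np.zeros(N_SAMPLES), "nasal"))


class TestExportEpochMeans:
    def test_zero_wave(self):
        out = export_epoch_means(hemiretinal_difference(
            _n2pc_wave(np.zeros(N_SAMPLES)), _n2pc_wave(np.zeros(N_SAMPLES), "temporal")))
        assert all(v == 0.0 for v in out.values())

    def test_boxcar_isolated_to_n170_window(self):
        v = np.zeros(N_SAMPLES)
        v[window_slice(155, 170)] = 1.0
        wave = hemiretinal_difference(_n2pc_wave(v), _n2pc_wave(np.zeros(N_SAMPLES), "temporal"))
        means = export_epoch_means(wave)
        assert means["N170"] == pytest.approx(1.0)
        assert means["P1.1"] == means["P1.2"] == means["EPN"] == 0.0

    def test_matches_direct_means(self, rng):
        v = rng.normal(size=N_SAMPLES)
        wave = hemiretinal_difference(_n2pc_wave(v), _n2pc_wave(np.zeros(N_SAMPLES), "temporal"))
        means = export_epoch_means(wave)
        from hemiretina.erp_measures import CANONICAL_WINDOWS
        for name, (lo, hi) in CANONICAL_WINDOWS.items():
            assert abs(means[name] - v[window_slice(lo, hi)].mean()) < 1e-12


def _subject_waves(eye, gt, spec_seed=(1,)):
    from hemiretina.conditions import SF_BANDS
    from hemiretina.preprocessing import ERPWaveform

    def make_wave(values, pool, label, n_trials):
        return ERPWaveform(values=np.asarray(values, float), srate_hz=SRATE_HZ, t0_ms=T0_MS,
                           pool=pool, label=label, n_trials=n_trials)

    spec = SubjectSpec(1, eye, spec_seed, (2,), {})
    waves = simulate_condition_averages(spec, gt, 100)
    fear_pools = {}
    for sf in SF_BANDS:
        for tt in ("fear_left", "fear_right"):
            label = ConditionLabel(eye, sf, tt)
            l, r = waves[(sf, tt)]
            fear_pools[(sf, tt)] = (
                make_wave(l, "left_parietal", label, 100),
                make_wave(r, "right_parietal", label, 100),
            )
    return subject_hemiretinal_waves(fear_pools, eye)


class TestEndToEnd:
    def test_injected_asymmetry_scales_linearly(self, quiet_gt):
        """Noise off: the hemiretinal wave equals the injected bump scaled by a."""
        import dataclasses

        for a in (-0.9, -0.45, 1.2):
            gt = dataclasses.replace(quiet_gt, asymmetry_uv={("BSF", "nasal"): a})
            _, hemidiff = _subject_waves("left", gt)
            expected = expected_asymmetry_wave(gt, a)
            np.testing.assert_allclose(hemidiff["BSF"].values, expected, atol=1e-10)
            np.testing.assert_allclose(hemidiff["HSF"].values, 0.0, atol=1e-10)

    def test_eye_counterbalancing_invariance(self, quiet_gt):
        """Relabelling the eye (with mirrored fields) leaves the hemiretinal wave unchanged."""
        _, left_eye = _subject_waves("left", quiet_gt)
        _, right_eye = _subject_waves("right", quiet_gt)
        for sf in ("BSF", "LSF", "HSF"):
            np.testing.assert_allclose(left_eye[sf].values, right_eye[sf].values, atol=1e-10)

    def test_neutral_trials_refused(self, quiet_gt, wave_factory):
        label = ConditionLabel("left", "BSF", "neutral")
        pools = {("BSF", "neutral"): (wave_factory(np.zeros(N_SAMPLES), "left_parietal", label),
                                      wave_factory(np.zeros(N_SAMPLES), "right_parietal", label))}
        with pytest.raises(ValueError, match="neutral"):
            subject_hemiretinal_waves(pools, "left")
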