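"""Cohort generator: design fidelity, determinism, and planted effects."""

import numpy as np
import pytest

from eegwm.connectivity import fir_bandpass, instantaneous_phase, phase_si
from eegwm.cfc import cfc_si
from eegwm.synthetic import (
    CohortConfig,
    ConfigError,
    generate_cohort,
    null_config,
    plant_cfc,
    plant_phase_coupling,
)

FS = 256


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,fragment",
        [
            ({"n_participants": 0}, "n_participants"),
            ({"sampling_rate": 100}, "sampling_rate"),
            ({"segment_duration_range": (0.1, 0.2)}, "segment_duration_range"),
            ({"cfc_effect": {"theta-beta": {"visual": 1.5}}}, "depth"),
            ({"cfc_effect": {"beta-theta": {"visual": 0.5}}}, "beta-theta"),
            ({"load_coupling_effect": {"theta": (1, 2, 3)}}, "6 values"),
            ({"noise_sd": -1.0}, "noise_sd"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, fragment):
        with pytest.raises(ConfigError, match=fragment):
            CohortConfig(**kwargs).validate()


class TestCohortStructure:
    def test_design_fidelity(self, tiny_cohort):
        cfg, pairs, truth = tiny_cohort
        assert len(pairs) == cfg.n_participants
        for rec_v, rec_av in pairs:
            assert rec_v.modality_tag == "visual"
            assert rec_av.modality_tag == "audiovisual"
            for rec in (rec_v, rec_av):
                labels = [l for _, l in rec.events]
                assert labels == (
                    ["baseline_pre"]
                    + [f"load_{k}" for k in range(1, 7)]
                    + ["baseline_post"]
                )
                assert rec.data.shape[0] == 64

    def test_durations_in_printed_range(self):
        cfg = null_config(n_participants=1, seed=3)
        (rec_v, _), _ = generate_cohort(cfg)[0][0], None
        onsets = [o for o, _ in rec_v.events] + [rec_v.n_samples]
        durs = np.diff(onsets) / rec_v.fs
        assert durs[0] == 60 and durs[-1] == 60
        assert np.all((durs[1:-1] >= 21) & (durs[1:-1] <= 37))

    def test_same_seed_bit_identical(self):
        cfg = null_config(
            n_participants=1, segment_duration_range=(6.0, 8.0),
            baseline_duration=10.0, seed=9,
        )
        (a_v, a_av), _ = generate_cohort(cfg)[0][0], None
        (b_v, b_av), _ = generate_cohort(cfg)[0][0], None
        assert np.array_equal(a_v.data, b_v.data)
        assert np.array_equal(a_av.data, b_av.data)
        assert a_v.events == b_v.events

    def test_ground_truth_covers_each_segment(self):
        cfg = CohortConfig(n_participants=1, segment_duration_range=(6.0, 8.0),
                           baseline_duration=10.0, seed=4)
        _, truth = generate_cohort(cfg)
        counts = truth.records.groupby(["modality", "segment"]).size()
        assert (counts == counts.iloc[0]).all()
        assert set(truth.records["segment"]) == set(range(1, 7))


class TestPlantPhaseCoupling:
    def _measure(self, a, b):
        fa = instantaneous_phase(fir_bandpass(a, 4, 8, FS))
        fb = instantaneous_phase(fir_bandpass(b, 4, 8, FS))
        core = slice(2 * FS, -2 * FS)
        return phase_si(fa[core], fb[core])

    def test_infinite_concentration_locks_phases(self):
        n = 30 * FS
        a, b = plant_phase_coupling(
            np.zeros(n), np.zeros(n), (4, 8), np.inf, seed=1, fs=FS
        )
        assert self._measure(a, b) > 0.99

    def test_zero_concentration_uncouples(self):
        n = 30 * FS
        a, b = plant_phase_coupling(
            np.zeros(n), np.zeros(n), (4, 8), 0.0, seed=1, fs=FS
        )
        assert self._measure(a, b) < 0.1

    def test_measured_si_matches_lag_resultant_oracle(self):
        n = 30 * FS
        a, b, lags = plant_phase_coupling(
            np.zeros(n), np.zeros(n), (4, 8), 2.0, seed=6, fs=FS, return_lags=True
        )
        core = slice(2 * FS, -2 * FS)
        oracle = phase_si(np.zeros(n)[core], -lags[core])
        assert self._measure(a, b) == pytest.approx(oracle, abs=0.05)

    def test_si_monotone_in_concentration(self):
        n = 20 * FS
        means = []
        for kappa in (0.0, 2.0, 8.0):
            vals = [
                self._measure(
                    *plant_phase_coupling(
                        np.zeros(n), np.zeros(n), (4, 8), kappa, seed=s, fs=FS
                    )
                )
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_bad_band_and_negative_concentration_rejected(self):
        with pytest.raises(ConfigError):
            plant_phase_coupling(np.zeros(100), np.zeros(100), (4, 200), 1.0, fs=FS)
        with pytest.raises(ConfigError):
            plant_phase_coupling(np.zeros(100), np.zeros(100), (4, 8), -1.0, fs=FS)


class TestPlantCfc:
    def test_output_length_and_depth_validation(self):
        x = np.zeros(1000)
        assert plant_cfc(x, 6.0, 21.0, 0.5, seed=0, fs=FS).shape == x.shape
        with pytest.raises(ConfigError):
            plant_cfc(x, 6.0, 21.0, 1.5, seed=0, fs=FS)
        with pytest.raises(ConfigError):
            plant_cfc(x, 21.0, 6.0, 0.5, seed=0, fs=FS)

    def test_cfc_si_monotone_in_depth(self, rng):
        n = 20 * FS
        means = []
        for depth in (0.0, 0.5, 1.0):
            vals = [
                cfc_si(
                    plant_cfc(
                        2 * np.random.default_rng(100 + s).standard_normal(n),
                        6.0, 21.0, depth, seed=s, fs=FS, a_low=4.0, a_high=3.0,
                    ),
                    5.0, 21.0, FS,
                )
                for s in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
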