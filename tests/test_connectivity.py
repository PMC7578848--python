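"""FIR filtering, instantaneous phase, and the synchronization index."""

import numpy as np
import pytest

from eegwm.connectivity import (
    ConnectivityError,
    channel_connectivity_features,
    fir_bandpass,
    instantaneous_phase,
    pairwise_connectivity,
    phase_si,
    roi_summary,
    si_matrix,
)
from eegwm.io import CHANNELS_64
from eegwm.segmentation import segment_acquisition
from eegwm.synthetic import plant_phase_coupling

FS = 256


class TestFirBandpass:
    def test_in_band_amplitude_preserved(self):
        t = np.arange(30 * FS) / FS
        x = np.sin(2 * np.pi * 6 * t)
        y = fir_bandpass(x, 4, 8, FS)
        core = slice(4 * FS, -4 * FS)
        assert 0.95 < y[core].std() / x[core].std() < 1.05

    def test_out_of_band_attenuated(self):
        t = np.arange(30 * FS) / FS
        x = np.sin(2 * np.pi * 20 * t)
        y = fir_bandpass(x, 4, 8, FS)
        assert y[4 * FS : -4 * FS].std() < 0.1 * x.std()

    def test_zero_phase(self):
        t = np.arange(30 * FS) / FS
        x = np.sin(2 * np.pi * 6 * t)
        y = fir_bandpass(x, 4, 8, FS)
        core = slice(4 * FS, -4 * FS)
        lags = np.arange(-10, 11)
        xc = [np.dot(x[core], np.roll(y, l)[core]) for l in lags]
        assert lags[np.argmax(xc)] == 0

    def test_short_series_and_bad_band_rejected(self):
        with pytest.raises(ConnectivityError):
            fir_bandpass(np.zeros(100), 4, 8, FS)
        with pytest.raises(ConnectivityError):
            fir_bandpass(np.zeros(10000), 4, 200, FS)


class TestInstantaneousPhase:
    def test_phase_advances_at_signal_frequency(self):
        t = np.arange(10 * FS) / FS
        phi = instantaneous_phase(np.cos(2 * np.pi * 6 * t))
        dphi = np.diff(np.unwrap(phi[FS:-FS]))
        assert dphi.mean() * FS / (2 * np.pi) == pytest.approx(6.0, abs=0.01)

    def test_sin_cos_quadrature(self):
        t = np.arange(10 * FS) / FS
        pc = instantaneous_phase(np.cos(2 * np.pi * 6 * t))[FS:-FS]
        ps = instantaneous_phase(np.sin(2 * np.pi * 6 * t))[FS:-FS]
        diff = np.angle(np.exp(1j * (pc - ps)))
        assert np.allclose(diff, np.pi / 2, atol=0.01)

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(2000)
        assert np.allclose(
            instantaneous_phase(x), instantaneous_phase(2 * x), atol=1e-9
        )


class TestPhaseSi:
    def test_identical_series_is_exactly_one(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 2560)
        assert phase_si(phi, phi) == 1.0

    def test_uniform_phasor_fan_is_zero(self):
        phi = np.linspace(0, 4 * np.pi, 400, endpoint=False)
        assert phase_si(np.zeros_like(phi), phi) == pytest.approx(0.0, abs=1e-20)

    def test_swap_symmetry_and_global_shift_invariance(self, rng):
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        assert phase_si(a, b) == phase_si(b, a)
        assert abs(phase_si(a + 0.7, b + 0.7) - phase_si(a, b)) < 1e-12

    def test_null_level_is_one_over_n(self, rng):
        n, n_seeds = 10_000, 100
        vals = [
            phase_si(np.zeros(n), rng.uniform(-np.pi, np.pi, n))
            for _ in range(n_seeds)
        ]
        # E[SI] = 1/n for independent phases; SI/n ~ Exp(1) so se = 1/(n sqrt(k))
        se = 1 / (n * np.sqrt(n_seeds))
        assert abs(np.mean(vals) - 1 / n) < 3 * se

    def test_unsquared_option_is_sqrt(self, rng):
        a = rng.uniform(-np.pi, np.pi, 300)
        b = rng.uniform(-np.pi, np.pi, 300)
        assert phase_si(a, b) == pytest.approx(phase_si(a, b, squared=False) ** 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConnectivityError):
            phase_si(np.zeros(5), np.zeros(6))

    def test_si_matrix_agrees_with_pairwise(self, rng):
        phases = rng.uniform(-np.pi, np.pi, (5, 800))
        mat = si_matrix(phases)
        for i in range(5):
            assert mat[i, i] == pytest.approx(1.0, abs=1e-12)
            for j in range(5):
                assert mat[i, j] == pytest.approx(
                    phase_si(phases[i], phases[j]), abs=1e-12
                )


class TestPairwiseConnectivity:
    def test_pair_count_excludes_neighbors(self, tiny_runs, adjacency):
        run_v, _ = tiny_runs
        si = pairwise_connectivity(run_v, "theta", adjacency, CHANNELS_64)
        assert set(si) == {f"load_{k}" for k in range(1, 7)}
        finite = np.isfinite(si["load_1"]).sum() // 2  # symmetric matrix
        assert finite == 64 * 63 // 2 - adjacency.n_pairs

    def test_planted_pair_has_maximal_si(self, tiny_cohort, adjacency):
        _, pairs, _ = tiny_cohort
        rec = pairs[0][0]
        data = rec.data.copy()
        i, j = rec.channel_index("F3"), rec.channel_index("PO3")
        data[i], data[j] = plant_phase_coupling(
            data[i], data[j], (4, 8), 50.0, seed=5, fs=rec.fs, amplitude=60.0
        )
        run = segment_acquisition(
            type(rec)(
                data=data, fs=rec.fs, channel_names=rec.channel_names,
                events=rec.events, modality_tag=rec.modality_tag,
                participant_id=rec.participant_id,
            )
        )
        si = pairwise_connectivity(run, "theta", adjacency, CHANNELS_64)["load_2"]
        assert np.nanargmax(si) in (i * 64 + j, j * 64 + i)

    def test_baselines_included_on_request(self, tiny_runs, adjacency):
        run_v, _ = tiny_runs
        si = pairwise_connectivity(
            run_v, "theta", adjacency, CHANNELS_64, include_baselines=True
        )
        assert "baseline_pre" in si and "baseline_post" in si


class TestReductions:
    def test_uniform_si_gives_constant_features(self):
        si = np.full((64, 64), 0.3)
        np.fill_diagonal(si, np.nan)
        feats = channel_connectivity_features(si)
        assert feats.shape == (64,)
        assert np.allclose(feats, 0.3)

    def test_roi_summary_uniform_and_labeling(self, roi_map):
        si = np.full((64, 64), 0.2)
        np.fill_diagonal(si, np.nan)
        out = roi_summary(si, roi_map, CHANNELS_64)
        assert len(out) == 10
        assert all(v == pytest.approx(0.2) for v in out.values())

    def test_frontopolar_pair_feeds_lf_rf_cell(self, roi_map):
        si = np.zeros((64, 64))
        i, j = CHANNELS_64.index("Fp1"), CHANNELS_64.index("Fp2")
        si[i, j] = si[j, i] = 1.0
        out = roi_summary(si, roi_map, CHANNELS_64)
        assert out[("left_frontal", "right_frontal")] > 0
        assert out[("left_frontal", "left_parieto_occipital")] == 0
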