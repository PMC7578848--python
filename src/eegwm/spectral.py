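"""Baseline-normalized band power features.

Per segment and channel, a Welch power spectral density (2-s Hann
windows, 50% overlap) is normalized to baseline activity in decibels,
10*log10(P_task / P_baseline), and averaged within each of the five
conventional bands. The baseline spectrum is the arithmetic mean of the
pre- and post-task baseline PSDs. Per participant this yields a
task(2) x load(6) x channel(64) x band(5) tensor, which is realigned
into one observations x channels matrix per band for classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import welch

from .bands import POWER_BANDS, BandTable
from .decoding import FeatureMatrix
from .segmentation import SegmentedRun


class SpectralError(Exception):
    pass


def compute_psd(
    segment: np.ndarray, fs: float, window_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per channel; returns (freqs, psd) with psd channels x freqs."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    nperseg = int(round(window_s * fs))
    if segment.shape[-1] < nperseg:
        raise SpectralError(
            f"segment of {segment.shape[-1]} samples is shorter than the "
            f"{nperseg}-sample analysis window"
        )
    freqs, psd = welch(
        segment, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=-1
    )
    return freqs, psd


def db_normalize(psd_task: np.ndarray, psd_baseline: np.ndarray) -> np.ndarray:
    """Decibel normalization 10*log10(task / baseline), bin-wise."""
    psd_task = np.asarray(psd_task, dtype=float)
    psd_baseline = np.asarray(psd_baseline, dtype=float)
    if np.any(psd_baseline <= 0):
        raise SpectralError("baseline PSD must be strictly positive at every bin")
    return 10.0 * np.log10(psd_task / psd_baseline)


def band_average(
    freqs: np.ndarray, db_spectrum: np.ndarray, band_table: BandTable = POWER_BANDS
) -> np.ndarray:
    """Mean dB value over the bins of each band (edges inclusive)."""
    freqs = np.asarray(freqs)
    db_spectrum = np.asarray(db_spectrum)
    out = []
    for band in band_table:
        mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        if not mask.any():
            raise SpectralError(
                f"frequency grid has no bins inside band {band.name!r} "
                f"({band.f_lo}-{band.f_hi} Hz)"
            )
        out.append(db_spectrum[..., mask].mean(axis=-1))
    return np.stack(out, axis=-1)


def segment_band_power(
    run: SegmentedRun, band_table: BandTable = POWER_BANDS, window_s: float = 2.0
) -> np.ndarray:
    """Normalized band power per load segment: load(6) x channel x band."""
    freqs, psd_pre = compute_psd(run.baseline_pre, run.fs, window_s)
    _, psd_post = compute_psd(run.baseline_post, run.fs, window_s)
    baseline = (psd_pre + psd_post) / 2.0
    rows = []
    for seg in run.load_segments:
        _, psd = compute_psd(seg, run.fs, window_s)
        rows.append(band_average(freqs, db_normalize(psd, baseline), band_table))
    return np.stack(rows, axis=0)


def assemble_power_tensor(
    run_visual: SegmentedRun,
    run_audiovisual: SegmentedRun,
    band_table: BandTable = POWER_BANDS,
    window_s: float = 2.0,
) -> np.ndarray:
    """One participant's task(2) x load(6) x channel x band power tensor."""
    if run_visual.modality_tag == run_audiovisual.modality_tag:
        raise SpectralError("need one run per modality")
    runs = {r.modality_tag: r for r in (run_visual, run_audiovisual)}
    return np.stack(
        [
            segment_band_power(runs["visual"], band_table, window_s),
            segment_band_power(runs["audiovisual"], band_table, window_s),
        ],
        axis=0,
    )


def realign_power_features(
    tensors: dict[str, np.ndarray],
    channel_names: list[str],
    band_table: BandTable = POWER_BANDS,
) -> dict[str, FeatureMatrix]:
    """Realign per-participant tensors into one FeatureMatrix per band.

    Rows are participant x task x load-segment observations
    (n_participants * 2 * 6 of them), columns the 64 channels.
    """
    band_names = band_table.names
    per_band: dict[str, list[np.ndarray]] = {b: [] for b in band_names}
    meta_rows = []
    for pid, tensor in tensors.items():
        if not np.all(np.isfinite(tensor)):
            raise SpectralError(f"non-finite power values for participant {pid}")
        for t_idx, modality in enumerate(("visual", "audiovisual")):
            for seg in range(6):
                meta_rows.append(
                    {"participant": pid, "modality": modality, "segment": seg + 1}
                )
                for b_idx, b in enumerate(band_names):
                    per_band[b].append(tensor[t_idx, seg, :, b_idx])
    meta = pd.DataFrame(meta_rows)
    return {
        b: FeatureMatrix(
            values=np.array(per_band[b]),
            meta=meta.copy(),
            family="power",
            band=b,
            channel_names=list(channel_names),
        )
        for b in band_names
    }
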