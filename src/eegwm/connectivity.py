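"""Inter-site phase synchronization between non-neighbor channel pairs.

The recipe per band: zero-phase least-squares FIR band-pass of the
continuous recording, Hilbert transform for instantaneous phase, cutting
into the baseline and six load segments, trimming 200 ms per edge, then
for every non-neighbor channel pair the synchronization index

    SI = | (1/n) * sum_t exp(i (phi2_t - phi1_t)) | ** 2,

the squared length of the mean resultant vector of the phase
differences. SI is 1 for perfectly locked phases and has expectation
1/n for independent ones. The 64 classification features per segment
are each channel's mean SI over all of its non-neighbor partners;
ROI-pair means are reported separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.fft import ifft, irfft, next_fast_len, rfft
from scipy.signal import firls, hilbert

from .bands import CONNECTIVITY_FILTER_BANDS
from .decoding import FeatureMatrix
from .io import AdjacencyMap, ROIMap
from .segmentation import SegmentedRun, trim_edges


class ConnectivityError(Exception):
    pass


def design_fir_bandpass(f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Least-squares linear-phase FIR band-pass.

    Order is at least 3 cycles of the low band edge and is lengthened so
    the transition band (15% of the low edge, capped at half the pass
    bandwidth so narrow filters stay selective) is actually realized;
    this keeps the two-pass passband gain flat to well within 5%.
    """
    nyq = fs / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ConnectivityError(
            f"band ({f_lo}, {f_hi}) Hz must lie strictly inside (0, {nyq}) Hz"
        )
    trans = min(0.15 * f_lo, 0.5 * (f_hi - f_lo))
    taps = max(int(3 * fs / f_lo), int(3.3 * fs / trans))
    taps += (taps + 1) % 2  # firls needs an odd tap count
    bands = [
        0.0,
        max(f_lo - trans, 1e-3),
        f_lo,
        f_hi,
        min(f_hi + trans, nyq * 0.999),
        nyq,
    ]
    return firls(taps, bands, [0, 0, 1, 1, 0, 0], fs=fs)


def _zero_phase_fir(
    x: np.ndarray, b: np.ndarray, analytic: bool = False
) -> np.ndarray:
    """Apply a symmetric FIR forward and backward (zero phase).

    For a linear-phase FIR this equals convolution with the filter's
    autocorrelation; computed by FFT with odd-reflection edge padding,
    which matches filtfilt away from the very ends but scales to long
    multi-channel recordings. With ``analytic=True`` the analytic
    (Hilbert) signal of the filtered series is returned from the same
    FFT pass instead of the real series.
    """
    pad = len(b)
    left = 2 * x[..., :1] - x[..., pad:0:-1]
    right = 2 * x[..., -1:] - x[..., -2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right], axis=-1)
    c = np.convolve(b, b[::-1])  # zero-phase kernel, length 2*len(b)-1
    n_xp = xp.shape[-1]
    m = next_fast_len(n_xp + len(c) - 1)
    start = (len(c) - 1) // 2  # center of the "same"-mode convolution
    sl = slice(start + pad, start + n_xp - pad)
    if not analytic:
        spec = rfft(xp, m, axis=-1) * rfft(c, m)
        return irfft(spec, m, axis=-1)[..., sl]
    # single precision: the phases and envelopes downstream are estimated
    # from tens of seconds of data, far above float32 resolution
    spec = rfft(xp.astype(np.float32), m, axis=-1) * rfft(
        c.astype(np.float32), m
    )
    full = np.zeros((*spec.shape[:-1], m), dtype=np.complex64)
    full[..., 0] = spec[..., 0]
    half = (m + 1) // 2
    full[..., 1:half] = 2.0 * spec[..., 1:half]
    if m % 2 == 0:
        full[..., m // 2] = spec[..., m // 2]
    return ifft(full, axis=-1)[..., sl]


def fir_bandpass(x: np.ndarray, f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Zero-phase band-pass: linear-phase FIR applied forward then backward."""
    x = np.asarray(x, dtype=float)
    b = design_fir_bandpass(f_lo, f_hi, fs)
    if x.shape[-1] <= 3 * len(b):
        raise ConnectivityError(
            f"series of {x.shape[-1]} samples too short for a {len(b)}-tap filter"
        )
    return _zero_phase_fir(x, b)


def analytic_bandpass(x: np.ndarray, f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Analytic signal of the zero-phase band-passed series (one FFT pass)."""
    x = np.asarray(x, dtype=float)
    b = design_fir_bandpass(f_lo, f_hi, fs)
    if x.shape[-1] <= 3 * len(b):
        raise ConnectivityError(
            f"series of {x.shape[-1]} samples too short for a {len(b)}-tap filter"
        )
    return _zero_phase_fir(x, b, analytic=True)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal, wrapped to (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    z = hilbert(x, N=next_fast_len(n), axis=-1)[..., :n]
    return np.angle(z)


def phase_si(phi1: np.ndarray, phi2: np.ndarray, squared: bool = True) -> float:
    """Synchronization index of two phase series.

    Squared mean resultant length of the phase difference by default; the
    unsquared mean resultant length is available with ``squared=False``
    (both are order-preserving).
    """
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape != phi2.shape:
        raise ConnectivityError("phase series lengths differ")
    r = np.abs(np.mean(np.exp(1j * (phi2 - phi1))))
    return float(r**2 if squared else r)


def si_matrix(phases: np.ndarray, squared: bool = True) -> np.ndarray:
    """All-pairs SI from a channels x samples phase array (vectorized)."""
    u = np.exp(1j * np.asarray(phases))
    r = np.abs(u.conj() @ u.T) / phases.shape[-1]
    return r**2 if squared else r


def _neighbor_mask(channel_names: list[str], adjacency: AdjacencyMap) -> np.ndarray:
    n = len(channel_names)
    mask = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(channel_names):
        for j, b in enumerate(channel_names):
            if i != j and adjacency.are_neighbors(a, b):
                mask[i, j] = True
    return mask


def band_phases(run: SegmentedRun, band: str) -> dict[str, np.ndarray]:
    """Instantaneous phase per labeled span, filtered on the continuous data.

    Filtering and the Hilbert transform are applied to the whole recording
    before cutting, so segment edges carry no filter transients beyond the
    200-ms trim.
    """
    if band not in CONNECTIVITY_FILTER_BANDS:
        raise ConnectivityError(f"unknown connectivity band {band!r}")
    f_lo, f_hi = CONNECTIVITY_FILTER_BANDS[band]
    if run.continuous is not None and run.spans is not None:
        phase = np.angle(analytic_bandpass(run.continuous, f_lo, f_hi, run.fs))
        return {label: phase[:, s:e] for label, (s, e) in run.spans.items()}
    out = {}
    for label in ["baseline_pre"] + [f"load_{k}" for k in range(1, 7)] + ["baseline_post"]:
        seg = run.segment(label)
        out[label] = np.angle(analytic_bandpass(seg, f_lo, f_hi, run.fs))
    return out


def pairwise_connectivity(
    run: SegmentedRun,
    band: str,
    adjacency: AdjacencyMap,
    channel_names: list[str],
    trim_s: float = 0.2,
    include_baselines: bool = False,
    squared: bool = True,
) -> dict[str, np.ndarray]:
    """Per-segment channel x channel SI with neighbors and diagonal masked.

    Returns a dict label -> 64 x 64 array; masked entries are NaN.
    """
    phases = band_phases(run, band)
    mask = _neighbor_mask(channel_names, adjacency)
    labels = [f"load_{k}" for k in range(1, 7)]
    if include_baselines:
        labels = ["baseline_pre"] + labels + ["baseline_post"]
    out = {}
    for label in labels:
        phi = trim_edges(phases[label], run.fs, trim_s)
        si = si_matrix(phi, squared=squared)
        si[mask] = np.nan
        np.fill_diagonal(si, np.nan)
        out[label] = si
    return out


def channel_connectivity_features(si: np.ndarray) -> np.ndarray:
    """Per channel, the mean SI over all its non-neighbor partners."""
    return np.nanmean(np.asarray(si), axis=1)


def roi_summary(
    si: np.ndarray, roi_map: ROIMap, channel_names: list[str]
) -> dict[tuple[str, str], float]:
    """Mean SI per (ROI, ROI) label, within- and between-region (10 labels)."""
    rois = roi_map.as_dict()
    idx = {
        name: [channel_names.index(c) for c in members if c in channel_names]
        for name, members in rois.items()
    }
    names = list(rois)
    out = {}
    si = np.asarray(si)
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b:
                block = si[np.ix_(idx[a], idx[a])]
            else:
                block = si[np.ix_(idx[a], idx[b])]
            vals = block[np.isfinite(block)]
            out[(a, b)] = float(vals.mean()) if vals.size else float("nan")
    return out


def connectivity_features(
    runs: list[SegmentedRun],
    band: str,
    adjacency: AdjacencyMap,
    channel_names: list[str],
    trim_s: float = 0.2,
) -> FeatureMatrix:
    """Observations x channels connectivity features for a cohort of runs."""
    rows, meta = [], []
    for run in runs:
        si_per_seg = pairwise_connectivity(
            run, band, adjacency, channel_names, trim_s=trim_s
        )
        for k in range(1, 7):
            rows.append(channel_connectivity_features(si_per_seg[f"load_{k}"]))
            meta.append(
                {
                    "participant": run.participant_id,
                    "modality": run.modality_tag,
                    "segment": k,
                }
            )
    return FeatureMatrix(
        values=np.array(rows),
        meta=pd.DataFrame(meta),
        family="connectivity",
        band=band,
        channel_names=list(channel_names),
    )
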