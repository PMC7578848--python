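"""Phase-of-power cross-frequency coupling (CFC).

For a modulating low band (theta 4-7 or alpha 8-13 Hz) and a modulated
high band (beta 14-30 or low gamma 31-45 Hz): the signal is narrow
band-pass filtered at a high-band center frequency, its power time
series p(t) = Re[z(t)]^2 + Im[z(t)]^2 is taken from the analytic signal
z(t), and that power series is band-pass filtered at the low-band
frequency before its Hilbert phase is extracted. The synchronization
index between this "phase of the power fluctuation" and the phase of
the raw signal filtered at the same low frequency quantifies how
strongly the low-frequency rhythm modulates high-frequency power.

Per channel and segment the SI is averaged over a grid of (low, high)
center-frequency combinations inside the labeled bands: high centers
15..45 Hz in 3-Hz steps with 3-Hz-wide filters, low centers 5..13 Hz in
2-Hz steps, also 3-Hz-wide. Step sizes are configurable; widths follow
the filtering recipe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import firls

from .bands import CFC_BANDS, CFC_PAIRS, BandTable
from .connectivity import _zero_phase_fir, phase_si
from .decoding import FeatureMatrix
from .segmentation import SegmentedRun, trim_edges


class CFCError(Exception):
    pass


def narrowband_filter(
    x: np.ndarray, f_lo: float, f_hi: float, fs: float, analytic: bool = False
) -> np.ndarray:
    """Zero-phase narrowband FIR with deliberately short kernels.

    Order is 3 cycles of the low cutoff with a 15% relative transition
    band (the classic EEGLAB eegfilt design). The resulting gentle
    roll-off is functional here, not a shortcut: amplitude modulation of
    a carrier at rate r puts sidebands at f_high ± r, outside a
    literal 3-Hz pass band, and a sharp filter would strip the very
    power fluctuation whose phase the coupling index measures. The
    short kernel attenuates but retains those sidebands.
    """
    nyq = fs / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise CFCError(f"band ({f_lo}, {f_hi}) Hz must lie inside (0, {nyq}) Hz")
    taps = int(3 * fs / f_lo)
    taps += (taps + 1) % 2
    trans = 0.15
    bands = [0, f_lo * (1 - trans), f_lo, f_hi, min(f_hi * (1 + trans), nyq * 0.999), nyq]
    b = firls(taps, bands, [0, 0, 1, 1, 0, 0], fs=fs)
    # normalize to unit gain at the band center so envelope power is
    # calibrated; pure scaling, leaves the response shape untouched
    f_c = 0.5 * (f_lo + f_hi)
    gain = np.abs(np.exp(-2j * np.pi * f_c / fs * np.arange(taps)) @ b)
    b = b / gain
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * taps:
        raise CFCError(
            f"series of {x.shape[-1]} samples too short for a {taps}-tap filter"
        )
    return _zero_phase_fir(x, b, analytic=analytic)


@dataclass(frozen=True)
class CFCGrid:
    """Center-frequency grids for the modulating and modulated ranges."""

    low_centers: tuple[float, ...] = (5.0, 7.0, 9.0, 11.0, 13.0)
    high_centers: tuple[float, ...] = (15.0, 18.0, 21.0, 24.0, 27.0, 30.0,
                                       33.0, 36.0, 39.0, 42.0, 45.0)
    low_width: float = 3.0
    high_width: float = 3.0

    def pair_centers(
        self, pair_label: str, band_table: BandTable = CFC_BANDS
    ) -> tuple[list[float], list[float]]:
        if pair_label not in CFC_PAIRS:
            raise CFCError(f"unknown CFC band pair {pair_label!r}")
        low_name, high_name = CFC_PAIRS[pair_label]
        low_band, high_band = band_table[low_name], band_table[high_name]
        lows = [f for f in self.low_centers if low_band.contains(f)]
        highs = [f for f in self.high_centers if high_band.contains(f)]
        if not lows or not highs:
            raise CFCError(f"no grid centers fall inside bands for {pair_label!r}")
        return lows, highs


def power_envelope(
    x: np.ndarray, f_center: float, fs: float, width: float = 3.0
) -> np.ndarray:
    """Power time series of the narrowband-filtered analytic signal."""
    lo, hi = f_center - width / 2.0, f_center + width / 2.0
    if not 0 < lo < hi < fs / 2.0:
        raise CFCError(f"band {lo}-{hi} Hz invalid at fs={fs}")
    z = narrowband_filter(x, lo, hi, fs, analytic=True)
    return z.real**2 + z.imag**2


def _low_phase(x: np.ndarray, f_low: float, fs: float, width: float) -> np.ndarray:
    return np.angle(
        narrowband_filter(
            x, f_low - width / 2.0, f_low + width / 2.0, fs, analytic=True
        )
    )


def _power_phase(
    x: np.ndarray, f_low: float, f_high: float, fs: float, grid: CFCGrid
) -> np.ndarray:
    p = power_envelope(x, f_high, fs, grid.high_width)
    p = p - p.mean(axis=-1, keepdims=True)
    return _low_phase(p, f_low, fs, grid.low_width)


def cfc_si(
    x: np.ndarray,
    f_low: float,
    f_high: float,
    fs: float,
    grid: CFCGrid = CFCGrid(),
) -> float:
    """SI between the low-frequency phase and the phase of the
    low-frequency fluctuation of the high-frequency power envelope."""
    if not f_low < f_high:
        raise CFCError("f_low must be below f_high")
    x = np.asarray(x, dtype=float)
    phi_l = _low_phase(x, f_low, fs, grid.low_width)
    phi_u = _power_phase(x, f_low, f_high, fs, grid)
    return phase_si(phi_l, phi_u)


def band_pair_cfc(
    run: SegmentedRun,
    pair_label: str,
    grid: CFCGrid = CFCGrid(),
    band_table: BandTable = CFC_BANDS,
    trim_s: float = 0.2,
) -> np.ndarray:
    """Per-segment, per-channel mean SI over the pair's frequency grid.

    Returns a load(6) x channel array. Filtering and phase extraction run
    on the continuous recording when available; segments are cut and
    trimmed afterwards.
    """
    lows, highs = grid.pair_centers(pair_label, band_table)
    if run.continuous is not None and run.spans is not None:
        data = run.continuous
        spans = [run.spans[f"load_{k}"] for k in range(1, 7)]
        segments = None
    else:
        data = None
        segments = run.load_segments

    n_ch = run.load_segments[0].shape[0]
    acc = np.zeros((6, n_ch))
    count = 0

    def _accumulate(phi_l, phi_u, k):
        pl = trim_edges(phi_l, run.fs, trim_s)
        pu = trim_edges(phi_u, run.fs, trim_s)
        r = np.abs(np.mean(np.exp(1j * (pu - pl)), axis=-1))
        acc[k] += r**2

    if data is not None:
        phi_l_full = {
            f_low: _low_phase(data, f_low, run.fs, grid.low_width) for f_low in lows
        }
        for f_high in highs:  # envelope depends on f_high only: compute once
            p = power_envelope(data, f_high, run.fs, grid.high_width)
            p -= p.mean(axis=-1, keepdims=True)
            for f_low in lows:
                phi_u_full = _low_phase(p, f_low, run.fs, grid.low_width)
                for k, (s, e) in enumerate(spans):
                    _accumulate(phi_l_full[f_low][:, s:e], phi_u_full[:, s:e], k)
                count += 1
    else:
        for k, seg in enumerate(run.load_segments):
            for f_high in highs:
                p = power_envelope(seg, f_high, run.fs, grid.high_width)
                p -= p.mean(axis=-1, keepdims=True)
                for f_low in lows:
                    phi_l = _low_phase(seg, f_low, run.fs, grid.low_width)
                    phi_u = _low_phase(p, f_low, run.fs, grid.low_width)
                    _accumulate(phi_l, phi_u, k)
        count = len(lows) * len(highs)
    return acc / count


def cfc_features(
    runs: list[SegmentedRun],
    pair_label: str,
    grid: CFCGrid = CFCGrid(),
    band_table: BandTable = CFC_BANDS,
    channel_names: list[str] | None = None,
    trim_s: float = 0.2,
) -> FeatureMatrix:
    """Observations x channels CFC features for one band pair."""
    rows, meta = [], []
    for run in runs:
        per_seg = band_pair_cfc(run, pair_label, grid, band_table, trim_s)
        for k in range(6):
            rows.append(per_seg[k])
            meta.append(
                {
                    "participant": run.participant_id,
                    "modality": run.modality_tag,
                    "segment": k + 1,
                }
            )
    return FeatureMatrix(
        values=np.array(rows),
        meta=pd.DataFrame(meta),
        family="cfc",
        band=pair_label,
        channel_names=list(channel_names or []),
    )
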