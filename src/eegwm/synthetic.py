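"""Synthetic EEG cohorts with the study design and plantable effects.

Each cohort has n participants, each recorded in a visual and an
audiovisual task: a 1-min pre-task baseline, six contiguous acquisition
segments whose duration is drawn uniformly from 21-37 s (the
working-memory staircase phases), and a 1-min post-task baseline.
Background activity is independent 1/f ("pink") noise plus white noise
per channel; no volume-conduction model is applied, so spatial
structure exists only where effects are planted into the ROI channel
lists.

Three effect families can be planted, each recovered by one feature
family downstream:

* modality-specific band-power offsets (dB) — a band-limited oscillator
  present in every channel whose task-segment amplitude is scaled by
  the per-modality offset relative to its baseline amplitude;
* load-dependent fronto-parietal phase coupling — frontal ROI channels
  share a band-limited reference whose parieto-occipital copies lag by
  a circular (von-Mises-shaped) phase offset with per-load-segment
  concentration;
* modality-dependent phase-of-power coupling — a low-frequency tone
  plus a high-frequency carrier whose amplitude is
  (1 + depth * cos(phase_low)) modulated, planted into ROI channels
  with per-modality depth.

Segment durations are drawn per participant and rounded to whole
seconds so every recording spans an integer number of seconds (exact
EDF data records).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.signal import hilbert

from .bands import CFC_PAIRS, POWER_BANDS
from .io import CHANNELS_64, RawRecording, default_roi_map


class ConfigError(ValueError):
    pass


#: Planting frequencies (low Hz, high Hz) per CFC pair label.
CFC_PLANT_FREQS = {
    "theta-beta": (6.0, 21.0),
    "theta-gamma": (6.0, 38.0),
    "alpha-beta": (10.0, 21.0),
    "alpha-gamma": (10.0, 38.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Design and planted-effect parameters of a synthetic cohort.

    Defaults follow the study design (18 participants, 21-37 s staircase
    segments, 60-s baselines) with effect magnitudes chosen so each
    feature family carries the signal the study reported: a theta power
    offset for modality, theta/alpha fronto-parietal coupling falling
    with load, and theta-beta phase-of-power coupling stronger in the
    audiovisual task.
    """

    n_participants: int = 18
    sampling_rate: float = 256.0
    segment_duration_range: tuple[float, float] = (21.0, 37.0)
    baseline_duration: float = 60.0
    #: band -> modality -> dB offset of task band power vs baseline
    modality_power_effect: dict = field(
        default_factory=lambda: {"theta": {"visual": 0.0, "audiovisual": 3.0}}
    )
    #: sd (dB) of slow per-segment amplitude fluctuations of the band
    #: oscillators, shared across channels — models vigilance/state drift
    #: so band-power classes overlap instead of separating perfectly
    power_effect_jitter_db: float = 1.0
    #: band -> six per-load-segment coupling concentrations
    load_coupling_effect: dict = field(
        default_factory=lambda: {
            "theta": (6.0, 4.0, 2.5, 1.5, 0.8, 0.3),
            "alpha": (5.0, 3.5, 2.2, 1.2, 0.6, 0.25),
        }
    )
    #: CFC pair label -> modality -> modulation depth in [0, 1]
    cfc_effect: dict = field(
        default_factory=lambda: {"theta-beta": {"visual": 0.15, "audiovisual": 0.7}}
    )
    noise_sd: float = 5.0  # white noise, µV
    pink_sd: float = 10.0  # 1/f noise, µV
    osc_amplitude: float = 10.0  # baseline sd of band-power oscillators, µV
    coupling_amplitude: float = 20.0  # sd of planted coupling components, µV
    cfc_low_amplitude: float = 8.0  # µV
    cfc_high_amplitude: float = 6.0  # µV
    edge_trim_s: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.sampling_rate < 128:
            raise ConfigError("sampling_rate must be >= 128 Hz")
        if self.sampling_rate != int(self.sampling_rate):
            raise ConfigError("sampling_rate must be an integer (EDF records)")
        lo, hi = self.segment_duration_range
        if not 0 < lo <= hi:
            raise ConfigError("segment_duration_range must satisfy 0 < lo <= hi")
        if round(lo) <= 2 * self.edge_trim_s:
            raise ConfigError("segment_duration_range too short for edge trimming")
        if self.baseline_duration <= 2 * self.edge_trim_s:
            raise ConfigError("baseline_duration too short for edge trimming")
        for band in self.modality_power_effect:
            POWER_BANDS[band]  # KeyError -> unknown band
        for band, kappas in self.load_coupling_effect.items():
            POWER_BANDS[band]
            if len(kappas) != 6:
                raise ConfigError(f"load_coupling_effect[{band!r}] needs 6 values")
            if any(k < 0 for k in kappas):
                raise ConfigError(f"load_coupling_effect[{band!r}] must be >= 0")
        for pair, depths in self.cfc_effect.items():
            if pair not in CFC_PAIRS:
                raise ConfigError(f"cfc_effect: unknown band pair {pair!r}")
            for m, d in depths.items():
                if not 0 <= d <= 1:
                    raise ConfigError(
                        f"cfc_effect[{pair!r}][{m!r}] depth must be in [0, 1]"
                    )
        for name in ("noise_sd", "pink_sd", "osc_amplitude", "coupling_amplitude",
                     "cfc_low_amplitude", "cfc_high_amplitude",
                     "power_effect_jitter_db"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted effect magnitudes per recording segment."""

    records: pd.DataFrame  # participant, modality, segment, effect, key, value

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# signal primitives


def pink_noise(n: int, rng: np.random.Generator, n_ch: int | None = None) -> np.ndarray:
    """Unit-variance noise with a 1/f amplitude spectrum (optionally multi-channel)."""
    m = next_fast_len(n)
    shape = (m,) if n_ch is None else (n_ch, m)
    spec = rfft(rng.standard_normal(shape), axis=-1)
    f = rfftfreq(m)
    f[0] = np.inf  # kill DC
    y = irfft(spec / np.sqrt(f), n=m, axis=-1)[..., :n]
    return y / y.std(axis=-1, keepdims=True)


def narrowband_noise(
    n: int,
    f_lo: float,
    f_hi: float,
    fs: float,
    rng: np.random.Generator,
    n_ch: int | None = None,
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (optionally multi-channel).

    Synthesized spectrally: complex Gaussian coefficients inside the band
    with half-cosine roll-offs, which is far cheaper than time-domain
    filtering for long multi-channel records.
    """
    m = next_fast_len(n)
    freqs = rfftfreq(m, 1.0 / fs)
    trans = min(1.0, f_lo / 2.0)
    gain = np.zeros_like(freqs)
    core = (freqs >= f_lo) & (freqs <= f_hi)
    gain[core] = 1.0
    lo_edge = (freqs >= f_lo - trans) & (freqs < f_lo)
    gain[lo_edge] = 0.5 * (1 + np.cos(np.pi * (f_lo - freqs[lo_edge]) / trans))
    hi_edge = (freqs > f_hi) & (freqs <= f_hi + trans)
    gain[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - f_hi) / trans))
    shape = (len(freqs),) if n_ch is None else (n_ch, len(freqs))
    spec = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * gain
    y = irfft(spec, n=m, axis=-1)[..., :n]
    return y / y.std(axis=-1, keepdims=True)


def _analytic(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    return hilbert(x, N=next_fast_len(n), axis=-1)[..., :n]


def lag_series(
    n: int, fs: float, concentration: float, rng: np.random.Generator,
    rate_hz: float = 2.0,
) -> np.ndarray:
    """Smooth circular phase-lag series with von-Mises-shaped dispersion.

    Lags are drawn at ``rate_hz`` and interpolated along the shortest
    circular path; concentration 0 gives independent uniform draws,
    infinity a constant zero lag.
    """
    m = max(int(np.ceil(n / fs * rate_hz)) + 2, 2)
    if np.isinf(concentration):
        draws = np.zeros(m)
    elif concentration == 0:
        draws = rng.uniform(-np.pi, np.pi, m)
    else:
        draws = rng.vonmises(0.0, min(concentration, 1e6), m)
    anchors = np.linspace(0, n - 1, m)
    return np.interp(np.arange(n), anchors, np.unwrap(draws))


def plant_phase_coupling(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    band: tuple[float, float],
    concentration: float,
    seed: int | np.random.Generator = 0,
    fs: float = 256.0,
    amplitude: float = 1.0,
    return_lags: bool = False,
):
    """Add band-limited components to two channels with coupled phases.

    The phase difference of the added components follows a circular
    unimodal distribution with the given concentration; concentration 0
    yields independent phases, infinity a constant lag.
    """
    ch_a = np.asarray(ch_a, dtype=float)
    ch_b = np.asarray(ch_b, dtype=float)
    if ch_a.shape != ch_b.shape:
        raise ConfigError("channel series must have equal length")
    if concentration < 0:
        raise ConfigError("concentration must be >= 0")
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi < fs / 2:
        raise ConfigError(f"band {band} must lie inside (0, Nyquist={fs / 2})")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = ch_a.shape[-1]
    z = _analytic(narrowband_noise(n, f_lo, f_hi, fs, rng))
    lags = lag_series(n, fs, concentration, rng)
    out_a = ch_a + amplitude * z.real
    out_b = ch_b + amplitude * np.real(z * np.exp(-1j * lags))
    if return_lags:
        return out_a, out_b, lags
    return out_a, out_b


def plant_cfc(
    x: np.ndarray,
    f_low: float,
    f_high: float,
    depth: float,
    seed: int | np.random.Generator = 0,
    fs: float = 256.0,
    a_low: float = 1.0,
    a_high: float = 1.0,
) -> np.ndarray:
    """Add a low-frequency tone plus a high-frequency carrier whose
    amplitude is (1 + depth*cos(phase_low))-modulated."""
    if not 0 <= depth <= 1:
        raise ConfigError("depth must be in [0, 1]")
    if not f_low < f_high < fs / 2:
        raise ConfigError("need f_low < f_high < Nyquist")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    t = np.arange(n) / fs
    ph0, ph1 = rng.uniform(0, 2 * np.pi, 2)
    phase_low = 2 * np.pi * f_low * t + ph0
    carrier = (1 + depth * np.cos(phase_low)) * np.cos(2 * np.pi * f_high * t + ph1)
    return x + a_low * np.cos(phase_low) + a_high * carrier


# ---------------------------------------------------------------------------
# cohort generation


def _segment_layout(cfg: CohortConfig, rng: np.random.Generator):
    """Integer-second durations and sample spans for one participant."""
    lo, hi = cfg.segment_duration_range
    durations = np.round(rng.uniform(lo, hi, 6)).astype(int)
    fs = int(cfg.sampling_rate)
    base = int(round(cfg.baseline_duration))
    labels = ["baseline_pre"] + [f"load_{k}" for k in range(1, 7)] + ["baseline_post"]
    secs = [base] + list(durations) + [base]
    onsets = np.concatenate([[0], np.cumsum(secs)[:-1]]) * fs
    total = int(sum(secs)) * fs
    spans = {
        lab: (int(on), int(on + d * fs)) for lab, on, d in zip(labels, onsets, secs)
    }
    return durations, spans, total


def _task_mask(spans: dict, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for k in range(1, 7):
        s, e = spans[f"load_{k}"]
        mask[s:e] = True
    return mask


def _generate_recording(
    cfg: CohortConfig,
    participant: str,
    modality: str,
    spans: dict,
    n_total: int,
    rng: np.random.Generator,
    truth_rows: list,
) -> RawRecording:
    fs = cfg.sampling_rate
    n_ch = len(CHANNELS_64)
    data = cfg.pink_sd * pink_noise(n_total, rng, n_ch=n_ch)
    data += cfg.noise_sd * rng.standard_normal((n_ch, n_total))

    task = _task_mask(spans, n_total)
    roi = default_roi_map()
    ch_index = {c: i for i, c in enumerate(CHANNELS_64)}

    # (a) modality-specific band-power offsets, with slow per-segment
    # amplitude jitter shared across channels
    for band, offsets in cfg.modality_power_effect.items():
        b = POWER_BANDS[band]
        db = float(offsets.get(modality, 0.0))
        env = np.ones(n_total)
        for label, (s, e) in spans.items():
            span_db = rng.normal(0.0, cfg.power_effect_jitter_db)
            if label.startswith("load_"):
                span_db += db
            env[s:e] = 10.0 ** (span_db / 20.0)
        nb = narrowband_noise(n_total, b.f_lo, b.f_hi, fs, rng, n_ch=n_ch)
        data += cfg.osc_amplitude * env * nb
        for k in range(1, 7):
            truth_rows.append(
                (participant, modality, k, "power_offset_db", band, db)
            )

    # (b) load-dependent fronto-parietal phase coupling
    frontal = sorted(roi.left_frontal | roi.right_frontal)
    parietal = sorted(roi.left_parieto_occipital | roi.right_parieto_occipital)
    for band, kappas in cfg.load_coupling_effect.items():
        b = POWER_BANDS[band]
        z = _analytic(narrowband_noise(n_total, b.f_lo, b.f_hi, fs, rng))
        for ch in frontal:
            data[ch_index[ch]] += cfg.coupling_amplitude * z.real
        for ch in parietal:
            lags = np.empty(n_total)
            for label, (s, e) in spans.items():
                if label.startswith("load_"):
                    kappa = float(kappas[int(label.split("_")[1]) - 1])
                else:
                    kappa = 0.0
                lags[s:e] = lag_series(e - s, fs, kappa, rng)
            data[ch_index[ch]] += cfg.coupling_amplitude * np.real(
                z * np.exp(-1j * lags)
            )
        for k in range(1, 7):
            truth_rows.append(
                (participant, modality, k, "coupling_kappa", band, float(kappas[k - 1]))
            )

    # (c) modality-dependent phase-of-power coupling
    t = np.arange(n_total) / fs
    for pair, depths in cfg.cfc_effect.items():
        depth = float(depths.get(modality, 0.0))
        f_low, f_high = CFC_PLANT_FREQS[pair]
        d_env = np.where(task, depth, 0.0)
        for ch in sorted(set(frontal) | set(parietal)):
            ph0, ph1 = rng.uniform(0, 2 * np.pi, 2)
            phase_low = 2 * np.pi * f_low * t + ph0
            data[ch_index[ch]] += cfg.cfc_low_amplitude * np.cos(phase_low)
            data[ch_index[ch]] += (
                cfg.cfc_high_amplitude
                * (1 + d_env * np.cos(phase_low))
                * np.cos(2 * np.pi * f_high * t + ph1)
            )
        for k in range(1, 7):
            truth_rows.append((participant, modality, k, "cfc_depth", pair, depth))

    events = [(s, label) for label, (s, _) in sorted(spans.items(), key=lambda kv: kv[1])]
    return RawRecording(
        data=data,
        fs=fs,
        channel_names=list(CHANNELS_64),
        events=events,
        modality_tag=modality,
        participant_id=participant,
    )


def iter_cohort(config: CohortConfig, truth_rows: list | None = None):
    """Yield (visual, audiovisual) recording pairs one participant at a time.

    Streaming counterpart of :func:`generate_cohort` for cohort-scale
    feature extraction without holding every recording in memory. If
    ``truth_rows`` is a list it accumulates the ground-truth records.
    """
    config.validate()
    sink: list = truth_rows if truth_rows is not None else []
    root = np.random.SeedSequence(config.seed)
    for p, p_seed in enumerate(root.spawn(config.n_participants), start=1):
        pid = f"P{p:02d}"
        layout_ss, vis_ss, av_ss = p_seed.spawn(3)
        _, spans, n_total = _segment_layout(config, np.random.default_rng(layout_ss))
        rec_v = _generate_recording(
            config, pid, "visual", spans, n_total,
            np.random.default_rng(vis_ss), sink,
        )
        rec_av = _generate_recording(
            config, pid, "audiovisual", spans, n_total,
            np.random.default_rng(av_ss), sink,
        )
        yield rec_v, rec_av


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[tuple[RawRecording, RawRecording]], GroundTruth]:
    """Generate (visual, audiovisual) recording pairs plus ground truth."""
    cfg = config or CohortConfig()
    truth_rows: list = []
    pairs = list(iter_cohort(cfg, truth_rows))
    truth = GroundTruth(
        pd.DataFrame(
            truth_rows,
            columns=["participant", "modality", "segment", "effect", "key", "value"],
        )
    )
    return pairs, truth


def null_config(**overrides) -> CohortConfig:
    """A cohort configuration with every planted effect switched off."""
    base = CohortConfig(
        modality_power_effect={}, load_coupling_effect={}, cfc_effect={}
    )
    return replace(base, **overrides)
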