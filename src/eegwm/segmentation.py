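"""High-pass filtering and cutting recordings into baselines + load segments.

A recording carries a 1-min pre-task baseline, six acquisition segments
(working-memory load 1..6, one per staircase phase), and a 1-min
post-task baseline, delimited by events. Spans are half-open
``[onset, next_onset)`` in 0-based samples.

Edge trimming (default 200 ms per side) is meant for phase-based
features, applied after filtering and the Hilbert transform; power
spectra use untrimmed segments. :class:`SegmentedRun` therefore keeps a
reference to the continuous data plus span indices so phase features can
be computed on the continuous series and sliced afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import EVENT_LABELS, RawRecording


class SegmentationError(Exception):
    pass


@dataclass
class SegmentedRun:
    """One task's baselines and six load segments (channels x samples each)."""

    baseline_pre: np.ndarray
    load_segments: list[np.ndarray]
    baseline_post: np.ndarray
    fs: float
    participant_id: str = "P00"
    modality_tag: str = "visual"
    # continuous source and the half-open sample span of each labeled part,
    # in EVENT_LABELS order; kept so phase features can avoid per-segment
    # filter transients.
    continuous: np.ndarray | None = field(default=None, repr=False)
    spans: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.load_segments) != 6:
            raise SegmentationError(
                f"expected exactly 6 load segments, got {len(self.load_segments)}"
            )

    def segment(self, label: str) -> np.ndarray:
        if label == "baseline_pre":
            return self.baseline_pre
        if label == "baseline_post":
            return self.baseline_post
        if label.startswith("load_"):
            return self.load_segments[int(label.split("_")[1]) - 1]
        raise KeyError(label)


def highpass(recording: RawRecording, cutoff: float = 0.5) -> RawRecording:
    """Zero-phase 4th-order Butterworth high-pass, removing drift and DC."""
    nyq = recording.fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    sos = butter(4, cutoff, btype="highpass", fs=recording.fs, output="sos")
    filtered = sosfiltfilt(sos, recording.data, axis=1)
    return RawRecording(
        data=filtered,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        events=list(recording.events),
        modality_tag=recording.modality_tag,
        participant_id=recording.participant_id,
    )


def segment_acquisition(recording: RawRecording) -> SegmentedRun:
    """Cut a recording at its event boundaries into baselines + 6 loads."""
    labels = [label for _, label in recording.events]
    missing = [l for l in EVENT_LABELS if l not in labels]
    duplicated = [l for l in set(labels) if labels.count(l) > 1]
    if missing or duplicated:
        raise SegmentationError(
            f"bad event set: missing={missing} duplicated={duplicated}"
        )
    onsets = dict(
        (label, onset) for onset, label in recording.events
    )
    ordered = sorted(recording.events)
    ends = {}
    for (onset, label), nxt in zip(ordered, ordered[1:] + [(recording.n_samples, "")]):
        ends[label] = nxt[0]
    spans = {l: (onsets[l], ends[l]) for l in EVENT_LABELS}
    cut = {l: recording.data[:, s:e] for l, (s, e) in spans.items()}
    return SegmentedRun(
        baseline_pre=cut["baseline_pre"],
        load_segments=[cut[f"load_{k}"] for k in range(1, 7)],
        baseline_post=cut["baseline_post"],
        fs=recording.fs,
        participant_id=recording.participant_id,
        modality_tag=recording.modality_tag,
        continuous=recording.data,
        spans=spans,
    )


def trim_samples(fs: float, trim_s: float = 0.2) -> int:
    return int(round(trim_s * fs))


def trim_edges(segment: np.ndarray, fs: float, trim_s: float = 0.2) -> np.ndarray:
    """Drop ``round(trim_s * fs)`` samples from each end of a segment."""
    segment = np.asarray(segment)
    t = trim_samples(fs, trim_s)
    n = segment.shape[-1]
    if n <= 2 * t:
        raise SegmentationError(
            f"segment of {n} samples too short to trim {t} per edge"
        )
    if t == 0:
        return segment
    return segment[..., t : n - t]
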