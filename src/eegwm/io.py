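"""EEG containers, montage geometry, ROI membership, and EDF round trip.

The montage is the standard 64-channel 10-10 layout (Biosemi-64 label
set). Channel adjacency — needed to exclude neighboring channel pairs
from connectivity — is derived from a Delaunay triangulation of the
2-D azimuthal-equidistant projection of the standard electrode
positions, a parameter-free notion of "neighbor".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .edf import read_id_fields, write_edf

#: Standard 64-channel 10-10 label set (Biosemi-64 layout).
CHANNELS_64: list[str] = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

#: Event labels every recording must carry, in temporal order.
EVENT_LABELS: list[str] = (
    ["baseline_pre"] + [f"load_{k}" for k in range(1, 7)] + ["baseline_post"]
)

MODALITIES = ("visual", "audiovisual")


class RecordingError(Exception):
    """Base class for recording I/O failures."""


class UnreadableFileError(RecordingError):
    pass


class MissingEventsError(RecordingError):
    pass


class UnknownChannelError(RecordingError):
    pass


@dataclass
class RawRecording:
    """A multi-channel EEG recording in microvolts.

    ``events`` is an ordered list of ``(onset_sample, label)``; each labeled
    span runs half-open from its onset to the next event's onset (the last
    one to the end of the recording). Sample indexing is 0-based.
    """

    data: np.ndarray  # channels x samples, µV
    fs: float
    channel_names: list[str]
    events: list[tuple[int, str]]
    modality_tag: str = "visual"
    participant_id: str = "P00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != len(set(self.channel_names)):
            raise ValueError("channel names must be unique")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for onset, label in self.events:
            if not 0 <= onset < self.n_samples:
                raise ValueError(f"event {label!r} onset {onset} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise UnknownChannelError(f"unknown channel {name!r}") from None


@dataclass(frozen=True)
class ROIMap:
    """Four scalp regions of interest used to summarize connectivity."""

    left_frontal: frozenset[str]
    right_frontal: frozenset[str]
    left_parieto_occipital: frozenset[str]
    right_parieto_occipital: frozenset[str]

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "left_frontal": self.left_frontal,
            "right_frontal": self.right_frontal,
            "left_parieto_occipital": self.left_parieto_occipital,
            "right_parieto_occipital": self.right_parieto_occipital,
        }

    def __post_init__(self) -> None:
        sets = list(self.as_dict().values())
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if a & b:
                    raise ValueError("ROI sets must be pairwise disjoint")


def default_roi_map() -> ROIMap:
    """The four ROI channel lists (11 + 10 + 9 + 9 channels)."""
    return ROIMap(
        left_frontal=frozenset(
            ["Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FC1", "FC3", "FC5", "FT7"]
        ),
        right_frontal=frozenset(
            ["Fp2", "F4", "F8", "FC2", "FC6", "F2", "AF4", "FC4", "F6", "AF8"]
        ),
        left_parieto_occipital=frozenset(
            ["P1", "P3", "P5", "P7", "CP3", "CP5", "PO3", "PO7", "O1"]
        ),
        right_parieto_occipital=frozenset(
            ["P2", "P4", "P6", "P8", "CP4", "CP6", "PO4", "PO8", "O2"]
        ),
    )


@lru_cache(maxsize=4)
def _standard_positions_cache(names: tuple[str, ...]) -> np.ndarray:
    import mne

    mne.set_log_level("ERROR")
    pos = mne.channels.make_standard_montage("standard_1005").get_positions()["ch_pos"]
    missing = [c for c in names if c not in pos]
    if missing:
        raise UnknownChannelError(f"no standard 10-10 position for {missing}")
    return np.array([pos[c] for c in names])


def standard_positions(channel_names: list[str]) -> np.ndarray:
    """3-D standard electrode positions (meters) for 10-10 labels."""
    return _standard_positions_cache(tuple(channel_names)).copy()


def project_2d(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of 3-D electrode positions."""
    x, y, z = np.asarray(positions, dtype=float).T
    r = np.sqrt(x**2 + y**2 + z**2)
    polar = np.arccos(np.clip(z / r, -1.0, 1.0))
    azimuth = np.arctan2(y, x)
    return np.column_stack([polar * np.cos(azimuth), polar * np.sin(azimuth)])


@dataclass(frozen=True)
class AdjacencyMap:
    """Symmetric, irreflexive channel-neighbor relation."""

    neighbors: dict[str, frozenset[str]]

    def are_neighbors(self, a: str, b: str) -> bool:
        return b in self.neighbors.get(a, frozenset())

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.neighbors.values()) // 2

    def pairs(self) -> set[tuple[str, str]]:
        out = set()
        for a, nbrs in self.neighbors.items():
            for b in nbrs:
                out.add(tuple(sorted((a, b))))
        return out


def build_adjacency(
    channel_names: list[str], positions: np.ndarray | None = None
) -> AdjacencyMap:
    """Delaunay adjacency on the 2-D projected montage."""
    from scipy.spatial import Delaunay

    if positions is None:
        positions = standard_positions(channel_names)
    xy = project_2d(positions)
    tri = Delaunay(xy)
    nbrs: dict[str, set[str]] = {c: set() for c in channel_names}
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            nbrs[channel_names[a]].add(channel_names[b])
            nbrs[channel_names[b]].add(channel_names[a])
    return AdjacencyMap({c: frozenset(s) for c, s in nbrs.items()})


# ---------------------------------------------------------------------------
# persistence


def write_events(path, events_s: list[tuple[float, float, str]]) -> None:
    """Write an event sidecar table (onset_s, duration_s, label)."""
    with open(path, "w") as fh:
        fh.write("onset_s\tduration_s\tlabel\n")
        for onset, duration, label in events_s:
            fh.write(f"{onset:.6f}\t{duration:.6f}\t{label}\n")


def read_events(path) -> list[tuple[float, float, str]]:
    path = Path(path)
    if not path.exists():
        raise MissingEventsError(f"event file not found: {path}")
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["onset_s", "duration_s", "label"]:
            raise MissingEventsError(f"malformed event file header in {path}")
        for line in fh:
            if not line.strip():
                continue
            onset, duration, label = line.rstrip("\n").split("\t")[:3]
            out.append((float(onset), float(duration), label))
    return out


def write_recording(recording: RawRecording, path, event_path) -> None:
    """Persist a recording as EDF plus a plain-text event sidecar."""
    write_edf(
        path,
        recording.data,
        recording.fs,
        recording.channel_names,
        patient_id=recording.participant_id,
        recording_id=f"modality={recording.modality_tag}",
    )
    onsets = [onset for onset, _ in recording.events] + [recording.n_samples]
    events_s = [
        (onsets[i] / recording.fs, (onsets[i + 1] - onsets[i]) / recording.fs, label)
        for i, (_, label) in enumerate(recording.events)
    ]
    write_events(event_path, events_s)


def read_recording(path, event_path) -> RawRecording:
    """Read an EDF/BDF recording and attach events from its sidecar."""
    import mne

    mne.set_log_level("ERROR")
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"file not found: {path}")
    try:
        if path.suffix.lower() == ".bdf":
            raw = mne.io.read_raw_bdf(path, preload=True, verbose="ERROR")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise UnreadableFileError(f"could not read {path}: {exc}") from exc

    data = raw.get_data() * 1e6  # mne returns volts for recognized EEG units
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)

    events_s = read_events(event_path)
    labels = [label for _, _, label in events_s]
    missing = [l for l in EVENT_LABELS if l not in labels]
    if missing:
        raise MissingEventsError(f"event file missing labels: {missing}")
    events = [(int(round(onset * fs)), label) for onset, _, label in events_s]

    patient, rec_id = read_id_fields(path)
    modality = rec_id.split("=", 1)[1] if "=" in rec_id else "visual"
    return RawRecording(
        data=data,
        fs=fs,
        channel_names=names,
        events=events,
        modality_tag=modality,
        participant_id=patient or "P00",
    )
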