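"""Frequency-band tables.

Two tables are shipped because the power/connectivity analyses and the
cross-frequency-coupling (CFC) analysis use slightly different alpha and
beta edges; both are kept verbatim rather than reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name!r}: f_lo must be < f_hi")

    def contains(self, f: float) -> bool:
        return self.f_lo <= f <= self.f_hi


class BandTable:
    """Ordered, non-overlapping collection of :class:`Band`."""

    def __init__(self, bands: list[Band]):
        srt = sorted(bands, key=lambda b: b.f_lo)
        for a, b in zip(srt, srt[1:]):
            if b.f_lo <= a.f_hi and a.name != b.name:
                raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")
        self.bands = list(bands)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]


#: Bands used for normalized power spectra and inter-site phase connectivity:
#: theta 4-7, alpha 8-12, beta 13-25, low gamma 26-45, high gamma 55-70 Hz.
POWER_BANDS = BandTable(
    [
        Band("theta", 4.0, 7.0),
        Band("alpha", 8.0, 12.0),
        Band("beta", 13.0, 25.0),
        Band("low_gamma", 26.0, 45.0),
        Band("high_gamma", 55.0, 70.0),
    ]
)

#: Bands used for cross-frequency coupling: theta and alpha modulate,
#: beta and low gamma are modulated. Alpha/beta edges differ from the
#: power table (8-13 and 14-30 Hz).
CFC_BANDS = BandTable(
    [
        Band("theta", 4.0, 7.0),
        Band("alpha", 8.0, 13.0),
        Band("beta", 14.0, 30.0),
        Band("low_gamma", 31.0, 45.0),
    ]
)

#: The four modulating-modulated combinations, as (label, low band, high band).
CFC_PAIRS: dict[str, tuple[str, str]] = {
    "theta-beta": ("theta", "beta"),
    "theta-gamma": ("theta", "low_gamma"),
    "alpha-beta": ("alpha", "beta"),
    "alpha-gamma": ("alpha", "low_gamma"),
}

#: Pass-band edges used when filtering for phase connectivity. Theta follows
#: the worked connectivity recipe (4-8 Hz) rather than the 4-7 Hz band-table
#: edge; the other bands use their printed edges.
CONNECTIVITY_FILTER_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 25.0),
    "low_gamma": (26.0, 45.0),
    "high_gamma": (55.0, 70.0),
}
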