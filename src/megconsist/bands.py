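"""Frequency band definitions.

The six classical bands used throughout resting-state MEG work: delta through
gamma, tiling 0.5--48 Hz. Band intervals are half-open ``[f_low, f_high)`` so
that touching edges (e.g. 4 Hz between delta and theta) are counted exactly
once and the six default bands partition the analyzed range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )

    def validate_for_fs(self, fs: float) -> None:
        """Raise if the band exceeds the Nyquist frequency for ``fs``."""
        if self.f_high > fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_high} Hz exceeds "
                f"Nyquist ({fs / 2} Hz at fs={fs} Hz)"
            )

    def contains(self, f: float) -> bool:
        return self.f_low <= f < self.f_high


#: The six classical frequency bands.
CLASSICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 48.0),
)

#: Total analyzed frequency range (Hz): the union of the classical bands.
TOTAL_RANGE: tuple[float, float] = (0.5, 48.0)


def band_by_name(name: str, bands: Sequence[BandDefinition] = CLASSICAL_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


def check_contiguous(bands: Iterable[BandDefinition]) -> None:
    """Validate that bands do not overlap (half-open intervals).

    Sorted by lower edge, no band may start before the previous one ends.
    Gaps are allowed (analyses may restrict to a band subset); overlap would
    double-count spectral content and raises ``ValueError``. The six default
    bands are exactly contiguous over 0.5--48 Hz.
    """
    ordered = sorted(bands, key=lambda b: b.f_low)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.f_low < prev.f_high:
            raise ValueError(
                f"bands {prev.name!r} and {nxt.name!r} overlap: "
                f"{nxt.f_low} < {prev.f_high}"
            )
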