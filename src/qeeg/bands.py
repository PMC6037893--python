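"""Frequency band definitions.

The six canonical resting-state bands partition 0.5-48 Hz: delta (0.5-4),
theta (4-8), alpha-1 (8-10), alpha-2 (10-13), beta (13-30) and gamma
(30-48 Hz). Bands are half-open intervals [lo, hi) so every frequency in
the analysis range belongs to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: lo must be < hi, got [{self.lo}, {self.hi})")

    def contains(self, freq: float) -> bool:
        return self.lo <= freq < self.hi

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


DELTA = Band("delta", 0.5, 4.0)
THETA = Band("theta", 4.0, 8.0)
ALPHA1 = Band("alpha1", 8.0, 10.0)
ALPHA2 = Band("alpha2", 10.0, 13.0)
BETA = Band("beta", 13.0, 30.0)
GAMMA = Band("gamma", 30.0, 48.0)

#: The six analysis bands, in ascending frequency order.
DEFAULT_BANDS: tuple[Band, ...] = (DELTA, THETA, ALPHA1, ALPHA2, BETA, GAMMA)

#: Broad alpha band used for phase-lag-index connectivity (union of alpha-1
#: and alpha-2, filtered as one band).
ALPHA_BAND = Band("alpha", 8.0, 13.0)

#: Broadband denominator for relative power.
BROADBAND = Band("broadband", 0.5, 48.0)


def band_for(freq: float, bands: tuple[Band, ...] = DEFAULT_BANDS) -> Band:
    """Return the unique band containing ``freq``.

    Raises ``ValueError`` if the frequency falls in no band (outside
    0.5-48 Hz for the defaults) or, with a pathological band set, in more
    than one.
    """
    hits = [b for b in bands if b.contains(freq)]
    if len(hits) != 1:
        raise ValueError(
            f"frequency {freq} Hz lies in {len(hits)} bands; expected exactly one"
        )
    return hits[0]


def validate_partition(bands: tuple[Band, ...] = DEFAULT_BANDS) -> None:
    """Check that the bands tile a contiguous range without overlap."""
    ordered = sorted(bands, key=lambda b: b.lo)
    for a, b in zip(ordered, ordered[1:]):
        if a.hi != b.lo:
            raise ValueError(f"bands {a.name!r} and {b.name!r} do not tile contiguously")
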