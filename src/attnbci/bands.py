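"""Frequency-band definitions shared by the generator and the feature extractor.

Seven contiguous, non-overlapping bands exactly tiling [1, 45) Hz:
delta [1,4), theta [4,8), alpha [8,12), low beta [12,18), high beta [18,25),
low gamma [25,35), high gamma [35,45).  Band membership is half-open
``[lo, hi)`` so the bands partition the total range and per-channel relative
powers sum to one by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Ordered band table: name -> (low edge, high edge) in Hz, half-open [lo, hi).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta_lo": (12.0, 18.0),
    "beta_hi": (18.0, 25.0),
    "gamma_lo": (25.0, 35.0),
    "gamma_hi": (35.0, 45.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BAND_EDGES)

#: Total range for relative-power normalization.
TOTAL_RANGE: tuple[float, float] = (1.0, 45.0)


@dataclass(frozen=True)
class BandDef:
    """The seven named analysis bands and the total normalization range."""

    edges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES)
    )
    total_range: tuple[float, float] = TOTAL_RANGE

    def __post_init__(self) -> None:
        lows = [lo for lo, _ in self.edges.values()]
        highs = [hi for _, hi in self.edges.values()]
        if any(hi <= lo for lo, hi in self.edges.values()):
            raise ValueError("each band must satisfy low < high")
        # bands must be contiguous and exactly tile total_range
        if lows[0] != self.total_range[0] or highs[-1] != self.total_range[1]:
            raise ValueError("bands must span the total range exactly")
        for hi_prev, lo_next in zip(highs[:-1], lows[1:]):
            if hi_prev != lo_next:
                raise ValueError("bands must be contiguous and non-overlapping")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.edges)

    @property
    def n_bands(self) -> int:
        return len(self.edges)


def default_bands() -> BandDef:
    return BandDef()
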