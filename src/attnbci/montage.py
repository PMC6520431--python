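"""Electrode montage for the 16-channel 10-20 recording layout.

The analysis assumes a fixed set of 16 scalp positions covering frontal,
central, centro-parietal, parietal and occipital regions.  Positions are
unit-free 2-D scalp coordinates (x: left-negative, y: anterior-positive)
used only for topographic reports, never for source modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order used everywhere in the package.
CHANNEL_NAMES: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "C3", "C4",
    "CP5", "CP1", "CP2", "CP6", "P3", "P4", "O1", "O2",
)

#: Approximate 2-D scalp coordinates on the unit disc (10-20 projection).
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.55), "F4": (0.40, 0.55), "F8": (0.81, 0.59),
    "C3": (-0.50, 0.00), "C4": (0.50, 0.00),
    "CP5": (-0.73, -0.29), "CP1": (-0.25, -0.28), "CP2": (0.25, -0.28), "CP6": (0.73, -0.29),
    "P3": (-0.40, -0.55), "P4": (0.40, -0.55),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

#: Frontal-polar channels used by the blink-detection criteria.
FRONTAL_CHANNELS: tuple[str, str] = ("Fp1", "Fp2")


@dataclass(frozen=True)
class Montage:
    """Ordered set of 16 channel labels with 2-D scalp coordinates."""

    channel_names: tuple[str, ...] = CHANNEL_NAMES
    positions: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(_POSITIONS[c] for c in CHANNEL_NAMES)
    )

    def __post_init__(self) -> None:
        if len(self.channel_names) != 16:
            raise ValueError(
                f"montage must have exactly 16 channels, got {len(self.channel_names)}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if set(self.channel_names) != set(CHANNEL_NAMES):
            raise ValueError(
                "channel names must be the 10-20 set "
                f"{sorted(CHANNEL_NAMES)}, got {sorted(self.channel_names)}"
            )
        if len(self.positions) != len(self.channel_names):
            raise ValueError("one 2-D position required per channel")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        """Row index of channel ``name`` in the sample matrix."""
        return self.channel_names.index(name)

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)


def default_montage() -> Montage:
    """The standard 16-channel montage in canonical order."""
    return Montage()
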