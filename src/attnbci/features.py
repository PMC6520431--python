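"""Epoching and band-power feature extraction.

Each cleaned recording is cut into non-overlapping epochs of 1, 3, 5, 10 or
30 s aligned to round starts, and each epoch is summarized by 224 features:
16 channels x 7 frequency bands x {absolute, relative} power.  Absolute
power is the sum of Hann-windowed one-sided periodogram bins whose centre
frequency falls in the half-open band [lo, hi); relative power divides by
the total over [1, 45) Hz.  Because the seven bands exactly tile [1, 45),
the seven relative powers of a channel sum to one.

Column order is channel-major: for each channel the 7 absolute powers in
band order, then the 7 relative powers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandDef, default_bands
from .montage import Montage
from .synth import Recording

EPOCH_LENGTHS_S: tuple[int, ...] = (1, 3, 5, 10, 30)


@dataclass
class Epoch:
    samples: np.ndarray      # channels x time, uV
    fs: float
    length_s: float
    label: str
    subject_id: str
    round_index: int


def make_epochs(rec: Recording, length_s: float) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping labeled epochs.

    Epochs start at each round start; the remainder of a round shorter than
    ``length_s`` is discarded, so every epoch lies fully inside one round.
    """
    if length_s not in EPOCH_LENGTHS_S:
        raise ValueError(
            f"epoch length {length_s} s unsupported; choose from {EPOCH_LENGTHS_S}"
        )
    n_per = round(length_s * rec.fs)
    epochs = []
    for ri, r in enumerate(rec.rounds):
        i0 = round(r.start_s * rec.fs)
        i_end = round(r.end_s * rec.fs)
        k = 0
        while i0 + (k + 1) * n_per <= i_end:
            seg = rec.samples[:, i0 + k * n_per : i0 + (k + 1) * n_per]
            epochs.append(Epoch(seg, rec.fs, length_s, r.label, rec.subject_id, ri))
            k += 1
    return epochs


def band_power(epoch: Epoch, bands: BandDef | None = None) -> np.ndarray:
    """Per-channel 14-vector: 7 absolute band powers then 7 relative.

    Hann-windowed one-sided periodogram; bin membership by bin centre
    frequency, half-open [lo, hi).  Channels whose total power over the
    normalization range is zero get NaN relative powers (flagged upstream).

    Returns an array of shape (n_channels, 14).
    """
    bands = bands or default_bands()
    x = np.asarray(epoch.samples, dtype=np.float64)
    n = x.shape[1]
    if n < epoch.fs:  # need at least 1 s to resolve the 1 Hz lower edge
        raise ValueError("epoch too short to resolve the 1 Hz band edge")
    win = np.hanning(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch.fs)
    spec = np.abs(np.fft.rfft(x * win, axis=1)) ** 2
    # one-sided power, normalized by the window's sum of squares
    spec *= 2.0 / (win @ win)
    spec[:, 0] /= 2.0
    if n % 2 == 0:
        spec[:, -1] /= 2.0

    lo_t, hi_t = bands.total_range
    total = spec[:, (freqs >= lo_t) & (freqs < hi_t)].sum(axis=1)

    out = np.empty((x.shape[0], 2 * bands.n_bands))
    for bi, (lo, hi) in enumerate(bands.edges.values()):
        p_abs = spec[:, (freqs >= lo) & (freqs < hi)].sum(axis=1)
        out[:, bi] = p_abs
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, bands.n_bands + bi] = np.where(total > 0, p_abs / total, np.nan)
    return out


def feature_names(montage: Montage, bands: BandDef | None = None) -> list[str]:
    """Deterministic 224 column names: ``<channel>_<band>_<abs|rel>``."""
    bands = bands or default_bands()
    names = []
    for ch in montage.channel_names:
        names += [f"{ch}_{b}_abs" for b in bands.names]
        names += [f"{ch}_{b}_rel" for b in bands.names]
    return names


@dataclass
class FeatureMatrix:
    """Per-epoch band-power table with labels and subject identifiers."""

    values: np.ndarray                 # epochs x 224
    feature_names: list[str]
    labels: np.ndarray                 # condition per epoch
    subject_ids: np.ndarray
    epoch_length_s: float
    bands: BandDef = field(default_factory=default_bands)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature name count must match column count")
        if not (len(self.labels) == len(self.subject_ids) == self.values.shape[0]):
            raise ValueError("labels/subject_ids must match row count")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, epoch_length_s: float = float("nan")) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            df[names].to_numpy(float),
            names,
            df["label"].to_numpy(),
            df["subject_id"].to_numpy(),
            epoch_length_s,
        )

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[mask],
            self.feature_names,
            self.labels[mask],
            self.subject_ids[mask],
            self.epoch_length_s,
            self.bands,
        )


def build_feature_matrix(
    epochs: list[Epoch], bands: BandDef | None = None, montage: Montage | None = None
) -> FeatureMatrix:
    """Extract the 224-column feature matrix from a list of epochs.

    Epochs with zero total power on any channel are excluded with a warning.
    All epochs must share the same length and montage geometry.
    """
    if not epochs:
        raise ValueError("no epochs given")
    bands = bands or default_bands()
    lengths = {e.length_s for e in epochs}
    if len(lengths) > 1:
        raise ValueError(f"epochs mix lengths {sorted(lengths)}")
    n_ch = {e.samples.shape[0] for e in epochs}
    if len(n_ch) > 1:
        raise ValueError("epochs mix channel counts (montage mismatch)")

    rows, labels, subjects = [], [], []
    n_dropped = 0
    for e in epochs:
        bp = band_power(e, bands)
        if np.isnan(bp).any():
            n_dropped += 1
            continue
        rows.append(bp.ravel())  # channel-major: per channel 7 abs then 7 rel
        labels.append(e.label)
        subjects.append(e.subject_id)
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} degenerate epoch(s) with zero total power",
            RuntimeWarning,
            stacklevel=2,
        )
    if not rows:
        raise ValueError("all epochs were degenerate")

    if montage is None:
        from .montage import default_montage

        montage = default_montage()
    return FeatureMatrix(
        np.vstack(rows),
        feature_names(montage, bands),
        np.array(labels),
        np.array(subjects),
        epochs[0].length_s,
        bands,
    )
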