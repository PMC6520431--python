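"""Synthetic multi-subject EEG cohorts with planted task-difficulty effects.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of subjects each playing cycles of 30 s rounds at three
difficulty levels in fixed easy-medium-hard order, recorded on the
16-channel montage.  Each channel is the sum of

* a 1/f^alpha Gaussian background, and
* seven band-limited noise oscillators (white noise band-passed into each
  analysis band) whose variance is the product of a per-band base power, a
  per-condition multiplicative gain for that channel/band, and a per-subject
  log-normal gain.

Condition effects are planted as multiplicative band-power gains, mirroring
the spectral correlates of attentional load the analysis is designed to
find: prefrontal theta and broad gamma power increasing with difficulty,
fronto-central high-beta increasing, and fronto-central alpha decreasing.
Eye blinks are injected separately as stereotyped frontal transients at a
condition-dependent Poisson rate (attentive subjects blink less), so the
blink-removal stage can be tested against ground truth.

All randomness is driven by explicit integer seeds; equal seeds reproduce
cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .bands import BAND_EDGES, BAND_NAMES
from .montage import Montage, default_montage

CONDITIONS: tuple[str, ...] = ("easy", "medium", "hard")

ROUND_DURATION_S: float = 30.0
DEFAULT_FS: float = 500.0
DEFAULT_N_CYCLES: int = 20
DEFAULT_N_SUBJECTS: int = 14


@dataclass(frozen=True)
class Round:
    """One annotated task round."""

    start_s: float
    end_s: float
    label: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """Continuous multi-channel recording with per-round difficulty labels.

    ``samples`` is channels x time in microvolts, rows ordered as
    ``montage.channel_names``.
    """

    samples: np.ndarray
    fs: float
    montage: Montage
    rounds: list[Round]
    subject_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"{self.samples.shape[0]} rows for a "
                f"{self.montage.n_channels}-channel montage"
            )
        dur = self.duration_s
        prev_end = 0.0
        for r in sorted(self.rounds, key=lambda r: r.start_s):
            if r.label not in CONDITIONS:
                raise ValueError(f"unknown round label {r.label!r}")
            if r.start_s < prev_end - 1e-9 or r.end_s > dur + 1e-9:
                raise ValueError("rounds must be non-overlapping and inside the signal")
            prev_end = r.end_s

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.samples.copy(), self.fs, self.montage, list(self.rounds), self.subject_id
        )


@dataclass(frozen=True)
class BandEffect:
    """Multiplicative band-power gain per condition on a channel group."""

    channels: tuple[str, ...]
    band: str
    gains: dict[str, float]  # condition -> gain, easy/medium/hard

    def validate(self) -> None:
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")
        for cond in CONDITIONS:
            g = self.gains.get(cond, 1.0)
            if not g > 0:
                raise ValueError(
                    f"effect on band {self.band!r} channels {self.channels} has "
                    f"non-positive gain {g} for condition {cond!r}"
                )


@dataclass
class EffectSpec:
    """Full specification of the planted cohort structure.

    Parameters
    ----------
    band_base_power : per-band oscillator variance in the easy condition (uV^2).
    effects : list of per-(channel-group, band) condition gains.
    blink_rate : blinks per minute per condition; must be non-increasing
        with difficulty (attentive subjects blink less).
    blink_amplitude : peak blink deflection at the frontal poles (uV).
    subject_gain_sd : sigma of the log-normal per-subject, per-channel-band gain.
    background_exponent : spectral slope alpha of the 1/f^alpha background.
    background_rms : background standard deviation per channel (uV).
    """

    band_base_power: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 10.0,
            "theta": 6.0,
            "alpha": 8.0,
            "beta_lo": 3.0,
            "beta_hi": 2.0,
            "gamma_lo": 1.0,
            "gamma_hi": 0.6,
        }
    )
    effects: list[BandEffect] = field(default_factory=list)
    blink_rate: dict[str, float] = field(
        default_factory=lambda: {"easy": 18.0, "medium": 14.0, "hard": 10.0}
    )
    blink_amplitude: float = 120.0
    subject_gain_sd: float = 0.25
    background_exponent: float = 1.0
    background_rms: float = 5.0

    def validate(self) -> None:
        for band, p in self.band_base_power.items():
            if band not in BAND_NAMES:
                raise ValueError(f"unknown band {band!r} in base powers")
            if not p > 0:
                raise ValueError(f"base power for band {band!r} must be > 0, got {p}")
        for eff in self.effects:
            eff.validate()
        r = [self.blink_rate.get(c, 0.0) for c in CONDITIONS]
        if any(v < 0 for v in r):
            raise ValueError("blink rates must be >= 0")
        if not (r[0] >= r[1] >= r[2]):
            raise ValueError(
                "blink rate must be non-increasing with difficulty "
                f"(easy >= medium >= hard), got {r}"
            )

    def gain_table(self, montage: Montage) -> np.ndarray:
        """Condition gains as a (n_conditions, n_channels, n_bands) array.

        Multiple effects hitting the same (channel, band) multiply.
        """
        self.validate()
        g = np.ones((len(CONDITIONS), montage.n_channels, len(BAND_NAMES)))
        for eff in self.effects:
            bi = BAND_NAMES.index(eff.band)
            for ch in eff.channels:
                ci = montage.index(ch)
                for k, cond in enumerate(CONDITIONS):
                    g[k, ci, bi] *= eff.gains.get(cond, 1.0)
        return g


def default_effects() -> EffectSpec:
    """Planted correlates of attentional load used throughout the tests.

    Theta rises with difficulty at the prefrontal/frontal sites, gamma rises
    broadly over the whole scalp, high beta rises at the central sites, and
    alpha drops fronto-centrally.  Magnitudes are generator choices; the
    study this emulates reports only the direction of each correlate.
    """
    prefrontal = ("Fp1", "Fp2", "F3", "F4")
    central = ("C3", "C4")
    fronto_central = ("C3", "C4", "CP1", "CP2")
    all_ch = tuple(default_montage().channel_names)
    return EffectSpec(
        effects=[
            BandEffect(prefrontal, "theta", {"easy": 1.0, "medium": 1.3, "hard": 1.6}),
            BandEffect(all_ch, "gamma_lo", {"easy": 1.0, "medium": 1.15, "hard": 1.3}),
            BandEffect(all_ch, "gamma_hi", {"easy": 1.0, "medium": 1.15, "hard": 1.3}),
            BandEffect(central, "beta_hi", {"easy": 1.0, "medium": 1.2, "hard": 1.4}),
            BandEffect(fronto_central, "alpha", {"easy": 1.0, "medium": 0.85, "hard": 0.7}),
        ]
    )


def null_effects() -> EffectSpec:
    """No condition effects and no blinks: every band identical across conditions."""
    return EffectSpec(effects=[], blink_rate={"easy": 0.0, "medium": 0.0, "hard": 0.0})


def make_rounds(n_cycles: int) -> list[Round]:
    """3 * n_cycles contiguous 30 s rounds cycling easy -> medium -> hard."""
    rounds = []
    t = 0.0
    for _ in range(n_cycles):
        for cond in CONDITIONS:
            rounds.append(Round(t, t + ROUND_DURATION_S, cond))
            t += ROUND_DURATION_S
    return rounds


def _one_over_f_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # flatten the shaping below 0.1 Hz so the slope does not inject huge drifts
    f = np.maximum(freqs, 0.1)
    shape = f ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * shape
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(n: int, fs: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise in [lo, hi] Hz."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def draw_subject_gains(
    effects: EffectSpec, montage: Montage, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject log-normal multiplicative gains, (n_channels, n_bands)."""
    sd = effects.subject_gain_sd
    return np.exp(rng.normal(0.0, sd, size=(montage.n_channels, len(BAND_NAMES))))


def generate_subject(
    effects: EffectSpec,
    montage: Montage | None = None,
    fs: float = DEFAULT_FS,
    n_cycles: int = DEFAULT_N_CYCLES,
    seed: int = 0,
    subject_id: str = "S01",
    subject_gains: np.ndarray | None = None,
) -> Recording:
    """Generate one subject's continuous recording (without blinks).

    Returns a Recording of ``3 * n_cycles`` rounds of 30 s each, cycling
    easy-medium-hard.  Identical arguments reproduce the output bit for bit.
    """
    if fs < 200:
        raise ValueError(f"fs must be >= 200 Hz to cover the 45 Hz band, got {fs}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    montage = montage or default_montage()
    effects.validate()

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    if subject_gains is None:
        subject_gains = draw_subject_gains(effects, montage, rng)

    rounds = make_rounds(n_cycles)
    n = round(3 * n_cycles * ROUND_DURATION_S * fs)
    gains = effects.gain_table(montage)  # (cond, ch, band)

    # per-sample condition index
    cond_idx = np.empty(n, dtype=int)
    for r in rounds:
        i0, i1 = round(r.start_s * fs), round(r.end_s * fs)
        cond_idx[i0:i1] = CONDITIONS.index(r.label)

    samples = np.empty((montage.n_channels, n))
    for ci in range(montage.n_channels):
        x = effects.background_rms * _one_over_f_noise(
            n, fs, effects.background_exponent, rng
        )
        for bi, band in enumerate(BAND_NAMES):
            lo, hi = BAND_EDGES[band]
            osc = _band_noise(n, fs, lo, hi, rng)
            var = (
                effects.band_base_power[band]
                * subject_gains[ci, bi]
                * gains[cond_idx, ci, bi]
            )
            x += np.sqrt(var) * osc
        samples[ci] = x

    return Recording(samples, fs, montage, rounds, subject_id)


@dataclass
class BlinkTruth:
    """Ground truth for injected blinks: oracle for the removal stage."""

    onsets_s: np.ndarray            # blink onset times
    mixing: np.ndarray              # (n_channels,) spatial pattern, unit peak
    template: np.ndarray            # the injected time course (uV at peak channel)
    clean: Recording                # the recording before injection


#: Frontal-dominant blink scalp pattern (relative deflection per channel).
BLINK_MIXING: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0,
    "F7": 0.12, "F3": 0.15, "F4": 0.15, "F8": 0.12,
    "C3": 0.04, "C4": 0.04,
    "CP5": 0.02, "CP1": 0.02, "CP2": 0.02, "CP6": 0.02,
    "P3": 0.02, "P4": 0.02, "O1": 0.02, "O2": 0.02,
}

BLINK_DURATION_S: float = 0.3


def blink_template(fs: float, duration_s: float = BLINK_DURATION_S) -> np.ndarray:
    """Smooth unipolar bump (squared Hann), unit peak amplitude."""
    n = max(3, round(duration_s * fs))
    return np.hanning(n) ** 2


def inject_blinks(
    rec: Recording, effects: EffectSpec, seed: int = 0
) -> tuple[Recording, BlinkTruth]:
    """Add stereotyped blink transients at condition-dependent Poisson rates.

    Blinks are projected through a fixed frontal-dominant mixing vector
    (largest loadings on Fp1/Fp2).  Returns the blink-laden recording and the
    ground truth (onsets, mixing vector, template, clean copy).
    """
    effects.validate()
    tmpl = effects.blink_amplitude * blink_template(rec.fs)
    if len(tmpl) / rec.fs >= min(r.duration_s for r in rec.rounds):
        raise ValueError("blink template must be shorter than the shortest round")
    mixing = np.array([BLINK_MIXING[c] for c in rec.montage.channel_names])

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB11_7C]))
    out = rec.copy()
    onsets: list[float] = []
    for r in rec.rounds:
        rate_hz = effects.blink_rate.get(r.label, 0.0) / 60.0
        if rate_hz <= 0:
            continue
        count = rng.poisson(rate_hz * r.duration_s)
        starts = rng.uniform(r.start_s, r.end_s - len(tmpl) / rec.fs, size=count)
        for t0 in np.sort(starts):
            i0 = round(t0 * rec.fs)
            out.samples[:, i0 : i0 + len(tmpl)] += np.outer(mixing, tmpl)
            onsets.append(t0)

    truth = BlinkTruth(np.array(onsets), mixing, tmpl, rec.copy())
    return out, truth


def generate_cohort(
    effects: EffectSpec,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    n_cycles: int = DEFAULT_N_CYCLES,
    montage: Montage | None = None,
) -> list[Recording]:
    """Generate a cohort of independent subjects (blinks not yet injected).

    Per-subject seeds are derived deterministically from the master seed;
    per-subject gains are drawn once per subject.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs >= 2 subjects (leave-one-subject-out)")
    montage = montage or default_montage()
    master = np.random.SeedSequence(int(seed))
    children = master.spawn(n_subjects)
    recs = []
    for k, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        recs.append(
            generate_subject(
                effects,
                montage=montage,
                fs=fs,
                n_cycles=n_cycles,
                seed=sub_seed,
                subject_id=f"S{k + 1:02d}",
            )
        )
    return recs
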