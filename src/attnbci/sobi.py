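"""Second-Order Blind Identification (SOBI) and automatic blink removal.

SOBI separates sources with distinct autocorrelation structure by (1)
whitening the channels, (2) computing symmetrized time-lagged covariance
matrices of the whitened data at a set of lags, and (3) approximately
jointly diagonalizing them with iterated Jacobi (Givens) rotations.  Eye
blinks form a source with a stereotyped frontal-dominant scalp pattern and
slow (< 5 Hz) dynamics, so flagged components are those whose mixing column
concentrates on Fp1/Fp2 and whose source power is predominantly low
frequency.  Removal zeroes the flagged sources and remixes.

The component-rejection criteria are automated (thresholds configurable)
so the whole pipeline is reproducible without manual component inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .montage import FRONTAL_CHANNELS, Montage
from .synth import Recording

DEFAULT_LAGS: tuple[int, ...] = tuple(range(1, 51))


@dataclass
class SobiModel:
    mixing: np.ndarray      # channels x components
    unmixing: np.ndarray    # components x channels
    sources: np.ndarray     # components x time
    lags: tuple[int, ...]
    mean: np.ndarray        # per-channel mean removed before decomposition
    fs: float
    converged: bool

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]


def _joint_diagonalize(
    matrices: np.ndarray, tol: float = 1e-8, max_sweeps: int = 200
) -> tuple[np.ndarray, bool]:
    """Orthogonal approximate joint diagonalizer of symmetric matrices.

    Jacobi scheme: for each pair (p, q) the Givens angle maximizing the
    summed squared diagonals is the principal axis of a 2x2 quadratic form
    accumulated over all matrices.  Sweeps repeat until every rotation sine
    in a sweep falls below ``tol``.

    Returns (V, converged) with ``V.T @ M @ V`` approximately diagonal.
    """
    k, m, _ = matrices.shape
    V = np.eye(m)
    A = matrices.copy()
    for _ in range(max_sweeps):
        max_sin = 0.0
        for p in range(m - 1):
            for q in range(p + 1, m):
                # 2x2 form from Cardoso-Souloumiac for symmetric matrices
                h1 = A[:, p, p] - A[:, q, q]
                h2 = A[:, p, q] + A[:, q, p]
                g11 = h1 @ h1
                g12 = h1 @ h2
                g22 = h2 @ h2
                theta = 0.5 * np.arctan2(2.0 * g12, g11 - g22)
                c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
                if abs(s) <= tol:
                    continue
                max_sin = max(max_sin, abs(s))
                G = np.array([[c, -s], [s, c]])
                A[:, :, [p, q]] = A[:, :, [p, q]] @ G
                A[:, [p, q], :] = np.einsum("ji,kjl->kil", G, A[:, [p, q], :])
                V[:, [p, q]] = V[:, [p, q]] @ G
        if max_sin <= tol:
            return V, True
    return V, False


def sobi_decompose(
    rec: Recording,
    lags: tuple[int, ...] = DEFAULT_LAGS,
    tol: float = 1e-8,
    max_sweeps: int = 200,
    rank_tol: float = 1e-10,
) -> SobiModel:
    """Decompose a recording into SOBI components.

    Rank-deficient channel covariance reduces the component count with a
    warning; non-convergence of the Jacobi sweeps is flagged on the model.
    """
    X = np.asarray(rec.samples, dtype=np.float64)
    n_ch, n_t = X.shape
    if n_ch < 2:
        raise ValueError("SOBI needs at least 2 channels")
    if n_t <= 4 * max(lags):
        raise ValueError("recording too short for the requested lags")

    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean

    # whitening via eigendecomposition of the zero-lag covariance
    C0 = (Xc @ Xc.T) / n_t
    evals, evecs = np.linalg.eigh(C0)
    keep = evals > rank_tol * evals.max()
    if keep.sum() < n_ch:
        warnings.warn(
            f"rank-deficient covariance: keeping {int(keep.sum())} of {n_ch} components",
            RuntimeWarning,
            stacklevel=2,
        )
    evals, evecs = evals[keep], evecs[:, keep]
    whitener = (evecs / np.sqrt(evals)).T      # comps x channels
    dewhitener = evecs * np.sqrt(evals)        # channels x comps
    Z = whitener @ Xc

    R = np.empty((len(lags), Z.shape[0], Z.shape[0]))
    for i, lag in enumerate(lags):
        r = (Z[:, :-lag] @ Z[:, lag:].T) / (n_t - lag)
        R[i] = 0.5 * (r + r.T)

    V, converged = _joint_diagonalize(R, tol=tol, max_sweeps=max_sweeps)
    unmixing = V.T @ whitener
    mixing = dewhitener @ V
    sources = unmixing @ Xc
    return SobiModel(mixing, unmixing, sources, tuple(lags), mean, rec.fs, converged)


@dataclass(frozen=True)
class BlinkCriteria:
    """Thresholds for automatic blink-component flagging."""

    frontal_fraction_min: float = 0.60   # L1 mass of the mixing column on Fp1/Fp2
    lowfreq_fraction_min: float = 0.70   # source power fraction below 5 Hz

    def __post_init__(self) -> None:
        for v in (self.frontal_fraction_min, self.lowfreq_fraction_min):
            if not (0 < v <= 1):
                raise ValueError("criteria fractions must lie in (0, 1]")


def identify_blink_components(
    model: SobiModel, montage: Montage, crit: BlinkCriteria | None = None
) -> list[int]:
    """Indices of components matching the frontal, low-frequency blink signature."""
    crit = crit or BlinkCriteria()
    frontal_idx = montage.indices(FRONTAL_CHANNELS)
    flagged = []
    freqs = np.fft.rfftfreq(model.sources.shape[1], d=1.0 / model.fs)
    low = freqs < 5.0
    for j in range(model.n_components):
        col = np.abs(model.mixing[:, j])
        l1 = col.sum()
        if l1 <= 0:
            continue
        frontal_frac = col[frontal_idx].sum() / l1
        if frontal_frac < crit.frontal_fraction_min:
            continue
        psd = np.abs(np.fft.rfft(model.sources[j])) ** 2
        total = psd.sum()
        if total <= 0:
            continue
        if psd[low].sum() / total >= crit.lowfreq_fraction_min:
            flagged.append(j)
    return flagged


def reconstruct_without(
    rec: Recording, model: SobiModel, removed: list[int] | tuple[int, ...]
) -> Recording:
    """Remix the recording with the given components zeroed out."""
    removed = list(removed)
    for j in removed:
        if not (0 <= j < model.n_components):
            raise IndexError(f"component index {j} out of range")
    sources = model.sources.copy()
    if removed:
        sources[removed, :] = 0.0
    out = rec.copy()
    out.samples = model.mixing @ sources + model.mean
    return out


def remove_blinks(
    rec: Recording,
    montage: Montage | None = None,
    crit: BlinkCriteria | None = None,
    lags: tuple[int, ...] = DEFAULT_LAGS,
) -> tuple[Recording, list[int]]:
    """Convenience: decompose, flag blink components, reconstruct without them."""
    montage = montage or rec.montage
    model = sobi_decompose(rec, lags=lags)
    flagged = identify_blink_components(model, montage, crit)
    return reconstruct_without(rec, model, flagged), flagged


def amari_index(P: np.ndarray) -> float:
    """Amari separation index of a permutation-like matrix ``P = unmixing @ mixing``.

    0 for a scaled permutation, increasing toward 1 for heavy cross-talk.
    """
    P = np.abs(np.asarray(P, dtype=float))
    m = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * m * (m - 1)))
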