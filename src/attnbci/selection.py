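"""Orthogonal forward regression (OFR) ranking with random-probe selection.

OFR greedily ranks candidate features: at each step it selects the
candidate with the largest squared cosine to the current residual target,
then orthogonalizes the remaining candidates and the target against the
selected feature (Gram-Schmidt), and repeats.  For multi-class targets the
relevance is the squared cosine between the candidate and the subspace
spanned by the residual target contrasts, which stays in [0, 1].

The stopping rule is the random-probe method: iid standard-normal probe
columns are appended to the candidate set and ranked jointly.  A true
feature is retained only if, at the moment of its selection, fewer than
(1 - probe_quantile) * n_probes probes have already been selected; the
first violation stops retention, so the kept features form a prefix of the
non-probe ranking.  At the default 95% quantile with 100 probes a feature
is kept only while fewer than 5 probes outrank it, which calibrates the
false-selection rate of pure-noise candidates near 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import CONDITIONS

_RESIDUAL_TOL = 1e-12


def encode_target(labels: np.ndarray, classes: list[str] | None = None) -> np.ndarray:
    """Encode condition labels as regression target column(s).

    Two classes: a single +/-1 vector.  Three classes: two Helmert contrast
    columns (class1 vs class2, and their mean vs class3), mutually
    orthogonal with zero mean under a balanced design.
    """
    labels = np.asarray(labels)
    if classes is None:
        present = set(labels.tolist())
        classes = [c for c in CONDITIONS if c in present]
        if not classes:  # labels outside the task vocabulary: sorted order
            classes = sorted(present)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to build a target")
    if len(classes) == 2:
        y = np.where(labels == classes[1], 1.0, -1.0)
        return y[:, None]
    if len(classes) == 3:
        codes = {
            classes[0]: (-1.0, -1.0),
            classes[1]: (1.0, -1.0),
            classes[2]: (0.0, 2.0),
        }
        Y = np.array([codes[l] for l in labels.tolist()])
        return Y
    raise ValueError(f"unsupported class count {len(classes)}")


@dataclass(frozen=True)
class SelectionConfig:
    n_probes: int = 100
    probe_quantile: float = 0.95
    max_features: int = 30
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.probe_quantile < 1):
            raise ValueError("probe_quantile must lie in (0, 1)")
        if self.n_probes < 20:
            raise ValueError("need at least 20 probes to resolve the quantile")


@dataclass
class RankingResult:
    """Outcome of (probe-guarded) OFR ranking.

    ``order`` lists true-feature indices in selection order; ``kept`` marks
    the retained prefix; ``probe_positions`` records the overall ranks
    (0-based, counting probes too) at which probes were selected.
    """

    order: list[int]
    relevance: list[float]
    kept: np.ndarray
    n_kept: int
    probe_positions: list[int]
    stopped_early: bool = False

    @property
    def kept_order(self) -> list[int]:
        return self.order[: self.n_kept]


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def rank_ofr(
    X: np.ndarray,
    Y: np.ndarray,
    max_features: int | None = None,
    n_true: int | None = None,
    probe_threshold: float | None = None,
    max_kept: int | None = None,
) -> RankingResult:
    """Rank features by OFR; optionally apply the probe stopping rule.

    Columns of ``X`` beyond index ``n_true`` (if given) are treated as
    probes: they participate in the ranking but are never reported in
    ``order``; retention of true features follows ``probe_threshold``
    (stop once that many probes have been selected).

    Zero-variance columns are dropped with a warning.  If the target
    residual collapses (norm < 1e-12) ranking stops early with a flag.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    n_true = p if n_true is None else n_true
    max_features = n_true if max_features is None else max_features

    Xr = X - X.mean(axis=0)
    Yr = Y - Y.mean(axis=0)

    norms = np.linalg.norm(Xr, axis=0)
    alive = norms > _RESIDUAL_TOL
    if (~alive[:n_true]).any():
        warnings.warn(
            f"dropping {int((~alive[:n_true]).sum())} zero-variance feature(s)",
            RuntimeWarning,
            stacklevel=2,
        )

    order: list[int] = []
    relevance: list[float] = []
    probe_positions: list[int] = []
    kept = np.zeros(n_true, dtype=bool)
    n_kept = 0
    probes_seen = 0
    stopped_early = False
    retaining = probe_threshold is not None
    step = 0

    while len(order) < max_features:
        if not alive.any():
            break
        # orthonormal basis of the residual target span
        Qy, Ry = np.linalg.qr(Yr)
        keep_y = np.abs(np.diag(Ry)) > _RESIDUAL_TOL
        if not keep_y.any():
            stopped_early = True
            break
        Qy = Qy[:, keep_y]

        col_norms = np.linalg.norm(Xr, axis=0)
        dead = col_norms <= _RESIDUAL_TOL
        alive &= ~dead
        if not alive.any():
            break
        proj = Qy.T @ Xr  # (t, p)
        rel = np.zeros(p)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel[alive] = (proj[:, alive] ** 2).sum(axis=0) / col_norms[alive] ** 2
        j = int(np.flatnonzero(alive)[np.argmax(rel[alive])])  # ties: lowest index

        if j >= n_true:
            probes_seen += 1
            probe_positions.append(step)
            if retaining and probes_seen >= probe_threshold:
                break  # no later feature can be retained
        else:
            order.append(j)
            relevance.append(float(min(rel[j], 1.0)))
            if retaining:
                if probes_seen < probe_threshold and n_kept == len(order) - 1:
                    kept[j] = True
                    n_kept += 1
                    if max_kept is not None and n_kept >= max_kept:
                        step += 1
                        break
            else:
                kept[j] = True
                n_kept += 1
        step += 1

        # Gram-Schmidt: remove the selected direction from candidates and target
        v = Xr[:, j] / np.linalg.norm(Xr[:, j])
        Xr = Xr - np.outer(v, v @ Xr)
        Yr = Yr - np.outer(v, v @ Yr)
        alive[j] = False

    return RankingResult(order, relevance, kept, n_kept, probe_positions, stopped_early)


def probe_select(X: np.ndarray, Y: np.ndarray, cfg: SelectionConfig) -> RankingResult:
    """OFR ranking of ``X`` against ``Y`` with random-probe retention.

    Appends ``cfg.n_probes`` iid standard-normal probe columns, ranks the
    joint set, and retains true features selected while fewer than
    ``(1 - probe_quantile) * n_probes`` probes have been chosen.
    """
    X = np.asarray(X, dtype=np.float64)
    if cfg.standardize:
        X = _standardize(X)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x9806E]))
    probes = rng.standard_normal((X.shape[0], cfg.n_probes))
    joint = np.hstack([X, probes])
    threshold = (1.0 - cfg.probe_quantile) * cfg.n_probes
    return rank_ofr(
        joint,
        Y,
        max_features=cfg.max_features + cfg.n_probes,
        n_true=X.shape[1],
        probe_threshold=threshold,
        max_kept=cfg.max_features,
    )
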