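"""Label-noise machinery: forward-corrected cross-entropy and transition matrices.

Weak slide/node-level labels contain mistakes (e.g. missed isolated tumor
cells).  Forward correction models the label noise with a row-stochastic
transition matrix T, where ``T[i][j]`` is the probability of *observing*
label j when the *true* label is i, and trains against the corrected class
distribution ``q = T' p`` instead of the raw prediction ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_ROW_TOL = 1e-9


class NoiseError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseTransition:
    """Row-stochastic K x K label-noise transition matrix (K = 2 here)."""

    T: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.T, dtype=np.float64)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise NoiseError("transition matrix must be square")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > _ROW_TOL):
            raise NoiseError("transition matrix rows must be non-negative and sum to 1")
        object.__setattr__(self, "T", t)

    @classmethod
    def identity(cls, k: int = 2) -> "NoiseTransition":
        return cls(np.eye(k))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.T, delimiter=",", fmt="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "NoiseTransition":
        return cls(np.atleast_2d(np.loadtxt(path, delimiter=",")))


def forward_corrected_ce(p: float, y: int, noise: NoiseTransition) -> float:
    """Forward-corrected binary cross-entropy.

    With predicted positive probability ``p`` and observed label ``y``, the
    corrected observed-class distribution is ``q = T' (1-p, p)`` and the loss
    is ``-ln q[y]``.  With T = I this is plain binary cross-entropy.
    """
    if not (0.0 < p < 1.0):
        raise NoiseError(f"p must be in (0, 1), got {p}")
    if y not in (0, 1):
        raise NoiseError(f"label must be 0 or 1, got {y}")
    q = noise.T.T @ np.array([1.0 - p, p])
    return float(-np.log(q[y]))


def forward_corrected_ce_grad(p: float, y: int, noise: NoiseTransition) -> float:
    """d loss / d p of :func:`forward_corrected_ce` (closed form)."""
    if not (0.0 < p < 1.0):
        raise NoiseError(f"p must be in (0, 1), got {p}")
    if y not in (0, 1):
        raise NoiseError(f"label must be 0 or 1, got {y}")
    q_y = noise.T[0, y] * (1.0 - p) + noise.T[1, y] * p
    return float(-(noise.T[1, y] - noise.T[0, y]) / q_y)


def estimate_transition(observed, truth) -> NoiseTransition:
    """Estimate T from annotator labels against ground truth by counting.

    ``observed`` may be one annotator's label list or a list of such lists
    (counts pool across annotators before normalizing).  A truth class with
    no examples falls back to Laplace add-one smoothing for that row.
    """
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0:
        raise NoiseError("empty input")
    obs_lists = observed
    if len(obs_lists) and np.isscalar(obs_lists[0]):
        obs_lists = [observed]
    counts = np.zeros((2, 2), dtype=np.float64)
    for obs in obs_lists:
        obs = np.asarray(obs, dtype=int)
        if obs.shape != truth.shape:
            raise NoiseError("observed and truth must have equal length")
        if np.any((obs != 0) & (obs != 1)) or np.any((truth != 0) & (truth != 1)):
            raise NoiseError("labels must be binary")
        for i in (0, 1):
            for j in (0, 1):
                counts[i, j] += np.sum((truth == i) & (obs == j))
    for i in (0, 1):
        if counts[i].sum() == 0:
            counts[i] += 1.0  # Laplace smoothing for an empty truth class
    return NoiseTransition(counts / counts.sum(axis=1, keepdims=True))
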