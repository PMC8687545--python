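"""Empirical mean-square-displacement estimators on event-indexed paths.

The centroid process is indexed by binding events, so the lag is an event
shift, not a physical time shift.  Three standard estimators are provided:
the overlapping and disjoint-window time averages (TAMSD) and the ensemble
average (EAMSD).  The two time averages coincide at lag 1, which is the lag
the analytic theory targets.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "tamsd_overlapping",
    "tamsd_disjoint",
    "eamsd",
    "mean_step_displacement",
]


def _as_positions(positions) -> np.ndarray:
    x = np.asarray(positions, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("positions must be an (N+1, 2) array of planar points")
    return x


def tamsd_overlapping(positions, k: int) -> float:
    """Time-averaged MSD with overlapping windows at event lag ``k``.

    ``(1/(N-k+1)) sum_{i=0}^{N-k} |x_{i+k} - x_i|^2`` for positions
    ``x_0 .. x_N``.
    """
    x = _as_positions(positions)
    N = len(x) - 1
    if not 1 <= k <= N:
        raise ValueError(f"lag k must lie in [1, {N}], got {k}")
    d = x[k:] - x[:-k]
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


def tamsd_disjoint(positions, k: int) -> float:
    """Time-averaged MSD with disjoint windows at event lag ``k``.

    ``(1/floor(N/k)) sum_{i=0}^{floor(N/k)-1} |x_{(i+1)k} - x_{ik}|^2``;
    identical to the overlapping estimator when ``k = 1``.
    """
    x = _as_positions(positions)
    N = len(x) - 1
    if k < 1:
        raise ValueError("lag k must be >= 1")
    M = N // k
    if M == 0:
        raise ValueError(f"no complete window of length {k} in {N} steps")
    xs = x[:: k][: M + 1]
    d = np.diff(xs, axis=0)
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


def eamsd(trajectories, tau: int) -> float:
    """Ensemble-averaged MSD: ``(1/P) sum_j |x^j(tau) - x^j(0)|^2``."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    sq = []
    for pos in trajectories:
        x = _as_positions(pos)
        if len(x) <= tau:
            raise ValueError(f"trajectory of length {len(x)} too short for tau={tau}")
        d = x[tau] - x[0]
        sq.append(d @ d)
    if not sq:
        raise ValueError("empty ensemble")
    return float(np.mean(sq))


def mean_step_displacement(positions) -> np.ndarray:
    """Mean per-event displacement vector ``(x_N - x_0)/N``."""
    x = _as_positions(positions)
    N = len(x) - 1
    if N == 0:
        raise ValueError("need at least one displacement")
    return (x[-1] - x[0]) / N
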