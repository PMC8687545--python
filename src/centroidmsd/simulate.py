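"""Event-driven simulation of the discrete centroid jump process.

Each binding event is one attach or one detach.  With ``k`` of ``n`` FAs
attached, the next event is an attachment with probability
``(n-k) r p`` where ``p = 1/(k + (n-k) r)``, and a detachment otherwise.
An attaching FA is placed at a random outreach from the current centroid;
after every event the centroid jumps to the mean of the attached positions
(it stays put if nothing is attached).

Randomness comes from a single seeded ``numpy`` generator with a fixed draw
order per event -- event-type uniform, FA-selection uniform, then (attach
only) the length and angle draws -- so trajectories are bit-reproducible.
The eligible FAs for selection are taken in increasing id order.
"""

from __future__ import annotations

import math
from bisect import insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    CellState,
    EventRecord,
    ModelParams,
    OutreachDistribution,
    Trajectory,
)

__all__ = ["InitPolicy", "attach_probability", "step", "simulate"]

ATTACH = "attach"
DETACH = "detach"


@dataclass(frozen=True)
class InitPolicy:
    """Initial condition for a simulation.

    ``circle_all_attached`` (the default) places the n FAs equally spaced on
    a circle around ``center`` whose radius is drawn uniformly from
    ``[radius_lo, radius_hi]``, with every FA attached.
    ``steady_state_count`` instead draws the attachment count from the
    stationary distribution and builds a sequential configuration with that
    many FAs attached (detached FAs parked at the centroid).
    """

    mode: str = "circle_all_attached"
    radius_lo: float = 0.0
    radius_hi: float = 10.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in ("circle_all_attached", "steady_state_count"):
            raise ValueError(f"unknown init mode {self.mode!r}")


def attach_probability(n: int, r, k: int):
    """Probability that the next event is an attachment, given k attached.

    Equals ``(n-k) * r * p`` with ``p = 1/(k + (n-k) r)``; the detach
    probability is the complement ``k * p`` and the two sum to one.  Works
    with exact ``Fraction`` arithmetic as well as floats.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, {n}], got {k}")
    return (n - k) * r / (k + (n - k) * r)


# ---------------------------------------------------------------------------
# Core event kernel.  Operates on flat mutable state (position lists, sorted
# id lists) shared by step() and simulate() so both follow the exact same
# random draw order.


def _recompute_centroid(px, py, attached, weights):
    if weights is None:
        sx = 0.0
        sy = 0.0
        for i in attached:
            sx += px[i]
            sy += py[i]
        m = len(attached)
        return sx / m, sy / m
    sx = sy = sw = 0.0
    for i in attached:
        w = weights[i]
        sx += w * px[i]
        sy += w * py[i]
        sw += w
    return sx / sw, sy / sw


def _event(n, r, px, py, attached, detached, cx, cy, rng, length_law, angle_law, weights):
    k = len(attached)
    u = rng.random()
    if u < (n - k) * r / (k + (n - k) * r):
        m = n - k
        idx = int(rng.random() * m)
        if idx == m:  # guard against u*m rounding up to m
            idx = m - 1
        fa = detached.pop(idx)
        L = length_law.sample(rng)
        theta = math.radians(angle_law.sample(rng))
        px[fa] = cx + L * math.cos(theta)
        py[fa] = cy + L * math.sin(theta)
        insort(attached, fa)
        kind = ATTACH
    else:
        idx = int(rng.random() * k)
        if idx == k:
            idx = k - 1
        fa = attached.pop(idx)
        insort(detached, fa)
        kind = DETACH
    if attached:
        cx, cy = _recompute_centroid(px, py, attached, weights)
    return kind, fa, cx, cy


def step(
    state: CellState,
    params: ModelParams,
    dist: OutreachDistribution,
    rng: np.random.Generator,
) -> tuple[CellState, EventRecord]:
    """Advance one binding event; returns the new state and its record."""
    n = state.n
    px = state.v[:, 0].tolist()
    py = state.v[:, 1].tolist()
    attached = [i for i in range(n) if state.psi[i]]
    detached = [i for i in range(n) if not state.psi[i]]
    weights = None
    if not np.allclose(state.weights, state.weights[0]):
        weights = state.weights.tolist()
    kind, fa, cx, cy = _event(
        n, params.r, px, py, attached, detached,
        float(state.c[0]), float(state.c[1]),
        rng, dist.length, dist.angle_deg, weights,
    )
    psi = state.psi.copy()
    psi[fa] = kind == ATTACH
    new = CellState(psi, np.column_stack([px, py]), np.array([cx, cy]), state.weights.copy())
    rec = EventRecord(0, kind, fa, len(attached), (cx, cy))
    return new, rec


def _initial_state(params, dist, init, rng):
    """Build the initial configuration; consumes draws in documented order."""
    n = params.n
    if init.mode == "circle_all_attached":
        radius = init.radius_lo + (init.radius_hi - init.radius_lo) * rng.random()
        angles = 2.0 * math.pi * np.arange(n) / n
        cx0, cy0 = init.center
        px = (cx0 + radius * np.cos(angles)).tolist()
        py = (cy0 + radius * np.sin(angles)).tolist()
        attached = list(range(n))
        detached = []
    else:  # steady_state_count
        from .theory import stationary_distribution

        pi = stationary_distribution(n, params.r)
        u = rng.random()
        k = int(np.searchsorted(np.cumsum(pi), u))
        k = min(k, n)
        cx0, cy0 = init.center
        px = [cx0] * n
        py = [cy0] * n
        attached = []
        detached = list(range(n))
        cx, cy = cx0, cy0
        for m in range(1, k + 1):
            fa = m - 1
            if m == 1:
                px[fa], py[fa] = cx, cy
            else:
                eta = dist.sample(rng)
                px[fa] = cx + eta[0]
                py[fa] = cy + eta[1]
                cx += eta[0] / m
                cy += eta[1] / m
            attached.append(fa)
            detached.remove(fa)
        if attached:
            cx, cy = _recompute_centroid(px, py, attached, None)
            return px, py, attached, detached, cx, cy
        return px, py, attached, detached, cx0, cy0
    cx, cy = _recompute_centroid(px, py, attached, None)
    return px, py, attached, detached, cx, cy


def simulate(
    params: ModelParams,
    dist: OutreachDistribution | None = None,
    init: InitPolicy | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run ``burn_in`` unrecorded events, then record ``events`` events.

    Deterministic given ``params.seed`` (or an explicit generator).  The
    returned trajectory's ``initial_centroid`` is the centroid right after
    burn-in, so ``trajectory.positions`` holds ``events + 1`` points.
    """
    if dist is None:
        dist = OutreachDistribution()
    if init is None:
        init = InitPolicy()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n, r = params.n, params.r
    length_law, angle_law = dist.length, dist.angle_deg
    px, py, attached, detached, cx, cy = _initial_state(params, dist, init, rng)

    for _ in range(params.burn_in):
        _, _, cx, cy = _event(
            n, r, px, py, attached, detached, cx, cy, rng, length_law, angle_law, None
        )

    initial_centroid = np.array([cx, cy])
    m = params.events
    kinds = np.empty(m, dtype=bool)  # True = attach
    fas = np.empty(m, dtype=np.int32)
    counts = np.empty(m, dtype=np.int16)
    cxs = np.empty(m)
    cys = np.empty(m)
    for j in range(m):
        kind, fa, cx, cy = _event(
            n, r, px, py, attached, detached, cx, cy, rng, length_law, angle_law, None
        )
        kinds[j] = kind == ATTACH
        fas[j] = fa
        counts[j] = len(attached)
        cxs[j] = cx
        cys[j] = cy

    records = pd.DataFrame(
        {
            "event": np.arange(1, m + 1),
            "kind": np.where(kinds, ATTACH, DETACH),
            "fa": fas,
            "attached": counts,
            "cx": cxs,
            "cy": cys,
        }
    )
    return Trajectory(
        records=records,
        initial_centroid=initial_centroid,
        params=params,
        dist=dist,
        init_mode=init.mode,
    )
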