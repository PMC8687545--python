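"""Geometry of the centroid jump process.

The cell is modelled as a set of ``n`` focal adhesions (FAs) in the plane,
each either attached to the substrate or detached, plus a centroid that sits
at the (weighted) mean of the attached FA positions -- the force balance of
identical linear springs.  A newly attaching FA is placed at a random
*outreach* vector from the current centroid, drawn from the distribution
``nu`` specified by a length law and an angle law.

This module holds the domain types (outreach distribution, cell state, model
parameters, event records, trajectories) and the exact first and second
moments of the outreach law that the analytic MSD formulas consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Uniform",
    "Degenerate",
    "OutreachDistribution",
    "CellState",
    "ModelParams",
    "EventRecord",
    "Trajectory",
    "UnsupportedLawError",
    "NoAttachedSitesError",
    "UnequalWeightsError",
    "sample_outreach",
    "outreach_mean_vector",
    "outreach_mean_square",
    "solve_centroid",
]


class UnsupportedLawError(ValueError):
    """A distribution law for which no closed-form moment is implemented."""


class NoAttachedSitesError(ValueError):
    """Centroid requested for a state with no attached focal adhesions."""


class UnequalWeightsError(ValueError):
    """Analytic formulas assume equal spring constants; unequal ones given."""


# ---------------------------------------------------------------------------
# Scalar laws


@dataclass(frozen=True)
class Uniform:
    """Continuous uniform law on ``[lo, hi]``.

    Consumes exactly one uniform variate per sample (``lo + (hi-lo)*u``).
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi >= self.lo:
            raise ValueError(f"uniform law needs hi >= lo, got [{self.lo}, {self.hi}]")

    def sample(self, rng: np.random.Generator) -> float:
        return self.lo + (self.hi - self.lo) * rng.random()

    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def mean_square(self) -> float:
        # E[X^2] = (lo^2 + lo*hi + hi^2)/3 for X ~ U(lo, hi)
        return (self.lo * self.lo + self.lo * self.hi + self.hi * self.hi) / 3.0

    def maximum(self) -> float:
        return self.hi


@dataclass(frozen=True)
class Degenerate:
    """Point mass at ``value``.  Consumes no random variates."""

    value: float

    def sample(self, rng: np.random.Generator) -> float:
        return self.value

    def mean(self) -> float:
        return self.value

    def mean_square(self) -> float:
        return self.value * self.value

    def maximum(self) -> float:
        return self.value


_LAW_NAMES = {Uniform: "uniform", Degenerate: "degenerate"}


def _law_to_config(law) -> dict:
    if isinstance(law, Uniform):
        return {"law": "uniform", "lo": law.lo, "hi": law.hi}
    if isinstance(law, Degenerate):
        return {"law": "degenerate", "value": law.value}
    raise UnsupportedLawError(f"cannot serialize law {law!r}")


def _law_from_config(cfg: dict):
    kind = cfg.get("law")
    if kind == "uniform":
        return Uniform(float(cfg["lo"]), float(cfg["hi"]))
    if kind == "degenerate":
        return Degenerate(float(cfg["value"]))
    raise UnsupportedLawError(f"unknown law {kind!r}")


def _angle_moments_deg(law) -> tuple[float, float]:
    """(E[cos theta], E[sin theta]) for an angle law given in degrees."""
    if isinstance(law, Degenerate):
        t = math.radians(law.value)
        return math.cos(t), math.sin(t)
    if isinstance(law, Uniform):
        a, b = math.radians(law.lo), math.radians(law.hi)
        if b == a:
            return math.cos(a), math.sin(a)
        return (math.sin(b) - math.sin(a)) / (b - a), (math.cos(a) - math.cos(b)) / (b - a)
    raise UnsupportedLawError(f"no closed-form angle moments for {law!r}")


def _length_law_check(law) -> None:
    if isinstance(law, (Uniform, Degenerate)):
        if law.maximum() <= 0 or not math.isfinite(law.maximum()):
            raise ValueError("length law must have a finite positive maximum")
        lo = law.lo if isinstance(law, Uniform) else law.value
        if lo < 0:
            raise ValueError("outreach lengths must be nonnegative")
        return
    raise UnsupportedLawError(f"unsupported length law {law!r}")


# ---------------------------------------------------------------------------
# Outreach distribution


@dataclass(frozen=True)
class OutreachDistribution:
    """The law ``nu`` of the outreach vector eta = (L cos th, L sin th).

    ``length`` is the law of L (length units) and ``angle_deg`` the law of
    the angle, in degrees counter-clockwise from the positive x-axis.  The
    defaults -- length uniform on [0, 10], angle uniform on [-30, 30]
    degrees -- give a forward-biased outreach with E[eta] = (15/pi, 0) and
    E[|eta|^2] = 100/3.
    """

    length: Uniform | Degenerate = field(default_factory=lambda: Uniform(0.0, 10.0))
    angle_deg: Uniform | Degenerate = field(default_factory=lambda: Uniform(-30.0, 30.0))

    def __post_init__(self) -> None:
        _length_law_check(self.length)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one outreach vector; draw order is length first, then angle."""
        L = self.length.sample(rng)
        theta = math.radians(self.angle_deg.sample(rng))
        return np.array([L * math.cos(theta), L * math.sin(theta)])

    def mean_vector(self) -> np.ndarray:
        """E[eta] = E[L] * (E[cos th], E[sin th]), exact for the supported laws."""
        ec, es = _angle_moments_deg(self.angle_deg)
        el = self.length.mean()
        return np.array([el * ec, el * es])

    def mean_square(self) -> float:
        """E[|eta|^2] = E[L^2]; the angle law drops out."""
        return self.length.mean_square()

    @property
    def max_length(self) -> float:
        """eta_max, the largest possible outreach length."""
        return self.length.maximum()

    def to_config(self) -> dict:
        return {"length": _law_to_config(self.length), "angle_deg": _law_to_config(self.angle_deg)}

    @classmethod
    def from_config(cls, cfg: dict) -> "OutreachDistribution":
        return cls(
            length=_law_from_config(cfg["length"]),
            angle_deg=_law_from_config(cfg["angle_deg"]),
        )


def sample_outreach(dist: OutreachDistribution, rng: np.random.Generator) -> np.ndarray:
    return dist.sample(rng)


def outreach_mean_vector(dist: OutreachDistribution) -> np.ndarray:
    return dist.mean_vector()


def outreach_mean_square(dist: OutreachDistribution) -> float:
    return dist.mean_square()


# ---------------------------------------------------------------------------
# Cell state and force balance


def solve_centroid(positions, weights=None) -> np.ndarray:
    """Centroid of the attached FA positions: the zero of the spring force sum.

    With spring constants ``alpha_i`` the force balance
    ``sum_i alpha_i (v_i - c) = 0`` over attached sites has the unique
    solution ``c = sum alpha_i v_i / sum alpha_i``.

    Raises
    ------
    NoAttachedSitesError
        If ``positions`` is empty; the caller should keep the previous
        centroid (the centroid does not move when every FA is detached).
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.size == 0:
        raise NoAttachedSitesError("no attached focal adhesions")
    if weights is None:
        return pos.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("spring weights must be positive")
    return (w[:, None] * pos).sum(axis=0) / w.sum()


@dataclass
class CellState:
    """Attachment pattern, FA positions, centroid and spring weights.

    Invariant: whenever at least one FA is attached, the centroid satisfies
    ``sum_i alpha_i psi_i (v_i - c) = 0``.  Detached FA positions are kept
    unchanged until the site reattaches.
    """

    psi: np.ndarray
    v: np.ndarray
    c: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=bool)
        self.v = np.asarray(self.v, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        n = self.psi.shape[0]
        if self.v.shape != (n, 2):
            raise ValueError(f"v must have shape ({n}, 2)")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,) or np.any(self.weights <= 0):
                raise ValueError("weights must be positive, one per FA")

    @property
    def n(self) -> int:
        return self.psi.shape[0]

    @property
    def attached_count(self) -> int:
        return int(self.psi.sum())

    def force_balance_residual(self) -> float:
        """Norm of ``sum alpha_i psi_i (v_i - c)``; zero at force balance."""
        if self.attached_count == 0:
            return 0.0
        f = (self.weights[self.psi, None] * (self.v[self.psi] - self.c)).sum(axis=0)
        return float(np.hypot(f[0], f[1]))

    def copy(self) -> "CellState":
        return CellState(self.psi.copy(), self.v.copy(), self.c.copy(), self.weights.copy())


@dataclass(frozen=True)
class ModelParams:
    """Simulation parameters: FA count, propensity ratio and event budget.

    ``r`` is the ratio of a detached FA's switching propensity to an attached
    one's; with ``k`` FAs attached the per-FA switch probabilities are ``p``
    (attached) and ``r p`` (detached) with ``k p + (n-k) r p = 1``.
    """

    n: int
    r: float
    events: int = 0
    burn_in: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        if not self.r > 0:
            raise ValueError("r must be positive")
        if self.events < 0 or self.burn_in < 0:
            raise ValueError("events and burn_in must be nonnegative")


class EventRecord(NamedTuple):
    """One binding event: its index, kind, the FA involved and the result."""

    index: int
    kind: str  # "attach" | "detach"
    fa_id: int
    attached_after: int
    centroid_after: tuple[float, float]


@dataclass
class Trajectory:
    """An ordered sequence of binding events with provenance metadata.

    ``records`` has columns ``event, kind, fa, attached, cx, cy`` with the
    event index starting at 1; ``initial_centroid`` is the centroid after
    burn-in, i.e. the position the first recorded displacement is measured
    from.  ``positions`` therefore has ``len(records) + 1`` rows.
    """

    records: pd.DataFrame
    initial_centroid: np.ndarray | None = None
    params: ModelParams | None = None
    dist: OutreachDistribution | None = None
    init_mode: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        pts = self.records[["cx", "cy"]].to_numpy(dtype=float)
        if self.initial_centroid is None:
            return pts
        return np.vstack([np.asarray(self.initial_centroid, dtype=float), pts])

    def event_records(self) -> list[EventRecord]:
        return [
            EventRecord(int(e), str(k), int(f), int(a), (float(x), float(y)))
            for e, k, f, a, x, y in self.records.itertuples(index=False)
        ]
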