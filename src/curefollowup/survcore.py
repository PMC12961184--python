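"""Kaplan-Meier estimation, least concave majorants and the Grenander
estimator of a nonincreasing density under right censoring.

The event-time distribution of interest is improper in a mixture cure
model: ``F(t) = p * Fu(t)`` where ``p < 1`` is the uncured fraction, so the
product-limit estimator plateaus below one.  The censoring distribution
``G`` is estimated by the same product-limit construction with the roles of
events and censorings exchanged.  The Grenander estimator of the (assumed
nonincreasing) subdensity ``f = p * fu`` is the left derivative of the
least concave majorant (LCM) of the Kaplan-Meier estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, OutOfRangeError

__all__ = [
    "SurvivalSample",
    "StepDistribution",
    "ConcaveMajorant",
    "MonotoneDensity",
    "km_distribution",
    "km_censoring",
    "lcm",
    "grenander_density",
    "density_at",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data: observed times and event indicators.

    Parameters
    ----------
    times
        Observed follow-up times ``Y_i = min(T_i, C_i) >= 0``.
    events
        Indicators ``delta_i = 1{T_i <= C_i}`` (1 = uncensored event).
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        if times.ndim != 1 or events.ndim != 1:
            raise InvalidInputError("times and events must be 1-d vectors")
        if times.size == 0:
            raise InvalidInputError("empty sample")
        if times.size != events.size:
            raise InvalidInputError(
                f"length mismatch: {times.size} times vs {events.size} events"
            )
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise InvalidInputError("times must be finite and nonnegative")
        if not np.isin(events, (0, 1)).all():
            raise InvalidInputError("events must be 0 or 1")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int8))

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def y_max(self) -> float:
        """Largest observed time Y_(n)."""
        return float(self.times.max())

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def y_max_event(self) -> float:
        """Largest uncensored time (the last jump of the KME)."""
        if self.n_events == 0:
            raise InvalidInputError("sample has no uncensored observations")
        return float(self.times[self.events == 1].max())


@dataclass(frozen=True)
class StepDistribution:
    """Right-continuous nondecreasing step function with values in [0, 1].

    Evaluation at ``t`` returns the value at the largest knot ``<= t`` and
    0 before the first knot.  ``left_limit`` gives the corresponding
    left-continuous version, used for the censoring mass ``1 - G(tauG-)``.
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.size != values.size:
            raise InvalidInputError("knots and values must have equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise InvalidInputError("knots must be strictly increasing")
        if values.size and (np.any(np.diff(values) < -1e-12)
                            or values[0] < -1e-12 or values[-1] > 1 + 1e-12):
            raise InvalidInputError("values must be nondecreasing in [0, 1]")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.knots.size == 0:
            out = np.zeros_like(t)
        else:
            idx = np.searchsorted(self.knots, t, side=side) - 1
            out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return float(out) if out.ndim == 0 else out

    def __call__(self, t):
        return self._eval(t, "right")

    def left_limit(self, t):
        """Value just before ``t``: the value at the largest knot < t."""
        return self._eval(t, "left")

    def to_text(self) -> str:
        lines = ["knot\tvalue"]
        lines += [f"{k:.12g}\t{v:.12g}" for k, v in zip(self.knots, self.values)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ConcaveMajorant:
    """Piecewise-linear least concave majorant, stored by its vertices."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.size < 2:
            raise InvalidInputError("a majorant needs at least two vertices")
        if np.any(np.diff(x) <= 0):
            raise InvalidInputError("vertex abscissae must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __call__(self, t):
        return np.interp(t, self.x, self.y)

    @property
    def slopes(self) -> np.ndarray:
        return np.diff(self.y) / np.diff(self.x)


@dataclass(frozen=True)
class MonotoneDensity:
    """Nonincreasing step density on a half-open region ``(edges[0], edges[-1]]``.

    ``heights[j]`` is the density value on ``(edges[j], edges[j+1]]``
    (left-continuous evaluation at the breakpoints).
    """

    edges: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if edges.size != heights.size + 1:
            raise InvalidInputError("need len(edges) == len(heights) + 1")
        if np.any(np.diff(edges) <= 0):
            raise InvalidInputError("edges must be strictly increasing")
        if np.any(heights < -1e-12):
            raise InvalidInputError("heights must be nonnegative")
        if np.any(np.diff(heights) > 1e-12):
            raise InvalidInputError("heights must be nonincreasing")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "heights", np.maximum(heights, 0.0))

    @property
    def region(self) -> tuple[float, float]:
        return float(self.edges[0]), float(self.edges[-1])

    def integral(self) -> float:
        """Total mass over the region (telescopes to the LCM increment)."""
        return float(np.sum(self.heights * np.diff(self.edges)))


def _risk_table(times: np.ndarray, events: np.ndarray):
    """Unique observed times with event counts, censoring counts and the
    number at risk (``#{j: Y_j >= t}``) at each."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted.astype(int), start)
    total = np.add.reduceat(np.ones_like(e_sorted, dtype=int), start)
    c = total - d
    at_risk = times.size - start  # counts with Y_j >= uniq (sorted)
    return uniq, d, c, at_risk


def _product_limit(uniq, counts, at_risk) -> StepDistribution:
    """Grouped product-limit distribution jumping at times with counts > 0."""
    jump = counts > 0
    factors = 1.0 - counts[jump] / at_risk[jump]
    surv = np.cumprod(factors)
    return StepDistribution(knots=uniq[jump], values=1.0 - surv)


def km_distribution(sample: SurvivalSample) -> StepDistribution:
    """Kaplan-Meier estimator of the (possibly improper) distribution of T.

    Grouped product-limit form: jumps only at uncensored times, with the
    convention that events precede censorings at tied times, so censored
    observations at a tied time are still in the risk set.
    """
    uniq, d, _, at_risk = _risk_table(sample.times, sample.events)
    return _product_limit(uniq, d, at_risk)


def km_censoring(sample: SurvivalSample) -> StepDistribution:
    """Product-limit estimator of the censoring distribution G.

    Mirror of :func:`km_distribution` with the roles of event and censoring
    indicators exchanged (censorings precede events at tied times).  The
    point mass of C at the end of follow-up is ``1 - G(tauG-)``, available
    through :meth:`StepDistribution.left_limit`.
    """
    uniq, _, c, at_risk = _risk_table(sample.times, sample.events)
    return _product_limit(uniq, c, at_risk)


def lcm(dist: StepDistribution, window: tuple[float, float]) -> ConcaveMajorant:
    """Least concave majorant of a step distribution over ``[t0, t1]``.

    The graph point ``(t0, dist(t0))`` anchors the majorant; if ``t1``
    exceeds the last knot the flat extension point ``(t1, dist(t1))`` is
    appended, so the Grenander density is defined on all of ``(t0, t1]``.
    Computed by an upper-convex-hull scan; returned vertices are a subset
    of the input graph points.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t1 > t0:
        raise InvalidInputError(f"empty window [{t0}, {t1}]")
    mask = (dist.knots > t0) & (dist.knots <= t1)
    xs = [t0, *dist.knots[mask]]
    ys = [dist(t0), *dist.values[mask]]
    if xs[-1] < t1:
        xs.append(t1)
        ys.append(dist(t1))
    if len(xs) < 2:
        raise InvalidInputError("no graph points in the window")

    # Upper hull, left to right: chord slopes must strictly decrease, so a
    # middle point making slopes non-decreasing (collinear included) is
    # popped; this keeps the vertex set minimal.
    hx: list[float] = []
    hy: list[float] = []
    for px, py in zip(xs, ys):
        while len(hx) >= 2:
            cross = (hx[-1] - hx[-2]) * (py - hy[-2]) - (px - hx[-2]) * (hy[-1] - hy[-2])
            if cross >= 0:  # turning left or collinear: middle point not a vertex
                hx.pop()
                hy.pop()
            else:
                break
        hx.append(px)
        hy.append(py)
    return ConcaveMajorant(x=np.array(hx), y=np.array(hy))


def grenander_density(majorant: ConcaveMajorant) -> MonotoneDensity:
    """Grenander-type estimator: left derivative of the LCM.

    A step function taking, on each inter-vertex segment, that segment's
    chord slope; left-continuous, so the value *at* a vertex is the slope
    of the segment ending there.
    """
    return MonotoneDensity(edges=majorant.x, heights=majorant.slopes)


def density_at(density: MonotoneDensity, t: float) -> float:
    """Left-continuous evaluation of a monotone step density at ``t``.

    ``t`` must lie in the half-open region ``(edges[0], edges[-1]]``.
    """
    lo, hi = density.region
    if not (lo < t <= hi):
        raise OutOfRangeError(f"t={t} outside the density region ({lo}, {hi}]")
    idx = int(np.searchsorted(density.edges, t, side="left")) - 1
    return float(density.heights[idx])
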