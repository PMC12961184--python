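"""Limiting law of the boundary Grenander estimator and its plug-in constant.

The centred and scaled Grenander estimate at the end of follow-up
converges to ``D_R[W](1)``: the right derivative, at t = 1, of the least
concave majorant of a standard Brownian motion on the half line.  No
closed form is available, so the law is approximated once by Monte Carlo
(discrete Brownian paths on ``[0, horizon]``, upper convex hull, slope of
the hull segment covering t = 1) and cached as a plain-text quantile
table.  The constant ``A1 = c [1 - G(tauG-)] / f(tauG)`` scales the
statistic; in practice both ingredients are replaced by plug-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit

from .exceptions import DegenerateDensityError, InvalidInputError

__all__ = [
    "SlopeQuantileTable",
    "PluginA1",
    "simulate_slope_quantiles",
    "plugin_a1",
    "default_slope_table",
]

DEFAULT_PROBS = np.round(np.arange(0.001, 1.0, 0.001), 3)
DEFAULT_META = {"reps": 100_000, "gridstep": 5e-4, "horizon": 5.0, "seed": 20260301}
_TABLE_RESOURCE = "slope_quantiles.tsv"


@dataclass(frozen=True)
class SlopeQuantileTable:
    """Empirical quantiles of ``D_R[W](1)`` with simulation metadata."""

    probs: np.ndarray
    quantiles: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        quantiles = np.asarray(self.quantiles, dtype=float)
        if probs.size != quantiles.size or probs.size < 2:
            raise InvalidInputError("probs and quantiles must align (length >= 2)")
        if np.any(np.diff(probs) <= 0) or probs[0] <= 0 or probs[-1] >= 1:
            raise InvalidInputError("probs must be strictly increasing in (0, 1)")
        if np.any(np.diff(quantiles) < 0):
            raise InvalidInputError("quantiles must be nondecreasing")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "quantiles", quantiles)

    def quantile(self, p: float) -> float:
        """Interpolated quantile at probability ``p``."""
        return float(np.interp(p, self.probs, self.quantiles))

    def cdf(self, x: float) -> float:
        """Interpolated distribution function at ``x`` (clamped to [0, 1])."""
        if x <= self.quantiles[0]:
            return float(self.probs[0])
        if x >= self.quantiles[-1]:
            return float(self.probs[-1])
        return float(np.interp(x, self.quantiles, self.probs))

    def upper_tail(self, x: float) -> float:
        """``P(D >= x)`` under the tabulated law."""
        return 1.0 - self.cdf(x)

    def to_text(self) -> str:
        lines = [
            "# distribution: right slope at t=1 of the LCM of Brownian motion",
            f"# reps={int(self.meta['reps'])}",
            f"# gridstep={self.meta['gridstep']:.10g}",
            f"# horizon={self.meta['horizon']:.10g}",
            f"# seed={int(self.meta['seed'])}",
            "prob\tquantile",
        ]
        lines += [f"{p:.6g}\t{q:.10g}" for p, q in zip(self.probs, self.quantiles)]
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "SlopeQuantileTable":
        meta = {}
        probs, quants = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, val = body.split("=", 1)
                    if key.strip() in ("reps", "gridstep", "horizon", "seed"):
                        meta[key.strip()] = float(val)
                continue
            if line.startswith("prob"):
                continue
            p, q = line.split("\t")
            probs.append(float(p))
            quants.append(float(q))
        for key in ("reps", "seed"):
            if key in meta:
                meta[key] = int(meta[key])
        return cls(probs=np.array(probs), quantiles=np.array(quants), meta=meta)

    @classmethod
    def load(cls, path) -> "SlopeQuantileTable":
        with open(path) as fh:
            return cls.from_text(fh.read())


@njit(cache=True)
def _hull_slopes_at_one(x, paths, out):  # pragma: no cover - jit kernel
    """Right slope at t=1 of the upper convex hull of each discrete path.

    ``x`` is the shared time grid (x[0] = 0 with path value 0), ``paths``
    a (reps, m) array of Brownian path values.  Monotone-chain scan with
    an index stack; the slope recorded is that of the hull segment whose
    left endpoint is <= 1 < right endpoint, i.e. the right derivative.
    """
    m = x.shape[0]
    stack = np.empty(m, dtype=np.int64)
    for r in range(paths.shape[0]):
        w = paths[r]
        top = 0
        stack[0] = 0
        for i in range(1, m):
            while top >= 1:
                i1 = stack[top - 1]
                i2 = stack[top]
                cross = (x[i2] - x[i1]) * (w[i] - w[i1]) - (x[i] - x[i1]) * (
                    w[i2] - w[i1]
                )
                if cross >= 0.0:
                    top -= 1
                else:
                    break
            top += 1
            stack[top] = i
        # locate the hull segment containing t = 1 on its left-closed side
        slope = 0.0
        for j in range(top):
            a = stack[j]
            b = stack[j + 1]
            if x[a] <= 1.0 < x[b]:
                slope = (w[b] - w[a]) / (x[b] - x[a])
                break
        out[r] = slope


def simulate_slope_quantiles(
    reps: int = DEFAULT_META["reps"],
    gridstep: float = DEFAULT_META["gridstep"],
    horizon: float = DEFAULT_META["horizon"],
    seed: int = DEFAULT_META["seed"],
    probs: np.ndarray | None = None,
    *,
    return_draws: bool = False,
):
    """Monte-Carlo approximation of the quantiles of ``D_R[W](1)``.

    Each replicate simulates a standard Brownian path on the grid
    ``{0, gridstep, ..., horizon}`` (started at (0, 0)), takes the least
    concave majorant of the discrete path and records the right derivative
    at t = 1.  The hull on ``[0, horizon]`` proxies the hull on the half
    line; horizon sensitivity is part of the test surface.
    """
    if horizon <= 1:
        raise InvalidInputError("horizon must exceed 1 (slope taken at t=1)")
    if reps < 1 or gridstep <= 0:
        raise InvalidInputError("need reps >= 1 and gridstep > 0")
    if probs is None:
        probs = DEFAULT_PROBS
    probs = np.asarray(probs, dtype=float)

    m = int(round(horizon / gridstep))
    x = np.linspace(0.0, m * gridstep, m + 1)
    rng = np.random.default_rng(seed)
    slopes = np.empty(reps)
    chunk = max(1, min(reps, int(2e7 // (m + 1))))
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        incr = rng.standard_normal((b, m)) * np.sqrt(gridstep)
        paths = np.empty((b, m + 1))
        paths[:, 0] = 0.0
        np.cumsum(incr, axis=1, out=paths[:, 1:])
        _hull_slopes_at_one(x, paths, slopes[done : done + b])
        done += b

    quantiles = np.quantile(slopes, probs)
    table = SlopeQuantileTable(
        probs=probs,
        quantiles=quantiles,
        meta={"reps": int(reps), "gridstep": float(gridstep),
              "horizon": float(horizon), "seed": int(seed)},
    )
    if return_draws:
        return table, slopes
    return table


def default_slope_table() -> SlopeQuantileTable:
    """The quantile table shipped with the package (see DEFAULT_META);
    regenerable with ``curefollowup quantile-table``."""
    text = resources.files("curefollowup").joinpath("data", _TABLE_RESOURCE).read_text()
    return SlopeQuantileTable.from_text(text)


@dataclass(frozen=True)
class PluginA1:
    """Plug-in of the scaling constant ``A1 = c [1 - G(tauG-)] / f(tauG)``.

    ``f(tauG)`` is replaced by the boundary Grenander estimate
    ``fG(tauG - c n^{-a})`` and the censoring mass by the product-limit
    left limit ``1 - G_hat(tauG-)``.
    """

    value: float
    c: float
    mass: float
    fhat: float


def plugin_a1(fhat_tauG: float, mass: float, c: float) -> PluginA1:
    """Compute the plug-in ``A1_hat = c * mass / fhat``.

    Raises a degenerate-density error when the density plug-in vanishes:
    the asymptotic test cannot be calibrated in that case and no value is
    fabricated.
    """
    if c <= 0:
        raise InvalidInputError("c must be positive")
    if not 0 < mass <= 1:
        raise InvalidInputError("censoring mass must lie in (0, 1]")
    if fhat_tauG <= 0:
        raise DegenerateDensityError(
            "Grenander plug-in density is zero at the evaluation point"
        )
    return PluginA1(value=c * mass / fhat_tauG, c=c, mass=mass, fhat=fhat_tauG)
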