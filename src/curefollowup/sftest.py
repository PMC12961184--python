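"""Tests for practically sufficient follow-up in survival data with a cure
fraction.

A follow-up of length ``tauG`` (the right endpoint of the censoring
distribution) is *practically sufficient* at tolerance ``epsilon`` when the
uncured event-time distribution satisfies ``Fu(tauG) > 1 - epsilon``: the
probability of an event after the end of the study is below ``epsilon``.
The null hypothesis is *insufficient* follow-up (``q_{1-eps} >= tauG``).
Under a nonincreasing tail density, insufficiency forces the subdensity
``f = p fu`` at ``tauG`` to stay above ``eps F(tauG) / (tau - tauG)`` for a
user-chosen horizon ``tau`` beyond which events are essentially
impossible, so the tests reject when a shape-constrained estimate of
``f(tauG)`` falls below that bound minus/plus a critical value:

* :func:`grenander_test` - boundary-evaluated Grenander estimator with an
  asymptotic critical value from the Brownian LCM slope law;
* :func:`smoothed_test` - boundary-kernel smoothed Grenander estimator
  with a smoothed-bootstrap critical value (the recommended test);
* :func:`alpha_n_test` - the classical comparator based on the gap between
  the largest observed and largest uncensored times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import smoothing, survcore
from .asymptotics import SlopeQuantileTable, default_slope_table, plugin_a1
from .exceptions import DegenerateDensityError, InvalidInputError, OutOfRangeError
from .smoothing import TRIWEIGHT, KernelSpec
from .survcore import SurvivalSample

__all__ = [
    "TestConfig",
    "TestResult",
    "grenander_test",
    "smoothed_test",
    "smoothed_bootstrap",
    "alpha_n_test",
    "apply_cutoff",
]


@dataclass(frozen=True)
class TestConfig:
    """Configuration shared by the follow-up tests.

    Parameters
    ----------
    epsilon
        Tolerated probability of an event after the end of the study.
    tau
        User horizon beyond which events are considered essentially
        impossible; must exceed ``tauG``.  Not data dependent.
    alpha
        Nominal level.
    a
        Boundary-evaluation exponent of the Grenander test; the estimator
        is evaluated at ``tauG - c n^{-a}`` with ``c = tauG``.
    B
        Number of smoothed-bootstrap replicates.
    seed
        Seed for every random stream used by a test run.
    tau_g
        Known end of follow-up (administrative censoring); ``None`` means
        "estimate by the largest observed time".
    region_start
        Left endpoint of the region where the density is assumed
        nonincreasing (0 = whole support).
    grid_points
        Resolution of the inverse-CDF grid used to sample from the
        oversmoothed density.
    """

    epsilon: float = 0.01
    tau: Optional[float] = None
    alpha: float = 0.05
    a: float = 0.34
    B: int = 500
    seed: Optional[int] = None
    tau_g: Optional[float] = None
    region_start: float = 0.0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    grid_points: int = 2000

    def __post_init__(self):
        if not 0 <= self.epsilon < 1:
            raise InvalidInputError("epsilon must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must lie in (0, 1)")
        if not 1 / 3 < self.a < 1:
            raise InvalidInputError("a must lie in (1/3, 1)")
        if self.B < 1:
            raise InvalidInputError("B must be >= 1")

    def resolve_tau_g(self, sample: SurvivalSample) -> float:
        if self.tau is None:
            raise InvalidInputError("tau (user horizon) is required")
        tau_g = self.tau_g if self.tau_g is not None else sample.y_max
        if not self.tau > tau_g:
            raise InvalidInputError(
                f"tau={self.tau} must exceed tauG={tau_g}"
            )
        if tau_g <= self.region_start:
            raise InvalidInputError("tauG must exceed the monotone-region start")
        return float(tau_g)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one follow-up test: statistic, threshold, p-value,
    decision and diagnostics."""

    method: str
    statistic: float
    threshold: float
    p_value: float
    reject: bool
    diagnostics: dict

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "threshold": self.threshold,
            "p_value": self.p_value,
            "reject": bool(self.reject),
            "diagnostics": {k: _jsonable(v) for k, v in self.diagnostics.items()},
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def apply_cutoff(sample: SurvivalSample, cutoff: float) -> SurvivalSample:
    """Administratively censor the sample at a hypothetical cutoff.

    Observations beyond the cutoff become censored at the cutoff; the
    sample size is unchanged.  Used to construct "what-if" scenarios with
    shorter follow-up.
    """
    if cutoff <= 0:
        raise InvalidInputError("cutoff must be positive")
    beyond = sample.times > cutoff
    times = np.where(beyond, cutoff, sample.times)
    events = np.where(beyond, 0, sample.events)
    return SurvivalSample(times=times, events=events)


def alpha_n_test(sample: SurvivalSample, config: TestConfig) -> TestResult:
    """Classical test of insufficient follow-up.

    ``q_n`` counts the fraction of uncensored observations in the interval
    ``(2 y~ - y, y~]`` where ``y`` is the largest observed and ``y~`` the
    largest uncensored time; the estimated p-value is ``(1 - q_n)^n``.
    """
    if sample.n_events == 0:
        raise InvalidInputError("alpha_n test needs at least one event")
    y = sample.y_max
    y_tilde = sample.y_max_event
    lower = 2 * y_tilde - y
    inside = (sample.times > lower) & (sample.times <= y_tilde)
    q_n = float(np.mean((sample.events == 1) & inside))
    alpha_n = float((1.0 - q_n) ** sample.n)
    return TestResult(
        method="alpha_n",
        statistic=q_n,
        threshold=config.alpha,
        p_value=alpha_n,
        reject=alpha_n < config.alpha,
        diagnostics={
            "q_n": q_n, "y_max": y, "y_max_event": y_tilde,
            "interval_lower": lower, "n": sample.n,
        },
    )


def _grenander_pieces(sample: SurvivalSample, config: TestConfig, tau_g: float):
    """KME, censoring KME, LCM on the monotone region and its slope density."""
    F = survcore.km_distribution(sample)
    G = survcore.km_censoring(sample)
    majorant = survcore.lcm(F, (config.region_start, tau_g))
    density = survcore.grenander_density(majorant)
    return F, G, majorant, density


def grenander_test(
    sample: SurvivalSample,
    config: TestConfig,
    table: SlopeQuantileTable | None = None,
) -> TestResult:
    """Asymptotic test based on the boundary-evaluated Grenander estimator.

    Rejects insufficient follow-up when ``fG(tauG - c n^{-a})`` (with
    ``c = tauG``) falls below
    ``eps F_n(tauG)/(tau - tauG) - Q^G_{1-alpha} / (A1_hat n^{(1-a)/2})``.
    The p-value inverts the rule through the tabulated slope law.
    """
    if table is None:
        table = default_slope_table()
    tau_g = config.resolve_tau_g(sample)
    n = sample.n
    F, G, _, density = _grenander_pieces(sample, config, tau_g)
    c = tau_g
    point = tau_g - c * n ** (-config.a)
    if point <= config.region_start:
        raise OutOfRangeError(
            f"evaluation point {point} falls at or below the monotone-region "
            f"start {config.region_start}; n too small for this tauG"
        )
    stat = survcore.density_at(density, point)
    mass = 1.0 - G.left_limit(tau_g)
    a1 = plugin_a1(stat, mass, c)
    f_bound = config.epsilon * F(tau_g) / (config.tau - tau_g)
    rate = n ** ((1 - config.a) / 2)
    s_value = a1.value * rate * (f_bound - stat)
    p_value = table.upper_tail(s_value)
    threshold = f_bound - table.quantile(1 - config.alpha) / (a1.value * rate)
    return TestResult(
        method="grenander",
        statistic=stat,
        threshold=threshold,
        p_value=p_value,
        reject=p_value < config.alpha,
        diagnostics={
            "tau_g": tau_g, "n": n, "evaluation_point": point,
            "F_n_tau_g": F(tau_g), "censoring_mass": mass,
            "A1_hat": a1.value, "density_bound": f_bound,
            "slope_statistic": s_value,
        },
    )


class _SmoothedMachinery:
    """Shared state for the smoothed test and its bootstrap: KME, LCM,
    bandwidths, the oversmoothed sampling density and the samplers."""

    def __init__(self, sample: SurvivalSample, config: TestConfig):
        self.sample = sample
        self.config = config
        self.tau_g = config.resolve_tau_g(sample)
        bw = smoothing.bandwidths(sample.n, self.tau_g)
        self.h, self.h0 = bw.h, bw.h0
        self.F, self.G, self.majorant, self.density = _grenander_pieces(
            sample, config, self.tau_g
        )
        self.statistic = smoothing.smoothed_grenander_endpoint(
            self.density, config.kernel, self.h, self.tau_g
        )
        self.p_star = float(self.F(self.tau_g))
        if self.p_star <= 0:
            raise DegenerateDensityError("KME mass is zero: no events observed")

        # oversmoothed density on a grid of [0, tauG] for inverse-CDF sampling
        self.grid = np.linspace(0.0, self.tau_g, config.grid_points)
        pdf = np.array([
            smoothing.oversmoothed_density(
                self.majorant, config.kernel, self.h0, self.tau_g, t
            )
            for t in self.grid
        ])
        cdf = np.concatenate([[0.0], cumulative_trapezoid(pdf, self.grid)])
        total = cdf[-1]
        if total <= 0:
            raise DegenerateDensityError(
                "oversmoothed density vanishes on [0, tauG]"
            )
        self.cdf = cdf / total
        self.ftil_tau_g = smoothing.oversmoothed_density(
            self.majorant, config.kernel, self.h0, self.tau_g, self.tau_g
        )

        # censoring sampler: inverse of the product-limit G with its point
        # mass at the largest observed time
        knots, values = self.G.knots, self.G.values
        if knots.size == 0 or values[-1] < 1.0:
            append_at = sample.y_max
            if knots.size and knots[-1] >= append_at:
                values = values.copy()
                values[-1] = 1.0
            else:
                knots = np.append(knots, append_at)
                values = np.append(values, 1.0)
        self.c_knots, self.c_values = knots, values

    def draw_sample(self, rng: np.random.Generator) -> SurvivalSample:
        n = self.sample.n
        uncured = rng.uniform(size=n) < self.p_star
        t_star = np.full(n, np.inf)
        t_star[uncured] = np.interp(
            rng.uniform(size=int(uncured.sum())), self.cdf, self.grid
        )
        idx = np.searchsorted(self.c_values, rng.uniform(size=n), side="left")
        c_star = self.c_knots[np.minimum(idx, self.c_knots.size - 1)]
        y_star = np.minimum(t_star, c_star)
        d_star = (t_star <= c_star).astype(int)
        return SurvivalSample(times=y_star, events=d_star)

    def bootstrap_statistics(self, rng: np.random.Generator) -> np.ndarray:
        """B centred statistics ``n^{2/5} (f*_SG(tauG) - f~_{n h0}(tauG))``."""
        cfg = self.config
        out = np.empty(cfg.B)
        scale = self.sample.n ** 0.4
        for b in range(cfg.B):
            boot = self.draw_sample(rng)
            Fb = survcore.km_distribution(boot)
            maj = survcore.lcm(Fb, (cfg.region_start, self.tau_g))
            dens = survcore.grenander_density(maj)
            f_star = smoothing.smoothed_grenander_endpoint(
                dens, cfg.kernel, self.h, self.tau_g
            )
            out[b] = scale * (f_star - self.ftil_tau_g)
        return out


def smoothed_bootstrap(sample: SurvivalSample, config: TestConfig) -> np.ndarray:
    """Smoothed-bootstrap sample of the centred endpoint statistic.

    Bootstrap data regeneration: uncured mass ``p* = F_n(tauG)``; uncured
    event times drawn from the oversmoothed density restricted to
    ``[0, tauG]`` (inverse CDF on a grid), cured subjects have infinite
    event time; censoring times drawn from the product-limit estimate of G
    with its point mass at the largest observed time.  Each bootstrap
    sample is smoothed with the *same* ``h`` and ``tauG`` as the original.
    """
    machinery = _SmoothedMachinery(sample, config)
    rng = np.random.default_rng(config.seed)
    return machinery.bootstrap_statistics(rng)


def smoothed_test(sample: SurvivalSample, config: TestConfig) -> TestResult:
    """Smoothed-Grenander test with smoothed-bootstrap critical values.

    Rejects insufficient follow-up when the boundary-kernel smoothed
    Grenander estimate at ``tauG`` falls below
    ``eps F_n(tauG)/(tau - tauG) + n^{-2/5} Q*_alpha`` where ``Q*_alpha``
    is the alpha-quantile of the bootstrap statistics.  The p-value is the
    empirical-CDF inversion of the rule (ties counted inclusively, the
    conservative direction).
    """
    machinery = _SmoothedMachinery(sample, config)
    rng = np.random.default_rng(config.seed)
    w = machinery.bootstrap_statistics(rng)
    n = sample.n
    f_bound = config.epsilon * machinery.F(machinery.tau_g) / (
        config.tau - machinery.tau_g
    )
    t_scaled = n ** 0.4 * (machinery.statistic - f_bound)
    p_value = float(np.mean(w <= t_scaled))
    q_alpha = float(np.quantile(w, config.alpha))
    threshold = f_bound + n ** (-0.4) * q_alpha
    return TestResult(
        method="smoothed",
        statistic=machinery.statistic,
        threshold=threshold,
        p_value=p_value,
        reject=p_value < config.alpha,
        diagnostics={
            "tau_g": machinery.tau_g, "n": n, "h": machinery.h,
            "h0": machinery.h0, "F_n_tau_g": machinery.F(machinery.tau_g),
            "censoring_mass": 1.0 - machinery.G.left_limit(machinery.tau_g),
            "density_bound": f_bound, "ftil_tau_g": machinery.ftil_tau_g,
            "bootstrap_quantile": q_alpha, "B": config.B,
            "p_star": machinery.p_star,
        },
    )


def run_all_tests(
    sample: SurvivalSample,
    config: TestConfig,
    table: SlopeQuantileTable | None = None,
) -> list[TestResult]:
    """Run the smoothed, Grenander and alpha_n tests on one sample."""
    return [
        smoothed_test(sample, config),
        grenander_test(sample, config, table),
        alpha_n_test(sample, config),
    ]
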