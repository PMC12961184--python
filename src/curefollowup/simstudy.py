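"""Mixture-cure data generators and the rejection-rate experiment runner.

Seven canonical settings probe the follow-up tests across uncured-time
families (exponential, Weibull, truncated exponential, log-normal
mixture), censoring mechanisms (uniform with a controllable point mass at
the end of follow-up, exponential drop-out) and uncured fractions.  Study
ends ``tauG`` are placed on a grid of upper quantiles of the uncured law,
so that the distance from the practical-sufficiency boundary (the
``1 - epsilon`` quantile) is controlled directly on the probability scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import lognorm

from .exceptions import DegenerateDensityError, InvalidInputError
from .sftest import TestConfig, alpha_n_test, grenander_test, smoothed_test
from .survcore import SurvivalSample

__all__ = [
    "Exponential",
    "Weibull",
    "TruncatedExponential",
    "LogNormalMixture",
    "SettingSpec",
    "QuantileGrid",
    "make_setting",
    "uncured_quantile",
    "censor_mass_uniform",
    "generate_sample",
    "quantile_grid",
    "rejection_rate",
]


@dataclass(frozen=True)
class Exponential:
    rate: float

    def cdf(self, t):
        return 1.0 - np.exp(-self.rate * np.asarray(t, dtype=float))

    def quantile(self, p: float) -> float:
        return -math.log1p(-p) / self.rate

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.exponential(1.0 / self.rate, size=size)


@dataclass(frozen=True)
class Weibull:
    shape: float
    scale: float

    def cdf(self, t):
        return 1.0 - np.exp(-((np.asarray(t, dtype=float) / self.scale) ** self.shape))

    def quantile(self, p: float) -> float:
        return self.scale * (-math.log1p(-p)) ** (1.0 / self.shape)

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.scale * rng.weibull(self.shape, size=size)


@dataclass(frozen=True)
class TruncatedExponential:
    """Exponential distribution conditioned on ``[0, endpoint]``."""

    rate: float
    endpoint: float

    @property
    def _norm(self) -> float:
        return -math.expm1(-self.rate * self.endpoint)

    def cdf(self, t):
        t = np.clip(np.asarray(t, dtype=float), 0.0, self.endpoint)
        return -np.expm1(-self.rate * t) / self._norm

    def quantile(self, p: float) -> float:
        return -math.log1p(-p * self._norm) / self.rate

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.uniform(size=size)
        return -np.log1p(-u * self._norm) / self.rate


@dataclass(frozen=True)
class LogNormalMixture:
    """Two-component log-normal mixture; the second, late mode breaks the
    nonincreasing-tail-density assumption on purpose."""

    weight: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float

    def _components(self):
        return (
            lognorm(s=self.sigma1, scale=math.exp(self.mu1)),
            lognorm(s=self.sigma2, scale=math.exp(self.mu2)),
        )

    def cdf(self, t):
        c1, c2 = self._components()
        t = np.asarray(t, dtype=float)
        return self.weight * c1.cdf(t) + (1 - self.weight) * c2.cdf(t)

    def quantile(self, p: float) -> float:
        c1, c2 = self._components()
        hi = max(c1.ppf(p), c2.ppf(p)) + 1.0
        return float(brentq(lambda t: self.cdf(t) - p, 0.0, hi, xtol=1e-12))

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        comp = rng.uniform(size=size) < self.weight
        out = np.empty(size)
        out[comp] = rng.lognormal(self.mu1, self.sigma1, size=int(comp.sum()))
        out[~comp] = rng.lognormal(self.mu2, self.sigma2, size=int((~comp).sum()))
        return out


@dataclass(frozen=True)
class SettingSpec:
    """One simulation scenario: uncured fraction, uncured event-time law
    and censoring mechanism.

    ``censor_uniform_delta`` selects the uniform censoring law with point
    mass ``Delta_G`` at ``tauG``; ``censor_exp_rate`` an exponential one.
    ``truncate`` applies administrative censoring ``C = min(C~, tauG)``.
    """

    id: int
    p: float
    uncured: object
    censor_uniform_delta: Optional[float] = None
    censor_exp_rate: Optional[float] = None
    truncate: bool = True
    tau_g_fixed: Optional[float] = None
    extended_grid: bool = False

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise InvalidInputError("uncured fraction p must lie in (0, 1)")
        if (self.censor_uniform_delta is None) == (self.censor_exp_rate is None):
            raise InvalidInputError("exactly one censoring law must be set")


def make_setting(
    id: int,
    p: float = 0.6,
    delta_g: float = 0.02,
    lam: float = 1.0,
    lam_c: float = 0.5,
) -> SettingSpec:
    """Factory for the seven canonical simulation settings.

    1: Exp(1) uncured, uniform censoring with mass ``delta_g`` at tauG.
    2: Exp(lam) uncured, Exp(0.5) censoring truncated at tauG.
    3: Weibull(0.5, 1.5) uncured (fast-decreasing density), uniform censoring.
    4: truncated Exp(1) on [0, 99% quantile of Exp(1)], uniform censoring.
    5: truncated Exp(5) on [0, 99% quantile of Exp(5)], Exp(lam_c) censoring.
    6: Exp(1) uncured, Exp(0.5) censoring, no truncation (tauG infinite).
    7: log-normal mixture (nonmonotone tail density), uniform censoring
       with mass 0.02 at the fixed tauG = 6.5, p = 0.6.
    """
    if id == 1:
        return SettingSpec(id=1, p=p, uncured=Exponential(1.0),
                           censor_uniform_delta=delta_g)
    if id == 2:
        return SettingSpec(id=2, p=p, uncured=Exponential(lam),
                           censor_exp_rate=0.5)
    if id == 3:
        return SettingSpec(id=3, p=p, uncured=Weibull(0.5, 1.5),
                           censor_uniform_delta=delta_g)
    if id == 4:
        law = Exponential(1.0)
        return SettingSpec(id=4, p=p,
                           uncured=TruncatedExponential(1.0, law.quantile(0.99)),
                           censor_uniform_delta=delta_g, extended_grid=True)
    if id == 5:
        law = Exponential(5.0)
        return SettingSpec(id=5, p=p,
                           uncured=TruncatedExponential(5.0, law.quantile(0.99)),
                           censor_exp_rate=lam_c, extended_grid=True)
    if id == 6:
        return SettingSpec(id=6, p=p, uncured=Exponential(1.0),
                           censor_exp_rate=0.5, truncate=False,
                           tau_g_fixed=math.inf)
    if id == 7:
        return SettingSpec(id=7, p=0.6,
                           uncured=LogNormalMixture(0.7, 0.0, 1.0, math.log(8), 0.3),
                           censor_uniform_delta=0.02, tau_g_fixed=6.5)
    raise InvalidInputError(f"unknown setting id {id}")


def uncured_quantile(spec: SettingSpec, prob: float) -> float:
    """Quantile of the uncured event-time law (closed form where it
    exists, numeric root for the log-normal mixture)."""
    if not 0 < prob < 1:
        raise InvalidInputError("prob must lie in (0, 1)")
    return float(spec.uncured.quantile(prob))


def censor_mass_uniform(tauG: float, deltaG: float) -> float:
    """Upper endpoint ``zeta`` of the uniform pre-censoring law.

    With ``C~ ~ U[0, zeta]`` and ``C = min(C~, tauG)``, choosing
    ``zeta = tauG / (1 - deltaG)`` puts point mass ``deltaG`` at ``tauG``.
    """
    if tauG <= 0:
        raise InvalidInputError("tauG must be positive")
    if not 0 <= deltaG < 1:
        raise InvalidInputError("deltaG must lie in [0, 1)")
    return tauG / (1.0 - deltaG)


def generate_sample(
    spec: SettingSpec, tauG: float, n: int, seed
) -> SurvivalSample:
    """Draw one mixture-cure sample of size ``n``.

    Cure status ``B ~ Bernoulli(p)``; uncured event times from the
    setting's law (cured times are infinite); censoring ``C = min(C~,
    tauG)`` when the setting truncates, ``C = C~`` otherwise.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    uncured = rng.uniform(size=n) < spec.p
    t = np.full(n, np.inf)
    t[uncured] = spec.uncured.rvs(rng, int(uncured.sum()))
    if spec.censor_uniform_delta is not None:
        zeta = censor_mass_uniform(tauG, spec.censor_uniform_delta)
        c_tilde = rng.uniform(0.0, zeta, size=n)
    else:
        c_tilde = rng.exponential(1.0 / spec.censor_exp_rate, size=n)
    if spec.truncate and math.isfinite(tauG):
        c = np.minimum(c_tilde, tauG)
    else:
        c = c_tilde
    y = np.minimum(t, c)
    d = (t <= c).astype(int)
    return SurvivalSample(times=y, events=d)


@dataclass(frozen=True)
class QuantileGrid:
    """Labelled grid of candidate study ends on the uncured quantile scale."""

    labels: tuple
    values: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.values))


def quantile_grid(spec: SettingSpec, extended: bool = False) -> QuantileGrid:
    """The twelve standard ``tauG`` positions (plus seven beyond-support
    extras for the truncated settings).

    q1-q4, q6, q12 are the 90, 92.5, 95, 97.5, 99 and 99.9 percent
    quantiles of the uncured law; q5 is the midpoint of q4 and q6; q7-q11
    are evenly spaced between q6 and q12 on the time scale.  Extras
    q13-q19 run evenly from the (finite) support endpoint to the 99.9
    percent quantile of the corresponding untruncated law.
    """
    q = uncured_quantile
    q1, q2, q3, q4 = (q(spec, pr) for pr in (0.90, 0.925, 0.95, 0.975))
    q6 = q(spec, 0.99)
    q12 = q(spec, 0.999)
    q5 = 0.5 * (q4 + q6)
    mids = [q6 + j * (q12 - q6) / 6 for j in range(1, 6)]
    labels = [f"q{i}" for i in range(1, 13)]
    values = [q1, q2, q3, q4, q5, q6, *mids, q12]
    if extended:
        if not isinstance(spec.uncured, TruncatedExponential):
            raise InvalidInputError(
                "extended grid is defined for the truncated settings only"
            )
        upper = Exponential(spec.uncured.rate).quantile(0.999)
        extras = np.linspace(spec.uncured.endpoint, upper, 7)
        labels += [f"q{i}" for i in range(13, 20)]
        values = [*values, *extras]
    return QuantileGrid(labels=tuple(labels), values=np.array(values))


def rejection_rate(
    spec: SettingSpec,
    tauG: float,
    test: str,
    n: int,
    reps: int,
    config: TestConfig,
    seed: int,
    table=None,
) -> float:
    """Empirical rejection rate of insufficient follow-up over seeded
    replicates.

    Replicate seeds are spawned from the master seed with a counter-based
    sequence, so replicates are reproducible independently of execution
    order.  ``config.tau_g`` is set to the known ``tauG`` except in the
    infinite-follow-up setting, where it is estimated by the largest
    observed time and, when ``config.tau`` is unset, the horizon defaults
    to 1.5 times that maximum.  A degenerate Grenander plug-in (zero
    estimated density at the evaluation point) counts as a rejection: it
    is the limit of the rejection rule as the density estimate vanishes.
    """
    if reps < 1:
        raise InvalidInputError("reps must be >= 1")
    if test not in ("smoothed", "grenander", "alphan"):
        raise InvalidInputError(f"unknown test {test!r}")
    children = np.random.SeedSequence(seed).spawn(reps)
    known_tau_g = None if spec.id == 6 else tauG
    rejections = 0
    for child in children:
        data_seed, test_seed = child.spawn(2)
        sample = generate_sample(spec, tauG, n=n, seed=data_seed)
        cfg = replace(
            config,
            seed=int(test_seed.generate_state(1)[0] % (2**31)),
            tau_g=known_tau_g,
        )
        if spec.id == 6 and config.tau is None:
            cfg = replace(cfg, tau=1.5 * sample.y_max)
        try:
            if test == "smoothed":
                result = smoothed_test(sample, cfg)
            elif test == "grenander":
                result = grenander_test(sample, cfg, table)
            else:
                result = alpha_n_test(sample, cfg)
            rejections += int(result.reject)
        except DegenerateDensityError:
            rejections += 1
    return rejections / reps
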