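"""Circular descriptive statistics and hypothesis tests.

Implements the descriptive summary (mean direction, mean resultant
length), the Rayleigh test of uniformity, the Mardia–Watson–Wheeler
(uniform-scores) two-sample test, and confidence intervals for the mean
direction of a circular sample. Directions are degrees clockwise from
North in [0, 360).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .angles import normalize_angle

__all__ = [
    "CircSummary",
    "RayleighResult",
    "MWWResult",
    "DirectionCI",
    "circ_mean_r",
    "rayleigh_test",
    "rayleigh_test_angles",
    "rayleigh_critical_r",
    "mean_direction_ci",
    "mww_test",
]


@dataclass(frozen=True)
class CircSummary:
    """Descriptive summary of a circular sample.

    Attributes
    ----------
    n : int
        Sample size.
    mean_direction : float or nan
        Mean direction alpha in degrees, undefined (nan) when r == 0.
    r : float
        Mean resultant length in [0, 1]; 0 = uniform, 1 = concentrated.
    """

    n: int
    mean_direction: float
    r: float


@dataclass(frozen=True)
class RayleighResult:
    n: int
    r: float
    Z: float
    p: float


@dataclass(frozen=True)
class MWWResult:
    W: float
    p: float
    n1: int
    n2: int


@dataclass(frozen=True)
class DirectionCI:
    level: float
    lower: float
    upper: float
    method: str

    def halfwidth(self) -> float:
        """Half the clockwise arc from lower to upper, degrees."""
        arc = (self.upper - self.lower) % 360.0
        return arc / 2.0

    def contains(self, angle: float) -> bool:
        """Whether ``angle`` lies on the clockwise arc lower -> upper."""
        a = (normalize_angle(angle) - self.lower) % 360.0
        arc = (self.upper - self.lower) % 360.0
        return a <= arc


def _to_radians(angles) -> np.ndarray:
    arr = np.asarray(angles, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError("empty circular sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite angle in sample")
    return np.deg2rad(arr)


def circ_mean_r(angles) -> CircSummary:
    """Circular mean direction and mean resultant length.

    The resultant of n unit vectors has length ``n*r``; the mean
    direction is its angle. When r is numerically zero the mean
    direction is undefined and reported as nan.
    """
    th = _to_radians(angles)
    C, S = np.sum(np.cos(th)), np.sum(np.sin(th))
    n = th.size
    r = float(np.hypot(C, S) / n)
    if r < 1e-12:
        alpha = float("nan")
        r = 0.0 if r < 1e-15 else r
    else:
        alpha = normalize_angle(np.rad2deg(np.arctan2(S, C)))
    return CircSummary(n=int(n), mean_direction=alpha, r=min(r, 1.0))


def rayleigh_test(n: int, r: float) -> RayleighResult:
    """Rayleigh test of circular uniformity from summary statistics.

    The statistic is Z = n*r^2 and the p-value uses the standard
    large-sample series approximation

        p = exp(-Z) * [1 + (2Z - Z^2)/(4n)
                         - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)],

    clipped into (0, 1]. Accurate to ~3 decimals for n >= 10 and
    adequate for the sample sizes of funnel experiments.
    """
    if n < 2:
        raise ValueError("Rayleigh test requires n >= 2")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0,1], got {r}")
    Z = n * r * r
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z**2) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n**2)
    )
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return RayleighResult(n=int(n), r=float(r), Z=float(Z), p=p)


def rayleigh_test_angles(angles) -> RayleighResult:
    """Rayleigh test computed directly from a sample of directions."""
    s = circ_mean_r(angles)
    return rayleigh_test(s.n, s.r)


def rayleigh_critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest mean resultant length significant at level ``alpha``.

    Root-found on the same approximation as :func:`rayleigh_test`; this
    is the radius of the dashed significance circles drawn on circular
    diagrams of group orientation data.
    """
    if n < 2:
        raise ValueError("requires n >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha in (0,1) required")

    def f(r: float) -> float:
        return rayleigh_test(n, r).p - alpha

    return float(optimize.brentq(f, 1e-9, 0.999999, xtol=1e-10))


def _percentile_arc(center_deg: float, deviations_deg: np.ndarray, level: float):
    lo, hi = np.percentile(deviations_deg, [50 * (1 - level), 50 + 50 * level])
    return normalize_angle(center_deg + lo), normalize_angle(center_deg + hi)


def mean_direction_ci(
    angles,
    level: float = 0.95,
    method: str = "bootstrap",
    B: int = 10_000,
    seed: int | None = None,
) -> DirectionCI:
    """Confidence arc for the mean direction of a circular sample.

    Parameters
    ----------
    angles : array-like of degrees
    level : confidence level (default 0.95)
    method : {"bootstrap", "dispersion"}
        ``bootstrap``: percentile arc of resampled mean directions,
        expressed as signed deviations from the sample mean (seeded,
        reproducible). ``dispersion``: classical normal-approximation
        arc, mu +- asin(z * sqrt(delta_hat / n)) with delta_hat the
        sample circular dispersion.
    B : bootstrap replicates.
    seed : RNG seed for the bootstrap.

    The sample must have a defined mean direction (r > 0); the caller
    is responsible for only interpreting the arc on significantly
    oriented samples.
    """
    th = _to_radians(angles)
    n = th.size
    summ = circ_mean_r(np.rad2deg(th))
    if summ.r == 0.0:
        raise ValueError("mean direction undefined (r = 0)")
    mu = summ.mean_direction

    if method == "bootstrap":
        if n < 5:
            warnings.warn("bootstrap CI unreliable for n < 5", stacklevel=2)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(B, n))
        C = np.cos(th)[idx].sum(axis=1)
        S = np.sin(th)[idx].sum(axis=1)
        means = np.rad2deg(np.arctan2(S, C))
        dev = (means - mu + 180.0) % 360.0 - 180.0
        lower, upper = _percentile_arc(mu, dev, level)
        return DirectionCI(level=level, lower=lower, upper=upper, method=method)

    if method == "dispersion":
        # Circular dispersion delta = (1 - rho2) / (2 r^2), rho2 the
        # second trigonometric moment about the mean direction.
        mu_rad = np.deg2rad(mu)
        rho2 = float(np.mean(np.cos(2.0 * (th - mu_rad))))
        r = summ.r
        delta = (1.0 - rho2) / (2.0 * r * r)
        se = np.sqrt(delta / n)
        z = stats.norm.ppf(0.5 + level / 2.0)
        arg = z * se
        if arg >= 1.0:
            # Dispersion too large for the normal-approximation arc.
            return DirectionCI(
                level=level,
                lower=normalize_angle(mu - 180.0),
                upper=normalize_angle(mu + 180.0),
                method=method,
            )
        half = np.rad2deg(np.arcsin(arg))
        return DirectionCI(
            level=level,
            lower=normalize_angle(mu - half),
            upper=normalize_angle(mu + half),
            method=method,
        )

    raise ValueError(f"unknown method {method!r}")


def mww_statistic(sample1, sample2) -> float:
    """Mardia–Watson–Wheeler uniform-scores statistic W.

    Pooled circular ranks are converted to uniform scores
    beta_i = 2*pi*R_i/N; W = 2 * sum_k (C_k^2 + S_k^2)/n_k with C_k, S_k
    the within-sample sums of cos/sin of the scores. Ties receive
    mid-ranks.
    """
    a1 = np.asarray(sample1, dtype=float)
    a2 = np.asarray(sample2, dtype=float)
    pooled = np.concatenate([a1, a2]) % 360.0
    N = pooled.size
    ranks = stats.rankdata(pooled, method="average")
    if np.unique(pooled).size < N:
        warnings.warn(
            "ties in pooled circular sample; uniform-scores test assumes "
            "continuous data (mid-ranks used)",
            stacklevel=2,
        )
    beta = 2.0 * np.pi * ranks / N
    W = 0.0
    offset = 0
    for a in (a1, a2):
        b = beta[offset : offset + a.size]
        W += (np.sum(np.cos(b)) ** 2 + np.sum(np.sin(b)) ** 2) / a.size
        offset += a.size
    return float(2.0 * W)


def mww_test(sample1, sample2) -> MWWResult:
    """Mardia–Watson–Wheeler two-sample test on circular data.

    Nonparametric test of a common underlying circular distribution;
    the large-sample null of W is chi-square with 2 df, so
    p = exp(-W/2). Invariant under a common rotation of both samples
    and under exchanging the samples.
    """
    n1, n2 = len(sample1), len(sample2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if n1 + n2 < 17:
        warnings.warn(
            "pooled n < 17: chi-square approximation to W is nominal only "
            "for larger samples",
            stacklevel=2,
        )
    W = mww_statistic(sample1, sample2)
    p = float(stats.chi2.sf(W, df=2))
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return MWWResult(W=W, p=p, n1=n1, n2=n2)
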