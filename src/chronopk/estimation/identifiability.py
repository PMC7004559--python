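"""Identifiability diagnostics: Sobol sensitivity and likelihood profiles.

A parameter that the cost function is insensitive to cannot be estimated
from the data, so a global variance decomposition of the cost over the
parameter box is used as a necessary screening condition (parameters whose
total-order index falls below a threshold are flagged non-identifiable and
are candidates for fixing or constraining).  Practical identifiability of
the remaining parameters is probed with likelihood profiles: each parameter
is swept over a grid while all others are re-optimized; a flat profile
marks a practically non-identifiable direction, and the threshold crossing
of the profile defines a confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from chronopk.estimation.cmaes import fmin_cmaes

__all__ = [
    "SobolResult",
    "sobol_sensitivity",
    "ProfilePoint",
    "ProfileResult",
    "likelihood_profile",
    "SOBOL_NONIDENTIFIABLE_TOTAL",
]

#: Total-order index below which a parameter is reported non-identifiable.
SOBOL_NONIDENTIFIABLE_TOTAL = 0.01

#: Cost increase defining the profile confidence interval (chi-square, 1 dof, 95%).
PROFILE_THRESHOLD = 3.84


@dataclass(frozen=True)
class SobolResult:
    names: tuple[str, ...]
    first_order: dict[str, float]
    total: dict[str, float]
    non_identifiable: tuple[str, ...]
    n_samples: int


def sobol_sensitivity(
    func: Callable[[Mapping[str, float]], float],
    bounds: Mapping[str, tuple[float, float]],
    n_samples: int = 256,
    seed: int = 0,
    log_scale: bool = True,
    threshold: float = SOBOL_NONIDENTIFIABLE_TOTAL,
) -> SobolResult:
    """First-order and total Sobol indices of ``func`` over a parameter box.

    Saltelli-type sampling (``n * (d + 2)`` evaluations, ``n_samples`` a
    power of two) with parameters drawn uniformly over the box — in log10
    coordinates by default, matching the log-space search of the fitter.
    """
    names = tuple(bounds)
    if any(hi <= lo for lo, hi in bounds.values()):
        raise ValueError("degenerate bounds")
    if n_samples & (n_samples - 1):
        raise ValueError("n_samples must be a power of two")
    if log_scale:
        lows = np.array([math.log10(bounds[n][0]) for n in names])
        highs = np.array([math.log10(bounds[n][1]) for n in names])
    else:
        lows = np.array([bounds[n][0] for n in names])
        highs = np.array([bounds[n][1] for n in names])

    def vectorized(x: np.ndarray) -> np.ndarray:
        # x: (d, n) in the unit/box coordinates handed out by the sampler
        out = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            vals = x[:, j]
            if log_scale:
                vals = 10.0**vals
            out[j] = func(dict(zip(names, vals)))
        return out

    dists = [stats.uniform(loc=lo, scale=hi - lo) for lo, hi in zip(lows, highs)]
    res = stats.sobol_indices(
        func=vectorized, n=n_samples, dists=dists, rng=np.random.default_rng(seed)
    )
    first = dict(zip(names, np.atleast_2d(res.first_order)[0]))
    total = dict(zip(names, np.atleast_2d(res.total_order)[0]))
    flagged = tuple(n for n in names if total[n] < threshold)
    return SobolResult(names=names, first_order=first, total=total,
                       non_identifiable=flagged, n_samples=n_samples)


@dataclass(frozen=True)
class ProfilePoint:
    value: float
    cost: float
    nuisance: dict[str, float]
    failed: bool = False


@dataclass(frozen=True)
class ProfileResult:
    parameter: str
    points: tuple[ProfilePoint, ...]
    min_cost: float
    confidence_interval: tuple[float, float]   # grid range with cost <= min + threshold
    identifiable: bool
    threshold: float

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.points])

    @property
    def costs(self) -> np.ndarray:
        return np.array([p.cost for p in self.points])


def likelihood_profile(
    cost: Callable[[Mapping[str, float]], float],
    parameter: str,
    grid: Sequence[float],
    nuisance_bounds: Mapping[str, tuple[float, float]],
    seed: int = 0,
    max_iter: int = 120,
    threshold: float = PROFILE_THRESHOLD,
) -> ProfileResult:
    """Profile ``cost`` along ``parameter``, re-optimizing all other parameters.

    ``cost`` takes the full parameter dict; ``nuisance_bounds`` define the
    log-space box for the re-optimized parameters (may be empty for a
    one-parameter problem).  Optimizer failures at grid points are recorded,
    not dropped.  A profile whose excursion above its minimum never exceeds
    ``threshold`` is flagged practically non-identifiable.
    """
    nuisance = tuple(nuisance_bounds)
    points: list[ProfilePoint] = []
    for gi, value in enumerate(grid):
        if not nuisance:
            try:
                c = float(cost({parameter: float(value)}))
                points.append(ProfilePoint(float(value), c, {}))
            except Exception:
                points.append(ProfilePoint(float(value), math.inf, {}, failed=True))
            continue
        log_lo = np.array([math.log10(nuisance_bounds[n][0]) for n in nuisance])
        log_hi = np.array([math.log10(nuisance_bounds[n][1]) for n in nuisance])

        def inner(z: np.ndarray) -> float:
            barrier = float(np.sum(np.maximum(z - log_hi, 0.0) ** 2 + np.maximum(log_lo - z, 0.0) ** 2))
            zc = np.clip(z, log_lo, log_hi)
            full = {parameter: float(value)}
            full.update({n: 10.0**v for n, v in zip(nuisance, zc)})
            try:
                return float(cost(full)) + 1e3 * barrier
            except Exception:
                return math.inf
        try:
            opt = fmin_cmaes(inner, (log_lo + log_hi) / 2.0, 0.5,
                             seed=seed + gi, max_iter=max_iter, ftol=1e-10)
            zb = np.clip(opt.xbest, log_lo, log_hi)
            points.append(ProfilePoint(
                float(value), float(opt.fbest),
                {n: float(10.0**v) for n, v in zip(nuisance, zb)},
                failed=not np.isfinite(opt.fbest),
            ))
        except Exception:
            points.append(ProfilePoint(float(value), math.inf, {}, failed=True))

    finite = [p for p in points if np.isfinite(p.cost)]
    if not finite:
        raise RuntimeError(f"profile of {parameter}: optimizer failed at every grid point")
    cmin = min(p.cost for p in finite)
    inside = [p.value for p in finite if p.cost <= cmin + threshold]
    ci = (min(inside), max(inside))
    excursion = max(p.cost for p in finite) - cmin
    return ProfileResult(
        parameter=parameter, points=tuple(points), min_cost=cmin,
        confidence_interval=ci, identifiable=excursion > threshold,
        threshold=threshold,
    )
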