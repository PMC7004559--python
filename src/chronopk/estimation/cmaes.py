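"""Covariance matrix adaptation evolution strategy (CMA-ES).

A self-contained (mu/mu_w, lambda) CMA-ES minimizer with cumulative step-size
adaptation and rank-one plus rank-mu covariance updates, following Hansen's
standard formulation.  Derivative-free and invariant to order-preserving
transformations of the objective, it is well suited to the rugged weighted
least-squares landscapes of compartmental PK fitting, where it is run in
log-parameter space.

Deterministic for a fixed seed: all sampling goes through a single
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["CMAESResult", "fmin_cmaes"]


@dataclass
class CMAESResult:
    xbest: np.ndarray
    fbest: float
    n_evaluations: int
    n_iterations: int
    converged: bool
    stop_reason: str
    seed: int
    trace: list[float] = field(default_factory=list)  # best f per iteration


def fmin_cmaes(
    func: Callable[[np.ndarray], float],
    x0: Sequence[float],
    sigma0: float,
    seed: int = 0,
    popsize: int | None = None,
    max_iter: int = 500,
    ftol: float = 1e-12,
    xtol: float = 1e-11,
    f_target: float | None = None,
) -> CMAESResult:
    """Minimize ``func`` starting from ``x0`` with initial step size ``sigma0``.

    ``popsize`` defaults to ``4 + floor(3 ln n)``.  Stops on ``max_iter``,
    when the spread of recent best values falls below ``ftol``, when the
    search distribution collapses (``sigma * max(diag C) < xtol``), or when
    ``f_target`` is reached.  Non-finite objective values are treated as
    +inf (optimizer-safe).
    """
    rng = np.random.default_rng(seed)
    xmean = np.asarray(x0, dtype=float).copy()
    n = xmean.size
    sigma = float(sigma0)

    lam = popsize if popsize is not None else 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    eigen_stale = 0

    fbest = np.inf
    xbest = xmean.copy()
    trace: list[float] = []
    n_eval = 0
    hist: list[float] = []
    stop = "max_iter"
    converged = False

    for it in range(max_iter):
        z = rng.standard_normal((lam, n))
        y = z * D @ B.T                       # y_k = B D z_k, rows
        xs = xmean + sigma * y
        fs = np.empty(lam)
        for k in range(lam):
            fk = func(xs[k])
            fs[k] = fk if np.isfinite(fk) else np.inf
        n_eval += lam
        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < fbest:
            fbest = float(fs[order[0]])
            xbest = xs[order[0]].copy()
        trace.append(fbest)

        ysel = y[order[:mu]]
        ybar = w @ ysel
        xmean = xmean + sigma * ybar

        # step-size path (in the isotropic coordinate system)
        c_inv_half_y = (ybar @ B) / D @ B.T
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * c_inv_half_y
        hsig = np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (it + 1))) / chi_n < 1.4 + 2 / (n + 1)
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * ybar

        # covariance update: rank-one + rank-mu
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
            + cmu * (ysel.T * w) @ ysel
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))

        eigen_stale += lam
        if eigen_stale > lam / ((c1 + cmu) * n * 10):
            eigen_stale = 0
            C = (C + C.T) / 2
            Dsq, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(Dsq, 1e-30))

        hist.append(float(fs[order[0]]))
        if f_target is not None and fbest <= f_target:
            stop, converged = "f_target", True
            break
        if len(hist) > 10 + int(30 * n / lam):
            hist.pop(0)
            if max(hist) - min(hist) < ftol:
                stop, converged = "ftol", True
                break
        if sigma * max(D) < xtol:
            stop, converged = "xtol", True
            break
        if not np.isfinite(fbest) and it > 50:
            stop = "no_feasible_point"
            break

    return CMAESResult(
        xbest=xbest, fbest=float(fbest), n_evaluations=n_eval,
        n_iterations=it + 1, converged=converged, stop_reason=stop,
        seed=seed, trace=trace,
    )
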