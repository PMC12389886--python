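"""Minimal expected-improvement Bayesian optimisation over an integer box.

Gaussian-process surrogate (Matern 5/2) on inputs rescaled to the unit
square; candidates are drawn uniformly from the box and scored by
expected improvement.  Deterministic given the seed.  Sufficient for
low-dimensional hyperparameter search (tens of evaluations over two
integer ranges).
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


def maximize_ei(
    objective: Callable[[int, int], float],
    bounds: tuple[tuple[int, int], tuple[int, int]],
    n_iterations: int,
    seed: int,
    n_initial: int = 8,
    n_candidates: int = 512,
) -> tuple[tuple[int, int], float, list[tuple[int, int, float]]]:
    """Maximise ``objective`` over the integer box ``bounds``.

    Returns ``((x1*, x2*), best_value, history)`` where history holds
    every evaluated ``(x1, x2, value)``.  ``n_iterations`` is the total
    evaluation budget including the initial design.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    rng = np.random.default_rng(seed)
    (lo1, hi1), (lo2, hi2) = bounds
    span = np.array([max(hi1 - lo1, 1), max(hi2 - lo2, 1)], dtype=float)
    lo = np.array([lo1, lo2], dtype=float)

    def draw(n: int) -> np.ndarray:
        return np.column_stack(
            [rng.integers(lo1, hi1 + 1, size=n), rng.integers(lo2, hi2 + 1, size=n)]
        )

    seen: dict[tuple[int, int], float] = {}
    history: list[tuple[int, int, float]] = []

    def evaluate(pt: np.ndarray) -> None:
        key = (int(pt[0]), int(pt[1]))
        if key not in seen:
            seen[key] = float(objective(*key))
            history.append((key[0], key[1], seen[key]))

    for pt in draw(min(n_initial, n_iterations)):
        evaluate(pt)

    kernel = ConstantKernel(1.0) * Matern(length_scale=[0.3, 0.3], nu=2.5) + WhiteKernel(
        1e-6, noise_level_bounds=(1e-10, 1e-1)
    )
    while len(history) < n_iterations:
        X = (np.array([(h[0], h[1]) for h in history]) - lo) / span
        y = np.array([h[2] for h in history])
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP convergence chatter on flat objectives
            gp.fit(X, y)
        cand = draw(n_candidates)
        cand = cand[[tuple(c) not in seen for c in cand]]
        if cand.size == 0:
            break  # box exhausted
        mu, sigma = gp.predict((cand - lo) / span, return_std=True)
        best = y.max()
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best) / sigma
        ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
        evaluate(cand[int(np.argmax(ei))])

    x1, x2, val = max(history, key=lambda h: (h[2], -h[0], -h[1]))
    return (x1, x2), val, history
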