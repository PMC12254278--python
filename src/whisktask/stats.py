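"""Circular statistics helpers.

Contains the Kuiper one-sample test of circular uniformity (the rotation-
invariant analogue of the Kolmogorov-Smirnov test) used to assess whisking
phase tuning, and the circular mean.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kuiper_statistic", "kuiper_p", "kuiper_test", "circular_mean"]


def kuiper_statistic(samples: np.ndarray) -> float:
    """Kuiper V = D+ + D- of samples on [0, 1) against the uniform CDF."""
    u = np.sort(np.asarray(samples, dtype=float))
    n = u.size
    if n == 0:
        raise ValueError("need at least one sample")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(d_plus + d_minus)


def kuiper_p(v: float, n: int, n_terms: int = 100) -> float:
    """Asymptotic upper-tail probability of Kuiper's V with the standard
    finite-sample correction (Stephens 1970)."""
    if n < 1:
        raise ValueError("n must be positive")
    lam = (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n)) * v
    if lam < 0.4:
        return 1.0
    k = np.arange(1, n_terms + 1)
    terms = (4.0 * k**2 * lam**2 - 1.0) * np.exp(-2.0 * k**2 * lam**2)
    return float(min(1.0, max(0.0, 2.0 * np.sum(terms))))


def kuiper_test(angles: np.ndarray) -> tuple[float, float]:
    """(V, p) of circular samples in radians against the uniform circle."""
    angles = np.asarray(angles, dtype=float)
    u = np.mod(angles, 2 * np.pi) / (2 * np.pi)
    v = kuiper_statistic(u)
    return v, kuiper_p(v, u.size)


def circular_mean(
    angles: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """(mean angle in [0, 2*pi), resultant length in [0, 1])."""
    angles = np.asarray(angles, dtype=float)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, dtype=float)
    if angles.size == 0 or w.sum() == 0:
        raise ValueError("need at least one weighted angle")
    z = np.sum(w * np.exp(1j * angles)) / w.sum()
    return float(np.mod(np.angle(z), 2 * np.pi)), float(np.abs(z))
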