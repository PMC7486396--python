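"""Rank-size statistics and information measures for city-size structures.

The Zipf reference distribution assigns share ``x_r = (1/r) / H(n)`` to the
city of rank ``r`` (``H`` the harmonic number): the largest city is twice the
second, three times the third, and so on.  Departures of an observed
structure from this reference are measured in bits — pointwise as the
surprise ``log2(P/P_z)`` and in aggregate as the Kullback-Leibler divergence,
which under the neutral interpretation of the dynamics quantifies the
selection information encoded in people's location choices.

Per-step growth factors of the share dynamics act as fitness values
``w_i = x_i(t+1)/x_i(t)``; their share-weighted mean is identically one, so
any departure of individual ``w_i`` from one signals selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "zipf_reference",
    "kl_divergence",
    "surprise",
    "RankSizeFit",
    "fit_ranksize",
    "cumulative_average_kl",
    "InfoReport",
    "fitness_report",
    "mutual_information_plugin",
]

#: floor applied to reference probabilities inside the KL sum
Q_FLOOR = 1e-15


def zipf_reference(n_cities: int) -> np.ndarray:
    """Zipf share vector ``x_r = (1/r)/H(n)`` for ranks ``r = 1..n``."""
    if n_cities < 1:
        raise ValueError("n_cities must be >= 1")
    w = 1.0 / np.arange(1, n_cities + 1)
    return w / math.fsum(w)


def kl_divergence(p, q, floor: float = Q_FLOOR) -> float:
    """Kullback-Leibler divergence ``sum p log2(p/q)`` in bits.

    Terms with ``p_i = 0`` contribute zero; reference entries below ``floor``
    are floored (with a warning) so that boundary-hugging structures remain
    comparable.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions differ in length")
    mask = p > 0
    qm = q[mask]
    n_floored = int(np.count_nonzero(qm < floor))
    if n_floored:
        warnings.warn(f"KL reference floored at {floor} for {n_floored} entries",
                      stacklevel=2)
        qm = np.maximum(qm, floor)
    return float(np.sum(p[mask] * np.log2(p[mask] / qm)))


def surprise(p, q, floor: float = Q_FLOOR) -> np.ndarray:
    """Pointwise surprise ``log2(p/q)`` in bits (zero off the support of p)."""
    p = np.asarray(p, dtype=float)
    q = np.maximum(np.asarray(q, dtype=float), floor)
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = np.log2(p[mask] / q[mask])
    return out


@dataclass
class RankSizeFit:
    """Windowed log-log regression of size against rank.

    ``exponent`` is ``z`` in ``N(r) = N_0 / r**z`` (minus the fitted slope);
    ``intercept`` is ``log N_0``; ``stderr`` the regression standard error of
    the slope.
    """

    exponent: float
    intercept: float
    stderr: float
    rank_window: tuple
    rvalue: float
    residuals: np.ndarray

    @property
    def top_size(self) -> float:
        return float(np.exp(self.intercept))


def fit_ranksize(sizes, window: tuple | None = None) -> RankSizeFit:
    """Fit the rank-size exponent by least squares on log size vs log rank.

    ``sizes`` may be shares or absolute sizes; they are ranked in descending
    order internally.  ``window = (r_lo, r_hi)`` restricts the fit to those
    ranks inclusive; the default is ``(5, n // 2)`` (clipped to at least
    three ranks), avoiding the systematic deviations at the very largest and
    smallest cities.
    """
    s = np.sort(np.asarray(sizes, dtype=float))[::-1]
    n = s.size
    if window is None:
        r_lo, r_hi = (5, max(n // 2, 7)) if n >= 10 else (1, n)
    else:
        r_lo, r_hi = int(window[0]), int(window[1])
    r_lo = max(r_lo, 1)
    r_hi = min(r_hi, n)
    if r_hi - r_lo + 1 < 3:
        raise ValueError("rank window must contain at least 3 ranks")
    sel = s[r_lo - 1:r_hi]
    if np.any(sel <= 0):
        raise ValueError("non-positive sizes inside the fit window")
    log_r = np.log(np.arange(r_lo, r_hi + 1, dtype=float))
    log_s = np.log(sel)
    fit = stats.linregress(log_r, log_s)
    resid = log_s - (fit.intercept + fit.slope * log_r)
    return RankSizeFit(exponent=-fit.slope, intercept=fit.intercept,
                       stderr=fit.stderr, rank_window=(r_lo, r_hi),
                       rvalue=fit.rvalue, residuals=resid)


def cumulative_average_kl(snapshots, align: str = "rank",
                          reference: np.ndarray | None = None):
    """Running averages of structure snapshots and their KL to Zipf.

    Returns ``(prefix_means, kl_trace)`` where ``prefix_means[k]`` is the
    mean of the first ``k+1`` snapshots (rank-aligned by default: each
    snapshot is sorted descending before averaging) and ``kl_trace[k]`` its
    divergence from the Zipf reference, in bits.
    """
    snaps = np.atleast_2d(np.asarray(snapshots, dtype=float))
    if align == "rank":
        snaps = -np.sort(-snaps, axis=1)
    elif align != "identity":
        raise ValueError("align must be 'rank' or 'identity'")
    counts = np.arange(1, snaps.shape[0] + 1, dtype=float)[:, np.newaxis]
    prefix = np.cumsum(snaps, axis=0) / counts
    ref = zipf_reference(snaps.shape[1]) if reference is None else reference
    kl = np.array([kl_divergence(row, ref) for row in prefix])
    return prefix, kl


@dataclass
class InfoReport:
    """Per-city fitness between two consecutive structures."""

    fitness: np.ndarray
    mean_fitness: float
    log_fitness: np.ndarray

    @property
    def neutral(self) -> bool:
        return bool(np.allclose(self.fitness, 1.0, atol=1e-12))


def fitness_report(x_t, x_t1) -> InfoReport:
    """Fitness ``w_i = x_i(t+1)/x_i(t)`` and its (unit) share-weighted mean.

    The log-fitness channel approximates the per-city relative growth rate
    and, averaged over structures and environments, is the mutual information
    between population structure and environment.
    """
    x_t = np.asarray(x_t, dtype=float)
    x_t1 = np.asarray(x_t1, dtype=float)
    if x_t.shape != x_t1.shape:
        raise ValueError("structures differ in length")
    if np.any((x_t == 0) & (x_t1 > 0)):
        raise ValueError("zero share acquired mass: supports differ")
    w = np.ones_like(x_t)
    mask = x_t > 0
    w[mask] = x_t1[mask] / x_t[mask]
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log2(np.maximum(w, 1e-300)), -np.inf)
    return InfoReport(fitness=w, mean_fitness=float(w @ x_t), log_fitness=logw)


def mutual_information_plugin(joint) -> float:
    """Plug-in mutual information (bits) of a joint probability table.

    A binned maximum-likelihood estimator: biased upward by roughly
    ``(rows-1)(cols-1)/(2 N ln 2)`` for ``N`` samples, so treat small values
    with caution.
    """
    j = np.asarray(joint, dtype=float)
    if np.any(j < 0):
        raise ValueError("joint table must be non-negative")
    total = j.sum()
    if total <= 0:
        raise ValueError("joint table must have positive mass")
    j = j / total
    px = j.sum(axis=1, keepdims=True)
    py = j.sum(axis=0, keepdims=True)
    mask = j > 0
    return float(np.sum(j[mask] * np.log2(j[mask] / (px @ py)[mask])))
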