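"""Cluster-mass sign-flip Monte Carlo test for event-locked curves.

Pointwise one-sample t-tests (each participant's curve against their own
baseline) are thresholded at p < 0.05; maximal runs of consecutive
significant, same-signed timepoints form clusters whose mass is the summed
t-value.  The null distribution is built by randomly mirroring each
participant's curve in their baseline (curve → 2·baseline − curve, i.e.
sign-flipping the deviation) and storing the most extreme |cluster mass|
per iteration.  A cluster's Monte Carlo p is the fraction of null masses
strictly exceeding its |mass|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

ALPHA = 0.05
N_ITER = 1000


@dataclass
class Cluster:
    start: float   # offset (s) of first timepoint in the cluster
    end: float     # offset (s) of last timepoint
    sign: int
    mass: float    # summed t-values
    mc_p: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster] = field(default_factory=list)
    n_iterations: int = 0
    seed: int | None = None


def pointwise_t(curves: np.ndarray, baselines: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t (and two-tailed p) of curve − own baseline vs 0.

    ``curves`` is participants × timepoints.  Timepoints with zero variance
    across participants (or fewer than 2 finite values) get t = 0, p = 1 so
    degenerate inputs stay well-defined.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need curves from at least 2 participants")
    d = curves - np.asarray(baselines, dtype=float)[:, None]
    n = np.sum(np.isfinite(d), axis=0)
    mean = np.nanmean(np.where(np.isfinite(d), d, np.nan), axis=0)
    sd = np.nanstd(np.where(np.isfinite(d), d, np.nan), axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = (sd == 0) | (n < 2) | ~np.isfinite(t)
    t = np.where(bad, 0.0, t)
    p = np.ones_like(t)
    ok = ~bad
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n[ok] - 1)
    return t, p


def form_clusters(t: np.ndarray, p: np.ndarray, offsets: np.ndarray,
                  alpha: float = ALPHA) -> list[Cluster]:
    """Maximal runs of consecutive p < alpha timepoints with equal sign."""
    sig = (p < alpha) & (t != 0)
    clusters: list[Cluster] = []
    i, n = 0, len(t)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        s = int(np.sign(t[i]))
        j = i
        while j + 1 < n and sig[j + 1] and int(np.sign(t[j + 1])) == s:
            j += 1
        clusters.append(Cluster(start=float(offsets[i]), end=float(offsets[j]),
                                sign=s, mass=float(t[i:j + 1].sum())))
        i = j + 1
    return clusters


def _max_cluster_mass(t: np.ndarray, p: np.ndarray,
                      alpha: float) -> float:
    sig = (p < alpha) & (t != 0)
    if not sig.any():
        return 0.0
    best = 0.0
    i, n = 0, len(t)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        s = np.sign(t[i])
        j = i
        acc = t[i]
        while j + 1 < n and sig[j + 1] and np.sign(t[j + 1]) == s:
            j += 1
            acc += t[j]
        best = max(best, abs(acc))
        i = j + 1
    return best


def monte_carlo_p(curves: np.ndarray, baselines: np.ndarray,
                  offsets: np.ndarray, n_iter: int = N_ITER,
                  seed: int | np.random.Generator = 0,
                  alpha: float = ALPHA) -> ClusterResult:
    """Sign-flip Monte Carlo over participants; deterministic given seed."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    curves = np.asarray(curves, dtype=float)
    baselines = np.asarray(baselines, dtype=float)
    t_obs, p_obs = pointwise_t(curves, baselines)
    clusters = form_clusters(t_obs, p_obs, offsets, alpha)

    d = curves - baselines[:, None]
    finite = np.isfinite(d)
    d0 = np.where(finite, d, 0.0)
    n_eff = finite.sum(axis=0)
    ssq = (d0 ** 2).sum(axis=0)  # invariant under sign flips
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_iter, curves.shape[0])) * 2 - 1

    dfree = np.maximum(n_eff - 1, 1)
    null = np.empty(n_iter)
    sums = signs @ d0  # n_iter × T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n_eff
        var = (ssq - n_eff * mean ** 2) / dfree
        var = np.maximum(var, 0.0)
        t_null = mean / np.sqrt(var / n_eff)
    t_null = np.where(np.isfinite(t_null), t_null, 0.0)
    p_null = 2.0 * stats.t.sf(np.abs(t_null), dfree)
    for it in range(n_iter):
        null[it] = _max_cluster_mass(t_null[it], p_null[it], alpha)

    for c in clusters:
        c.mc_p = float(np.mean(null > abs(c.mass)))
    return ClusterResult(clusters=clusters, n_iterations=n_iter,
                         seed=None if isinstance(seed, np.random.Generator)
                         else int(seed))


def mirror(curve: np.ndarray, baseline: float) -> np.ndarray:
    """Mirror a curve in its baseline (involution used by the null)."""
    return 2.0 * baseline - np.asarray(curve, dtype=float)
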