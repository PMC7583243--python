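"""Demographic-history statistics per nesting unit.

Tajima's D (with a fixed-S coalescent simulation p-value), Fu's Fs via the
Ewens sampling formula, and the mismatch distribution with a least-squares
sudden-expansion fit yielding SSD (goodness of fit) and Harpending's
raggedness index, both with parametric-bootstrap p-values.

Sites containing missing data (``N``/``-``) are excluded column-wise
(complete-case) for these statistics, which assume a rectangular data matrix.
Negative D and Fs indicate an excess of rare variants, the classic signature
of demographic expansion; positive values point at decline or structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .seqdata import Alignment, MISSING_CODE

__all__ = [
    "NeutralityStats",
    "tajimas_d",
    "tajimas_d_pvalue",
    "fus_fs",
    "ewens_k_tail_probability",
    "mismatch_expansion_fit",
    "expected_mismatch",
    "raggedness",
    "mismatch_histogram",
    "neutrality_table",
]

#: Conventional significance levels: 0.05 for D/SSD/r; Fu's Fs is customarily
#: judged at 0.02 because its null distribution is skewed.
ALPHA_DEFAULT = 0.05
ALPHA_FS = 0.02


@dataclass
class NeutralityStats:
    """Per-unit neutrality/demography summary (study-table layout)."""
    n: int
    s: int
    d: float
    p_d: float
    fs: float
    p_fs: float
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float
    r: float
    p_r: float


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def _complete_matrix(a: Alignment | np.ndarray) -> np.ndarray:
    mat = a.matrix() if isinstance(a, Alignment) else np.asarray(a, np.uint8)
    keep = ~(mat == MISSING_CODE).any(axis=0)
    return mat[:, keep]


def _seg_sites(mat: np.ndarray) -> int:
    return int(np.sum((mat != mat[0]).any(axis=0)))


def _mean_pairwise(mat: np.ndarray) -> float:
    n = mat.shape[0]
    tot = 0
    for i in range(n - 1):
        tot += int(((mat[i] != mat[i + 1:])).sum())
    return tot / (n * (n - 1) / 2)


def _pairwise_diff_counts(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        out[i, i + 1:] = (mat[i] != mat[i + 1:]).sum(axis=1)
    return out + out.T


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def _tajimas_d_from_summary(n: int, s: int, k_hat: float) -> float:
    if s == 0:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * s + e2 * s * (s - 1)
    return float((k_hat - s / a1) / math.sqrt(var))


def tajimas_d(a: Alignment | np.ndarray) -> float:
    """Tajima's D from the standard constants (NaN when S = 0 or n < 4)."""
    mat = _complete_matrix(a)
    n = mat.shape[0]
    if n < 4:
        return float("nan")
    s = _seg_sites(mat)
    if s == 0:
        return float("nan")
    return _tajimas_d_from_summary(n, s, _mean_pairwise(mat))


def _kingman_branches(n: int, rng: np.random.Generator):
    """One constant-size Kingman genealogy: per-branch descendant counts and
    lengths (time in units of N generations).  Vector form for speed."""
    desc = np.ones(2 * n - 1, dtype=np.int64)
    birth = np.zeros(2 * n - 1)
    blen = np.zeros(2 * n - 2)
    active = list(range(n))
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = rng.integers(0, k)
        j = rng.integers(0, k - 1)
        if j >= i:
            j += 1
        c1, c2 = active[i], active[j]
        desc[nxt] = desc[c1] + desc[c2]
        birth[nxt] = t
        blen[c1] = t - birth[c1]
        blen[c2] = t - birth[c2]
        active[min(i, j)] = nxt
        active.pop(max(i, j))
        nxt += 1
    return desc[: 2 * n - 2], blen


def tajimas_d_pvalue(a: Alignment | np.ndarray, n_sims: int = 1000,
                     seed: int = 0, return_null: bool = False):
    """Two-tailed simulation p-value for Tajima's D.

    The null distribution is generated from constant-size coalescent
    genealogies conditioned on the sample size and the observed number of
    segregating sites S: each simulated genealogy receives exactly S
    mutations placed multinomially along branches in proportion to branch
    length (infinite sites), matching common practice in the software this
    statistic is usually computed with.
    """
    mat = _complete_matrix(a)
    n = mat.shape[0]
    s = _seg_sites(mat)
    d_obs = tajimas_d(mat)
    if not np.isfinite(d_obs):
        return (float("nan"), np.array([])) if return_null else float("nan")
    rng = np.random.default_rng(seed)
    pair_norm = n * (n - 1) / 2.0
    null = np.empty(n_sims)
    for b in range(n_sims):
        desc, blen = _kingman_branches(n, rng)
        probs = blen / blen.sum()
        muts = rng.multinomial(s, probs)
        freq = desc[muts > 0]
        counts = muts[muts > 0]
        k_hat = float(np.sum(counts * freq * (n - freq)) / pair_norm)
        null[b] = _tajimas_d_from_summary(n, s, k_hat)
    lo = np.mean(null <= d_obs + 1e-12)
    hi = np.mean(null >= d_obs - 1e-12)
    p = min(1.0, 2.0 * min(lo, hi))
    p = max(p, 1.0 / (n_sims + 1))
    return (p, null) if return_null else p


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the Ewens sampling formula.

    Uses the sequential (Chinese-restaurant) recursion
    P(new allele at step j) = theta / (theta + j - 1), which is exactly
    |S1(n, k)| theta^k / (theta)_n without forming Stirling numbers.
    """
    if n < 1 or theta <= 0:
        raise ValueError("need n >= 1 and theta > 0")
    p = np.zeros(n + 1)
    p[1] = 1.0
    for j in range(1, n):
        new = theta / (theta + j)
        p_next = np.zeros(n + 1)
        p_next[1:] = p[1:] * (1 - new) + p[:-1] * new
        p = p_next
    return p


def ewens_k_tail_probability(n: int, theta: float, k_obs: int) -> float:
    """S' = P(K >= k_obs | theta, n)."""
    p = ewens_k_distribution(n, theta)
    return float(p[k_obs:].sum())


def fus_fs(a: Alignment | np.ndarray) -> float:
    """Fu's Fs = ln(S'/(1-S')) with theta-hat the mean pairwise differences.

    Returns NaN when pi = 0 (undefined), +inf when every sequence is
    identical apart from... i.e. when S' is numerically 1 (k_obs = 1 always
    gives S' = 1), -inf when S' underflows to 0; a log-space fallback keeps
    moderate tail values accurate.
    """
    mat = _complete_matrix(a)
    n = mat.shape[0]
    if n < 3:
        return float("nan")
    theta = _mean_pairwise(mat)
    if theta <= 0:
        return float("nan")
    k_obs = np.unique(mat, axis=0).shape[0]
    s_prime = ewens_k_tail_probability(n, theta, k_obs)
    if s_prime >= 1.0:
        return float("inf")
    if s_prime <= 0.0:
        # log-space fallback via the same recursion on log-probabilities
        logp = _ewens_log_distribution(n, theta)
        log_s = logsumexp(logp[k_obs:])
        if not np.isfinite(log_s):
            return float("-inf")
        return float(log_s - math.log1p(-math.exp(min(log_s, -1e-12))))
    return float(math.log(s_prime) - math.log1p(-s_prime))


def _ewens_log_distribution(n: int, theta: float) -> np.ndarray:
    logp = np.full(n + 1, -np.inf)
    logp[1] = 0.0
    for j in range(1, n):
        l_new = math.log(theta) - math.log(theta + j)
        l_old = math.log(j) - math.log(theta + j)
        nxt = np.full(n + 1, -np.inf)
        nxt[1:] = np.logaddexp(logp[1:] + l_old, logp[:-1] + l_new)
        logp = nxt
    return logp


def fus_fs_pvalue(a: Alignment | np.ndarray, n_sims: int = 1000,
                  seed: int = 0) -> float:
    """Simulation p-value for Fu's Fs: lower-tail rank of the observed value
    among Fs computed on constant-size coalescent samples conditioned on the
    observed theta-hat (mutations Poisson along branches).  Fu's convention:
    significance is assessed in the lower (negative) tail."""
    mat = _complete_matrix(a)
    n = mat.shape[0]
    fs_obs = fus_fs(mat)
    if not np.isfinite(fs_obs):
        return float("nan")
    theta = _mean_pairwise(mat)
    rng = np.random.default_rng(seed)
    null = np.empty(n_sims)
    for b in range(n_sims):
        k_sim = _simulate_ewens_k(n, theta, rng)
        sp = ewens_k_tail_probability(n, theta, k_sim)
        if sp >= 1.0:
            null[b] = np.inf
        elif sp <= 0.0:
            null[b] = -np.inf
        else:
            null[b] = math.log(sp) - math.log1p(-sp)
    p = (np.sum(null <= fs_obs + 1e-12) + 1) / (n_sims + 1)
    return float(p)


def _simulate_ewens_k(n: int, theta: float, rng) -> int:
    """Number of alleles from the Chinese-restaurant construction."""
    k = 1
    for j in range(1, n):
        if rng.random() < theta / (theta + j):
            k += 1
    return k


# ---------------------------------------------------------------------------
# Mismatch distribution and sudden-expansion fit
# ---------------------------------------------------------------------------

def mismatch_histogram(a: Alignment | np.ndarray) -> np.ndarray:
    """Relative frequencies of pairwise difference counts, classes 0..max."""
    mat = _complete_matrix(a)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    diffs = _pairwise_diff_counts(mat)
    iu = np.triu_indices(n, 1)
    vals = diffs[iu]
    hist = np.bincount(vals)
    return hist / hist.sum()


def _geometric_equilibrium(theta: float, i: np.ndarray) -> np.ndarray:
    if theta <= 0:
        return (i == 0).astype(float)
    return theta ** i / (1.0 + theta) ** (i + 1)


def expected_mismatch(tau: float, theta0: float, theta1: float,
                      n_classes: int) -> np.ndarray:
    """Expected pairwise-difference distribution under sudden expansion.

    A population at mutation-scaled size theta0 grows instantaneously to
    theta1 at tau mutational time units before present (tau = 2ut).  The
    probability of observing i differences mixes coalescence after the
    expansion (geometric with parameter theta1, truncated at tau) with
    coalescence before it (Poisson(tau) shift convolved with the theta0
    geometric).  Classes 0..n_classes-1.
    """
    i = np.arange(n_classes)
    f1 = _geometric_equilibrium(theta1, i)
    f0 = _geometric_equilibrium(theta0, i)
    if tau <= 0:
        return f0
    th1 = max(theta1, 1e-12)
    lam1 = (th1 + 1.0) / th1
    # P(coalesced before tau under theta1) split per class:
    log_pois_lam = -lam1 * tau + i * np.log(lam1 * tau + 1e-300) - gammaln(i + 1)
    q = np.cumsum(np.exp(log_pois_lam))
    piece1 = f1 * (1.0 - np.minimum(q, 1.0))
    log_pois = -tau + i * np.log(tau) - gammaln(i + 1)
    pois = np.exp(log_pois)
    conv = np.array([np.sum(pois[: k + 1] * f0[k::-1]) for k in i])
    piece2 = math.exp(-tau / th1) * conv
    return piece1 + piece2


def raggedness(freqs) -> float:
    """Harpending's raggedness on normalised class frequencies.

    Convention pinned for testability: classes run 0..d with d = (largest
    observed difference) + 1 and frequency 0 in class d; the sum of squared
    successive differences starts at i = 0 with x_{-1} defined as 0.
    A flat two-class histogram (0.5, 0.5) therefore gives r = 0.5.
    """
    x = np.asarray(freqs, dtype=float)
    padded = np.concatenate([[0.0], x, [0.0]])
    return float(np.sum(np.diff(padded) ** 2))


def _fit_expansion(obs: np.ndarray, rng: np.random.Generator,
                   n_restarts: int = 10):
    """Bounded quasi-Newton least-squares fit of (tau, theta0, theta1) with
    jittered moment-based restarts; theta1 >= theta0 >= 0 enforced via
    reparameterisation theta1 = theta0 + dtheta."""
    n_classes = len(obs)
    mean_d = float(np.sum(np.arange(n_classes) * obs))

    def ssd_of(params):
        tau, th0, dth = params
        exp_f = expected_mismatch(tau, th0, th0 + dth, n_classes)
        return float(np.sum((obs - exp_f) ** 2))

    best = None
    starts = [(max(mean_d, 0.1), 0.5, max(4.0 * mean_d, 1.0))]
    for _ in range(n_restarts - 1):
        starts.append((max(mean_d, 0.1) * rng.uniform(0.3, 2.0),
                       rng.uniform(0.0, max(mean_d, 1.0)),
                       rng.uniform(0.5, 8.0) * max(mean_d, 1.0)))
    for x0 in starts:
        res = minimize(ssd_of, x0, method="L-BFGS-B",
                       bounds=[(0.0, 4.0 * n_classes),
                               (0.0, 10.0 * max(mean_d, 1.0)),
                               (1e-6, 1e4)],
                       options={"ftol": 1e-12, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("mismatch expansion fit failed to converge")
    tau, th0, dth = best.x
    return float(tau), float(th0), float(th0 + dth), float(best.fun)


def _simulate_expansion_sample(n: int, tau: float, theta0: float,
                               theta1: float, rng: np.random.Generator):
    """Coalescent sample of pairwise differences under the fitted
    sudden-expansion history.  Time in mutational units (pair mutation rate
    1, per-lineage 1/2); coalescence rate C(k,2)/theta(t) with theta = theta1
    for t < tau and theta0 before the expansion."""
    t = 0.0
    active = list(range(n))
    parent_mut = np.zeros(2 * n - 1)
    birth = np.full(2 * n - 1, 0.0)
    desc = np.zeros((2 * n - 1, n), dtype=bool)
    desc[np.arange(n), np.arange(n)] = True
    nxt = n
    th0 = max(theta0, 1e-9)
    th1 = max(theta1, 1e-9)
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0
        if t < tau:
            dt = rng.exponential(th1 / rate)
            if t + dt > tau:
                t = tau
                continue
        else:
            dt = rng.exponential(th0 / rate)
        t += dt
        i = rng.integers(0, k)
        j = rng.integers(0, k - 1)
        if j >= i:
            j += 1
        c1, c2 = active[i], active[j]
        parent_mut[c1] = rng.poisson(0.5 * (t - birth[c1]))
        parent_mut[c2] = rng.poisson(0.5 * (t - birth[c2]))
        desc[nxt] = desc[c1] | desc[c2]
        birth[nxt] = t
        active[min(i, j)] = nxt
        active.pop(max(i, j))
        nxt += 1
    x = desc[: nxt - 1, :].astype(float)
    m = parent_mut[: nxt - 1]
    s = m @ x
    g = (x * m[:, None]).T @ x
    diffs = s[:, None] + s[None, :] - 2.0 * g
    iu = np.triu_indices(n, 1)
    return np.rint(diffs[iu]).astype(np.int64)


def mismatch_expansion_fit(a: Alignment | np.ndarray, n_boot: int = 100,
                           seed: int = 0):
    """Fit the sudden-expansion model to the mismatch distribution.

    Returns ``(tau, theta0, theta1, SSD, p_SSD, r, p_r)``.  SSD is the sum of
    squared deviations between observed and fitted class frequencies; its
    p-value (and that of the raggedness index) comes from a parametric
    bootstrap: *n_boot* coalescent samples simulated under the fitted
    expansion history, each refitted, with p the fraction of bootstrap
    statistics at least as large as observed.
    """
    mat = _complete_matrix(a)
    n = mat.shape[0]
    if n < 4:
        raise ValueError("need at least four sequences")
    obs = mismatch_histogram(mat)
    if len(obs) < 2:
        raise ValueError("maximum pairwise difference is zero — nothing to fit")
    rng = np.random.default_rng(seed)
    tau, th0, th1, ssd = _fit_expansion(obs, rng)
    r_obs = raggedness(obs)
    if n_boot <= 0:
        return tau, th0, th1, ssd, float("nan"), r_obs, float("nan")
    ssd_null = np.empty(n_boot)
    r_null = np.empty(n_boot)
    for b in range(n_boot):
        diffs = _simulate_expansion_sample(n, tau, th0, th1, rng)
        hist = np.bincount(diffs)
        freqs = hist / hist.sum()
        _, _, _, ssd_b = _fit_expansion(freqs, rng, n_restarts=3)
        ssd_null[b] = ssd_b
        r_null[b] = raggedness(freqs)
    p_ssd = (np.sum(ssd_null >= ssd - 1e-15) + 1) / (n_boot + 1)
    p_r = (np.sum(r_null >= r_obs - 1e-15) + 1) / (n_boot + 1)
    return tau, th0, th1, ssd, float(p_ssd), r_obs, float(p_r)


# ---------------------------------------------------------------------------
# Per-unit battery
# ---------------------------------------------------------------------------

def neutrality_table(a: Alignment, level: int, n_sims: int = 1000,
                     n_boot: int = 100, seed: int = 0) -> pd.DataFrame:
    """Per-unit neutrality statistics at one level (study-table columns).

    Infinite Fs values are serialised as ``+inf``/``-inf`` strings in the
    TSV writer and are excluded from significance assessment.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for unit, ix in a.unit_indices(level).items():
        sub = a.subset(ix).matrix()
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        d = tajimas_d(sub)
        p_d = tajimas_d_pvalue(sub, n_sims=n_sims, seed=sub_seed) \
            if np.isfinite(d) else float("nan")
        fs = fus_fs(sub)
        p_fs = fus_fs_pvalue(sub, n_sims=n_sims, seed=sub_seed + 1) \
            if np.isfinite(fs) else float("nan")
        try:
            tau, th0, th1, ssd, p_ssd, r, p_r = mismatch_expansion_fit(
                sub, n_boot=n_boot, seed=sub_seed + 2)
        except (ValueError, RuntimeError):
            tau = th0 = th1 = ssd = p_ssd = r = p_r = float("nan")
        rows.append({"unit": unit, "n": sub.shape[0], "S": _seg_sites(sub),
                     "D": d, "p_D": p_d, "Fs": fs, "p_Fs": p_fs,
                     "tau": tau, "theta0": th0, "theta1": th1,
                     "SSD": ssd, "p_SSD": p_ssd, "r": r, "p_r": p_r})
    return pd.DataFrame(rows).set_index("unit")
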