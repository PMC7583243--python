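"""Diversity and differentiation statistics.

Implements the per-unit diversity indices (haplotype diversity Hd, nucleotide
diversity pi), molecular-variance fixation indices (frequency-mode F_ST on
haplotype identity and distance-mode Phi_ST on pairwise nucleotide
differences, both as AMOVA variance-component estimators with permutation
p-values), the Markov-chain exact test of population differentiation on
haplotype contingency tables, the three-level hierarchical AMOVA (F_CT),
the Mantel test, and the Benjamini-Yekutieli false-discovery-rate correction
with the harmonic-sum penalty.

Missing sites (``N``/``-``) are handled pairwise-complete throughout: a pair
of sequences is compared only at sites where both carry a called base.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .seqdata import Alignment, HaplotypeTable, MISSING_CODE

__all__ = [
    "DiversityIndices",
    "PairwiseDifferentiation",
    "AmovaResult",
    "haplotype_diversity",
    "nucleotide_diversity",
    "pairwise_distance_matrix",
    "amova_fst",
    "fst_from_counts",
    "pairwise_differentiation",
    "exact_differentiation_test",
    "enumerate_exact_test",
    "hierarchical_amova",
    "mantel_test",
    "benjamini_yekutieli_adjust",
    "diversity_table",
]


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityIndices:
    """Per-unit diversity summary (one row of the study-style tables)."""
    n: int
    n_hap: int
    hd: float
    pi: float


def haplotype_diversity(counts) -> float:
    """Nei's haplotype (gene) diversity with small-sample correction.

    Hd = n (1 - sum p_i^2) / (n - 1).  Returns NaN for n < 2.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n * (1.0 - np.sum(p ** 2)) / (n - 1.0))


def pairwise_distance_matrix(a: Alignment | np.ndarray):
    """Pairwise difference matrices with pairwise-complete site handling.

    Returns ``(prop, diffs, comps)``: the per-site-normalised proportion of
    differing sites, the raw difference counts and the number of comparable
    sites per pair.  All symmetric with zero diagonal.  A pair with zero
    comparable sites raises, naming the pair.
    """
    mat = a.matrix() if isinstance(a, Alignment) else np.asarray(a, np.uint8)
    n = mat.shape[0]
    valid = mat != MISSING_CODE
    diffs = np.zeros((n, n), dtype=np.int64)
    comps = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1:]
        d = (mat[i] != mat[i + 1:]) & both
        diffs[i, i + 1:] = d.sum(axis=1)
        comps[i, i + 1:] = both.sum(axis=1)
    diffs += diffs.T
    comps += comps.T
    np.fill_diagonal(comps, mat.shape[1])
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        if (comps[off] == 0).any():
            i, j = np.argwhere((comps == 0) & off)[0]
            ids = a.ids if isinstance(a, Alignment) else list(range(n))
            raise ValueError(
                f"no comparable sites between {ids[i]} and {ids[j]}")
    with np.errstate(invalid="ignore"):
        prop = np.where(comps > 0, diffs / np.maximum(comps, 1), 0.0)
    return prop, diffs, comps


def nucleotide_diversity(a: Alignment | np.ndarray) -> float:
    """Nucleotide diversity per site: mean over all sequence pairs of
    (differences / comparable sites).  NaN for n < 2."""
    prop, _, _ = pairwise_distance_matrix(a)
    n = prop.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, 1)
    return float(prop[iu].mean())


def mean_pairwise_differences(a: Alignment | np.ndarray) -> float:
    """Mean number of raw pairwise differences (the ``pi_total`` of the
    neutrality statistics)."""
    _, diffs, _ = pairwise_distance_matrix(a)
    n = diffs.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, 1)
    return float(diffs[iu].mean())


def diversity_table(a: Alignment, level: int) -> pd.DataFrame:
    """Per-unit n, nHap, Hd and pi at one geographic level (study-table layout)."""
    table = []
    ht = _collapse(a, level)
    idx = a.unit_indices(level)
    for j, unit in enumerate(ht.unit_names):
        counts = ht.counts[:, j]
        sub = a.subset(idx[unit])
        table.append({
            "unit": unit,
            "n": int(counts.sum()),
            "nHap": int((counts > 0).sum()),
            "Hd": haplotype_diversity(counts),
            "pi": nucleotide_diversity(sub),
        })
    return pd.DataFrame(table).set_index("unit")


def _collapse(a: Alignment, level: int) -> HaplotypeTable:
    from .seqdata import collapse_haplotypes
    return collapse_haplotypes(a, level)


# ---------------------------------------------------------------------------
# AMOVA F_ST / Phi_ST
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Variance components of a (possibly hierarchical) AMOVA.

    ``sigma_a`` is the among-group, ``sigma_b`` the among-units-within-group
    and ``sigma_c`` the within-unit component; for a flat (two-level) AMOVA
    ``sigma_a`` is 0 and F_CT is NaN.
    """
    sigma_a: float
    sigma_b: float
    sigma_c: float
    f_ct: float
    f_sc: float
    f_st: float
    p_fct: float = float("nan")
    p_fst: float = float("nan")


def _flat_amova_from_counts(counts: np.ndarray):
    """Frequency-mode (haplotype identity distance) one-level AMOVA from a
    haplotype x unit count matrix.  Returns (sigma_a, sigma_w)."""
    counts = np.asarray(counts, dtype=float)
    n_p = counts.sum(axis=0)
    keep = n_p > 0
    counts, n_p = counts[:, keep], n_p[keep]
    n_tot = n_p.sum()
    n_pops = len(n_p)
    if n_pops < 2 or n_tot <= n_pops:
        return float("nan"), float("nan")
    tot = counts.sum(axis=1)
    ssd_t = (n_tot ** 2 - np.sum(tot ** 2)) / (2.0 * n_tot)
    ssd_w = np.sum((n_p ** 2 - np.sum(counts ** 2, axis=0)) / (2.0 * n_p))
    ssd_a = ssd_t - ssd_w
    df_a, df_w = n_pops - 1, n_tot - n_pops
    sigma_w = ssd_w / df_w
    n_bar = (n_tot - np.sum(n_p ** 2) / n_tot) / df_a
    sigma_a = (ssd_a / df_a - sigma_w) / n_bar
    return float(sigma_a), float(sigma_w)


def _flat_amova_from_sqdist(d2: np.ndarray, groups: list[np.ndarray]):
    """One-level AMOVA from squared distances and per-unit index arrays."""
    n_p = np.array([len(g) for g in groups], dtype=float)
    n_tot = n_p.sum()
    n_pops = len(groups)
    allix = np.concatenate(groups)
    sub = d2[np.ix_(allix, allix)]
    ssd_t = sub.sum() / (2.0 * n_tot)
    ssd_w = sum(d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups)
    ssd_a = ssd_t - ssd_w
    df_a, df_w = n_pops - 1, n_tot - n_pops
    if df_w <= 0:
        return float("nan"), float("nan")
    sigma_w = ssd_w / df_w
    n_bar = (n_tot - np.sum(n_p ** 2) / n_tot) / df_a
    sigma_a = (ssd_a / df_a - sigma_w) / n_bar
    return float(sigma_a), float(sigma_w)


def fst_from_counts(counts: np.ndarray) -> float:
    """Frequency-mode AMOVA F_ST from a haplotype x unit count matrix.

    Reported as computed (may be slightly negative); NaN when every unit is
    fixed for the same haplotype (monomorphic — F_ST undefined).
    """
    counts = np.asarray(counts, dtype=float)
    if np.count_nonzero(counts.sum(axis=1)) <= 1:
        return float("nan")  # monomorphic: every unit fixed for one haplotype
    sigma_a, sigma_w = _flat_amova_from_counts(counts)
    tot = sigma_a + sigma_w
    if not np.isfinite(tot) or tot == 0:
        return float("nan")
    return sigma_a / tot


def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    """Upper-tail permutation p with the +1 correction (never exactly 0)."""
    null = null[np.isfinite(null)]
    k = int(np.sum(null >= obs - 1e-12))
    return (k + 1) / (len(null) + 1)


def amova_fst(data, units=None, mode: str = "frequency",
              n_perm: int = 0, seed: int | None = None):
    """AMOVA fixation index between units, frequency or distance mode.

    Parameters
    ----------
    data
        Frequency mode: a :class:`HaplotypeTable` (or raw count matrix).
        Distance mode: an :class:`Alignment` with *units* the analysis level,
        or a precomputed squared-distance matrix with *units* a list of
        per-unit index arrays.
    mode
        ``"frequency"`` uses haplotype identity distance (conventional F_ST);
        ``"distance"`` uses raw pairwise nucleotide differences (Phi_ST).
    n_perm, seed
        If ``n_perm > 0``, a permutation p-value is computed by permuting
        individuals among units (seed is then mandatory).

    Returns
    -------
    (fst, p) if permutations were requested, else fst.
    """
    rng = _require_rng(n_perm, seed)
    if mode == "frequency":
        counts = data.counts if isinstance(data, HaplotypeTable) else np.asarray(data)
        obs = fst_from_counts(counts)
        if n_perm:
            null = _permute_counts_fst(counts, n_perm, rng)
            return obs, _perm_pvalue(obs, null)
        return obs
    if mode != "distance":
        raise ValueError("mode must be 'frequency' or 'distance'")
    if isinstance(data, Alignment):
        _, diffs, _ = pairwise_distance_matrix(data)
        groups = list(data.unit_indices(units).values())
    else:
        diffs = np.asarray(data, dtype=float)
        groups = [np.asarray(g) for g in units]
    sigma_a, sigma_w = _flat_amova_from_sqdist(diffs, groups)
    tot = sigma_a + sigma_w
    obs = float("nan") if (not np.isfinite(tot) or tot == 0) else sigma_a / tot
    if n_perm:
        null = np.empty(n_perm)
        sizes = [len(g) for g in groups]
        allix = np.concatenate(groups)
        for b in range(n_perm):
            perm = rng.permutation(allix)
            gs, off = [], 0
            for s in sizes:
                gs.append(perm[off:off + s]); off += s
            sa, sw = _flat_amova_from_sqdist(diffs, gs)
            t = sa + sw
            null[b] = sa / t if t else np.nan
        return obs, _perm_pvalue(obs, null)
    return obs


def _require_rng(n_perm, seed):
    if n_perm and seed is None:
        raise ValueError("a seed is mandatory when permutations are requested")
    return np.random.default_rng(seed) if seed is not None else None


def _permute_counts_fst(counts: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Null F_ST distribution by permuting individuals among units."""
    counts = np.asarray(counts, dtype=np.int64)
    n_hap, n_units = counts.shape
    hap_of_ind = np.repeat(np.arange(n_hap), counts.sum(axis=1))
    sizes = counts.sum(axis=0)
    out = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(hap_of_ind)
        newc = np.zeros_like(counts)
        off = 0
        for j, s in enumerate(sizes):
            np.add.at(newc[:, j], perm[off:off + s], 1)
            off += s
        out[b] = fst_from_counts(newc)
    return out


# ---------------------------------------------------------------------------
# Exact test of differentiation (Raymond & Rousset Markov chain)
# ---------------------------------------------------------------------------

def _log_hypergeom(table: np.ndarray) -> float:
    """log probability (up to the margin constant) of a contingency table
    under the multivariate hypergeometric: log P = const - sum log(a_ij!)."""
    return -float(np.sum(gammaln(table + 1.0)))


def exact_differentiation_test(table, chain_len: int = 100_000,
                               burnin: int = 10_000,
                               seed: int | None = None) -> float:
    """Markov-chain exact test of haplotype differentiation for two units.

    Estimates the probability, under fixed margins, of observing a table as
    or less likely than the data (Fisher-type) via a Metropolis walk over
    fixed-margin tables with the hypergeometric stationary distribution.
    Degenerate tables (a single haplotype, or a single non-empty unit)
    return p = 1.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected a haplotype x 2-unit contingency table")
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) > 0).sum() < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    cur = table.copy()
    log_obs = _log_hypergeom(table)
    n_hap = cur.shape[0]
    hits = 0
    kept = 0
    log_cur = log_obs
    # pre-draw proposals in blocks for speed
    total = burnin + chain_len
    block = 20_000
    done = 0
    while done < total:
        m = min(block, total - done)
        r1 = rng.integers(0, n_hap, size=m)
        r2 = rng.integers(0, n_hap, size=m)
        swap = rng.random(size=m)
        acc = rng.random(size=m)
        for t in range(m):
            a, b = r1[t], r2[t]
            if a == b:
                if done + t >= burnin:
                    kept += 1
                    hits += log_cur <= log_obs + 1e-9
                continue
            # move one individual of haplotype a from unit0 to unit1 and one
            # of haplotype b from unit1 to unit0 (or the mirrored move)
            if swap[t] < 0.5:
                c1, c2 = 0, 1
            else:
                c1, c2 = 1, 0
            if cur[a, c1] == 0 or cur[b, c2] == 0:
                if done + t >= burnin:
                    kept += 1
                    hits += log_cur <= log_obs + 1e-9
                continue
            ratio = (cur[a, c1] * cur[b, c2]) / \
                ((cur[a, c2] + 1.0) * (cur[b, c1] + 1.0))
            if acc[t] < ratio:
                cur[a, c1] -= 1
                cur[a, c2] += 1
                cur[b, c2] -= 1
                cur[b, c1] += 1
                log_cur = _log_hypergeom(cur)
            if done + t >= burnin:
                kept += 1
                hits += log_cur <= log_obs + 1e-9
        done += m
    return hits / kept if kept else 1.0


def enumerate_exact_test(table) -> float:
    """Exhaustive exact test for small haplotype x 2-unit tables.

    Enumerates every table with the observed margins and sums hypergeometric
    probabilities of tables no more probable than the observed one.  Used as
    the independent oracle for the Markov-chain estimate; feasible for
    tables with up to ~1e5 configurations.
    """
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    col0 = int(table[:, 0].sum())
    n = int(table.sum())
    log_denom = gammaln(n + 1) - gammaln(col0 + 1) - gammaln(n - col0 + 1)

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_obs = sum(log_choose(rows[h], table[h, 0]) for h in range(len(rows))) \
        - log_denom
    suffix = np.concatenate([np.cumsum(rows[::-1])[::-1][1:], [0]])
    total_p = 0.0

    def rec(h: int, remaining: int, log_p: float):
        nonlocal total_p
        if h == len(rows):
            if remaining == 0 and log_p <= log_obs + 1e-9:
                total_p += math.exp(log_p)
            return
        lo = max(0, remaining - suffix[h])
        hi = min(rows[h], remaining)
        for a in range(lo, hi + 1):
            rec(h + 1, remaining - a,
                log_p + float(log_choose(rows[h], a)))

    rec(0, col0, -float(log_denom))
    return min(total_p, 1.0)


# ---------------------------------------------------------------------------
# Pairwise differentiation battery
# ---------------------------------------------------------------------------

@dataclass
class PairwiseDifferentiation:
    """All-pairs differentiation at one level: F_ST matrix, permutation and
    exact-test p-values and the post-FDR significance mask."""
    unit_names: list[str]
    fst: np.ndarray
    p_perm: np.ndarray
    p_exact: np.ndarray
    significant: np.ndarray
    fdr_threshold: float
    mode: str = "frequency"

    def to_frame(self, which: str = "fst") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.unit_names, columns=self.unit_names)


def pairwise_differentiation(a: Alignment, level: int,
                             mode: str = "frequency",
                             n_perm: int = 10_000,
                             exact_chain_len: int = 100_000,
                             exact_burnin: int = 10_000,
                             alpha: float = 0.05,
                             seed: int = 0) -> PairwiseDifferentiation:
    """Pairwise F_ST (or Phi_ST) with permutation p-values, exact tests and
    Benjamini-Yekutieli correction across all unit pairs at *level*."""
    ht = _collapse(a, level)
    units = ht.unit_names
    k = len(units)
    idx = a.unit_indices(level)
    fst = np.zeros((k, k))
    p_perm = np.ones((k, k))
    p_exact = np.ones((k, k))
    if mode == "distance":
        _, diffs, _ = pairwise_distance_matrix(a)
    rng = np.random.default_rng(seed)
    pair_ps = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for i, j in pairs:
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        if mode == "frequency":
            counts = ht.counts[:, [i, j]]
            f, p = amova_fst(counts, mode="frequency", n_perm=n_perm,
                             seed=sub_seed)
        else:
            f, p = amova_fst(diffs, [idx[units[i]], idx[units[j]]],
                             mode="distance", n_perm=n_perm, seed=sub_seed)
        pe = exact_differentiation_test(ht.counts[:, [i, j]],
                                        chain_len=exact_chain_len,
                                        burnin=exact_burnin,
                                        seed=sub_seed + 1)
        fst[i, j] = fst[j, i] = f
        p_perm[i, j] = p_perm[j, i] = p
        p_exact[i, j] = p_exact[j, i] = pe
        pair_ps.append(p)
    sig_flat, thr = benjamini_yekutieli_adjust(np.array(pair_ps), alpha)
    significant = np.zeros((k, k), dtype=bool)
    for (i, j), s in zip(pairs, sig_flat):
        significant[i, j] = significant[j, i] = bool(s)
    return PairwiseDifferentiation(units, fst, p_perm, p_exact, significant,
                                   thr, mode)


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------

def hierarchical_amova(a: Alignment, grouping: dict[str, list[str]],
                       level: int, mode: str = "frequency",
                       n_perm: int = 1000, seed: int = 0) -> AmovaResult:
    """Three-level AMOVA: groups of units / units / individuals.

    *grouping* maps group names to lists of unit names at *level*.  The F_CT
    p-value permutes whole units among groups (preserving group sizes).
    """
    if len(grouping) < 2:
        raise ValueError("hierarchical AMOVA needs at least two groups")
    units = a.units(level)
    assigned = [u for g in grouping.values() for u in g]
    if sorted(assigned) != sorted(units):
        raise ValueError("grouping must partition the units exactly")
    if mode == "frequency":
        ht = _collapse(a, level)
        cols = {u: j for j, u in enumerate(ht.unit_names)}

        def components(gdef: list[list[str]]):
            return _hier_components_counts(ht.counts, cols, gdef)
    else:
        _, diffs, _ = pairwise_distance_matrix(a)
        idx = a.unit_indices(level)

        def components(gdef: list[list[str]]):
            return _hier_components_dist(diffs, idx, gdef)

    gdef = [list(v) for v in grouping.values()]
    sa, sb, sc = components(gdef)
    tot = sa + sb + sc
    res = AmovaResult(sa, sb, sc,
                      f_ct=sa / tot if tot else float("nan"),
                      f_sc=sb / (sb + sc) if (sb + sc) else float("nan"),
                      f_st=(sa + sb) / tot if tot else float("nan"))
    if n_perm:
        rng = np.random.default_rng(seed)
        sizes = [len(g) for g in gdef]
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = list(rng.permutation(units))
            gs, off = [], 0
            for s in sizes:
                gs.append(perm[off:off + s]); off += s
            pa, pb, pc = components(gs)
            t = pa + pb + pc
            null[b] = pa / t if t else np.nan
        res.p_fct = _perm_pvalue(res.f_ct, null)
    return res


def _hier_ss(counts_list):
    """Sums of squares pieces for identity distance from count vectors."""
    tot = sum(c.sum() for c in counts_list)
    pooled = sum(counts_list)
    ssd = (tot ** 2 - np.sum(pooled.astype(float) ** 2)) / (2.0 * tot)
    return ssd


def _hier_components_counts(counts, cols, gdef):
    counts = counts.astype(float)
    unit_counts = {u: counts[:, j] for u, j in cols.items()}
    n_p = {u: c.sum() for u, c in unit_counts.items()}
    n_tot = sum(n_p.values())
    n_units = len(unit_counts)
    n_groups = len(gdef)
    ssd_w = sum((n_p[u] ** 2 - np.sum(unit_counts[u] ** 2)) / (2.0 * n_p[u])
                for u in unit_counts if n_p[u] > 0)
    ssd_t = _hier_ss(list(unit_counts.values()))
    ssd_wg = sum(_hier_ss([unit_counts[u] for u in g]) for g in gdef)
    ssd_ap = ssd_wg - ssd_w          # among units within groups
    ssd_ag = ssd_t - ssd_wg          # among groups
    ng = {i: sum(n_p[u] for u in g) for i, g in enumerate(gdef)}
    sum_np2_within = sum(sum(n_p[u] ** 2 for u in g) / ng[i]
                         for i, g in enumerate(gdef))
    n1 = (n_tot - sum_np2_within) / (n_units - n_groups)
    n2 = (sum_np2_within - sum(n_p[u] ** 2 for u in n_p) / n_tot) / (n_groups - 1)
    n3 = (n_tot - sum(v ** 2 for v in ng.values()) / n_tot) / (n_groups - 1)
    sigma_c = ssd_w / (n_tot - n_units)
    sigma_b = (ssd_ap / (n_units - n_groups) - sigma_c) / n1
    sigma_a = (ssd_ag / (n_groups - 1) - sigma_c - n2 * sigma_b) / n3
    return float(sigma_a), float(sigma_b), float(sigma_c)


def _hier_components_dist(d2, idx, gdef):
    n_p = {u: len(ix) for u, ix in idx.items()}
    n_tot = sum(n_p.values())
    n_units = len(idx)
    n_groups = len(gdef)

    def ssd_of(ix):
        return d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix))

    ssd_w = sum(ssd_of(ix) for ix in idx.values())
    all_ix = np.concatenate(list(idx.values()))
    ssd_t = ssd_of(all_ix)
    ssd_wg = sum(ssd_of(np.concatenate([idx[u] for u in g])) for g in gdef)
    ssd_ap = ssd_wg - ssd_w
    ssd_ag = ssd_t - ssd_wg
    ng = {i: sum(n_p[u] for u in g) for i, g in enumerate(gdef)}
    sum_np2_within = sum(sum(n_p[u] ** 2 for u in g) / ng[i]
                         for i, g in enumerate(gdef))
    n1 = (n_tot - sum_np2_within) / (n_units - n_groups)
    n2 = (sum_np2_within - sum(v ** 2 for v in n_p.values()) / n_tot) / (n_groups - 1)
    n3 = (n_tot - sum(v ** 2 for v in ng.values()) / n_tot) / (n_groups - 1)
    sigma_c = ssd_w / (n_tot - n_units)
    sigma_b = (ssd_ap / (n_units - n_groups) - sigma_c) / n1
    sigma_a = (ssd_ag / (n_groups - 1) - sigma_c - n2 * sigma_b) / n3
    return float(sigma_a), float(sigma_b), float(sigma_c)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(d1: np.ndarray, d2: np.ndarray, n_perm: int = 10_000,
                seed: int = 0, alternative: str = "greater"):
    """Mantel test of matrix correlation.

    Pearson correlation of the off-diagonal elements, with a permutation
    p-value obtained by jointly permuting rows and columns of *d2*.  The
    default alternative is one-sided positive (the isolation-by-distance
    convention); ``"two-sided"`` is available.  Returns ``(r, p)``.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 units")
    iu = np.triu_indices(n, 1)
    x, y = d1[iu], d2[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")

    def corr(yy):
        return float(np.corrcoef(x, yy)[0, 1])

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2[np.ix_(perm, perm)][iu]
        r = corr(yp)
        if alternative == "greater":
            count += r >= r_obs - 1e-12
        elif alternative == "less":
            count += r <= r_obs + 1e-12
        else:
            count += abs(r) >= abs(r_obs) - 1e-12
    return r_obs, (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def benjamini_yekutieli_adjust(pvals, alpha: float = 0.05):
    """Benjamini-Yekutieli step-up FDR with the harmonic-sum penalty.

    Rejects H_(1..k*) where k* is the largest k with
    ``p_(k) <= k * alpha / (m * c(m))`` and ``c(m) = sum_{i=1..m} 1/i``
    (the modified FDR recommended for population-genetic test batteries).

    Returns ``(significant, threshold)`` where *significant* is a boolean
    array in the original order and *threshold* is the step-up critical value
    actually applied (0 when nothing is rejected).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    crit = np.arange(1, m + 1) * alpha / (m * c_m)
    passed = p[order] <= crit
    significant = np.zeros(m, dtype=bool)
    threshold = 0.0
    if passed.any():
        k_star = int(np.max(np.nonzero(passed)[0]))
        significant[order[:k_star + 1]] = True
        threshold = float(crit[k_star])
    return significant, threshold
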