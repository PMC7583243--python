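"""Approximate Bayesian computation: scenario choice and parameter estimation.

The ABC engine compares competing colonization scenarios by (1) building a
reference table of simulated datasets summarised by all pairwise F_ST values
among sampled demes, (2) ranking simulations by Euclidean proximity to the
observed summary vector on median/MAD-normalised statistics, (3) fitting a
multinomial logistic regression of scenario identity on the statistics within
the retained set, evaluated at the observed vector, over a grid of
retained-set sizes, and (4) estimating parameter posteriors from the retained
simulations of the chosen scenario with the classic local-linear regression
adjustment.

Model fit per retained-set size is summarised by McFadden's pseudo-R^2 with
bootstrap confidence intervals; the selected scenario is the one with the
highest posterior probability at the largest retained-set size, with a flag
recording whether its confidence band is clear of the runner-up's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .coalsim import ScenarioSpec, SimulatedDataset, sample_priors, \
    simulate_dataset, validate_scenario
from .seqdata import Alignment, collapse_haplotypes
from .sumstats import fst_from_counts, haplotype_diversity

__all__ = [
    "ReferenceTable",
    "ModelChoiceResult",
    "summarize_for_abc",
    "stat_names_for",
    "build_reference_table",
    "rejection_rank",
    "logistic_model_choice",
    "posterior_parameters",
    "prior_predictive_check",
    "DEFAULT_N_GRID",
]

#: Retained-simulation counts over which the logistic model choice is traced.
DEFAULT_N_GRID = (8000, 16000, 24000, 32000, 40000)
#: Desk-scale default reference-table size per scenario; the full-scale
#: analysis this mirrors used 4,000,000 simulated datasets overall.
DEFAULT_TABLE_ROWS = 100_000


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _deme_hap_counts(matrix: np.ndarray, demes: list[str],
                     deme_order: list[str]) -> np.ndarray:
    """Haplotype x deme count matrix by hashing sequence rows."""
    mat = np.ascontiguousarray(matrix)
    col = {d: j for j, d in enumerate(deme_order)}
    hap_id: dict[bytes, int] = {}
    counts: list[np.ndarray] = []
    for i in range(mat.shape[0]):
        key = mat[i].tobytes()
        h = hap_id.setdefault(key, len(hap_id))
        if h == len(counts):
            counts.append(np.zeros(len(deme_order), dtype=np.int64))
        counts[h][col[demes[i]]] += 1
    return np.stack(counts)


def stat_names_for(demes: list[str], extended: bool = False) -> list[str]:
    """Canonical summary-statistic ordering for a set of sampled demes."""
    demes = sorted(demes)
    names = [f"fst_{a}_{b}" for i, a in enumerate(demes)
             for b in demes[i + 1:]]
    if extended:
        names += [f"hd_{d}" for d in demes]
        names += [f"pi_{d}" for d in demes]
    return names


def summarize_for_abc(data, level: int = 1,
                      extended: bool = False) -> np.ndarray:
    """Summary-statistic vector: all pairwise frequency-mode F_ST values
    among sampled demes in canonical (sorted-name) order; optionally extended
    with per-deme haplotype diversity and mean within-deme pairwise
    distance per site.  Undefined F_ST pairs (monomorphic) are imputed as 0.

    *data* is a :class:`SimulatedDataset` or an :class:`Alignment` with a
    population map at *level*.
    """
    if isinstance(data, SimulatedDataset):
        demes = sorted(set(data.sample_demes))
        counts = _deme_hap_counts(data.matrix, data.sample_demes, demes)
        mat = data.matrix
        deme_of = np.asarray(data.sample_demes)
    elif isinstance(data, Alignment):
        ht = collapse_haplotypes(data, level)
        demes = sorted(ht.unit_names)
        perm = [ht.unit_names.index(d) for d in demes]
        counts = ht.counts[:, perm]
        mat = data.matrix()
        deme_of = data.labels_at(level).to_numpy()
    else:
        raise TypeError("expected SimulatedDataset or Alignment")
    if len(demes) < 2:
        raise ValueError("need at least two demes with samples")
    stats = []
    for i in range(len(demes)):
        for j in range(i + 1, len(demes)):
            f = fst_from_counts(counts[:, [i, j]])
            stats.append(0.0 if not np.isfinite(f) else f)
    if extended:
        for j, d in enumerate(demes):
            stats.append(haplotype_diversity(counts[:, j]))
        for d in demes:
            sub = mat[deme_of == d]
            stats.append(_mean_pairwise_per_site(sub))
    return np.asarray(stats, dtype=float)


def _mean_pairwise_per_site(mat: np.ndarray) -> float:
    n, sites = mat.shape
    if n < 2:
        return 0.0
    tot = 0
    for i in range(n - 1):
        tot += int((mat[i] != mat[i + 1:]).sum())
    return tot / (n * (n - 1) / 2) / sites


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

def _flatten_draw(spec: ScenarioSpec, draw: dict) -> dict[str, float]:
    out = {f"N_{k}": v for k, v in draw["sizes"].items()}
    for i, (ev, t) in enumerate(zip(spec.events, draw["times"])):
        out[f"t{i + 1}_{ev.kind}_{ev.deme}"] = t
        if draw["fractions"][i] is not None:
            out[f"frac{i + 1}_{ev.deme}"] = draw["fractions"][i]
    out["mu"] = draw["mu"]
    return out


@dataclass
class ReferenceTable:
    """Simulated parameter draws and summary statistics, one row per dataset.

    ``table`` holds a ``scenario`` column, parameter columns and the
    summary-statistic columns listed in ``stat_names``.  Normalisation
    constants (per-statistic median and MAD over the whole table) are
    computed once at construction and reused for every query.
    """
    table: pd.DataFrame
    stat_names: list[str]
    param_names: list[str]
    scenario_ids: list[str]
    median: np.ndarray = field(default=None)
    mad: np.ndarray = field(default=None)

    def __post_init__(self):
        stats = self.stats_matrix()
        if self.median is None:
            self.median = np.median(stats, axis=0)
        if self.mad is None:
            self.mad = np.median(np.abs(stats - self.median), axis=0)

    def stats_matrix(self) -> np.ndarray:
        return self.table[self.stat_names].to_numpy(dtype=float)

    def normalized_stats(self) -> np.ndarray:
        return self._normalize(self.stats_matrix())

    def _normalize(self, stats: np.ndarray) -> np.ndarray:
        scale = np.where(self.mad > 0, self.mad, 1.0)
        return (stats - self.median) / scale

    @property
    def usable_stats(self) -> np.ndarray:
        """Mask of statistics with non-zero spread (zero-MAD excluded)."""
        return self.mad > 0

    def save(self, path: str | Path) -> None:
        head = (f"# rookery-reference-table-v1\tstats="
                f"{','.join(self.stat_names)}\tscenarios="
                f"{','.join(self.scenario_ids)}\n")
        with open(path, "w") as fh:
            fh.write(head)
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceTable":
        with open(path) as fh:
            head = fh.readline()
            if not head.startswith("# rookery-reference-table-v1"):
                raise ValueError("not a rookery reference table")
            fields = dict(p.split("=", 1) for p in head.strip().split("\t")[1:])
            df = pd.read_csv(fh, sep="\t")
        stat_names = fields["stats"].split(",")
        scen = fields["scenarios"].split(",")
        params = [c for c in df.columns
                  if c != "scenario" and c not in stat_names]
        return cls(df, stat_names, params, scen)


def build_reference_table(scenarios: dict[str, ScenarioSpec] | list[ScenarioSpec],
                          n_per_scenario: int, seed: int,
                          extended: bool = False,
                          workers: int = 1) -> ReferenceTable:
    """Simulate *n_per_scenario* datasets per scenario into a reference table.

    Row seeds are derived deterministically from ``(seed, row index)``, so a
    rebuild with the same arguments is identical and the table can be
    extended reproducibly.  A failing simulation is retried with a derived
    seed (and a warning).  ``workers`` is accepted for interface stability;
    the builder is serial, which is the reproducible and portable default.
    """
    if isinstance(scenarios, dict):
        scen_list = list(scenarios.values())
    else:
        scen_list = list(scenarios)
    for s in scen_list:
        validate_scenario(s)
    demes0 = sorted(scen_list[0].sampled_demes)
    for s in scen_list[1:]:
        if sorted(s.sampled_demes) != demes0:
            raise ValueError("scenarios must share sampled-deme structure")
    stat_names = stat_names_for(demes0, extended)
    rows = []
    global_idx = 0
    for s in scen_list:
        for _ in range(n_per_scenario):
            row_seed = (seed * 1_000_003 + global_idx) % (2 ** 31 - 1)
            global_idx += 1
            for attempt in range(3):
                try:
                    ds = simulate_dataset(s, row_seed + attempt * 7_654_321)
                    stats = summarize_for_abc(ds, extended=extended)
                    break
                except Exception as exc:   # pragma: no cover - defensive
                    if attempt == 2:
                        raise
                    warnings.warn(f"simulation retry for {s.name}: {exc}")
            rec = {"scenario": s.name}
            rec.update(_flatten_draw(s, ds.params))
            rec.update(dict(zip(stat_names, stats)))
            rows.append(rec)
    df = pd.DataFrame(rows)
    params = [c for c in df.columns if c != "scenario" and c not in stat_names]
    return ReferenceTable(df, stat_names, params, [s.name for s in scen_list])


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

def rejection_rank(rt: ReferenceTable, observed: np.ndarray, n_keep: int):
    """Indices and distances of the *n_keep* simulations nearest to the
    observed statistics (Euclidean on median/MAD-normalised stats;
    zero-MAD statistics are excluded from the distance; ties broken by row
    index)."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (len(rt.stat_names),):
        raise ValueError("observed vector has wrong dimensionality")
    use = rt.usable_stats
    z = rt.normalized_stats()[:, use]
    zo = rt._normalize(observed[None, :])[0, use]
    d = np.sqrt(((z - zo) ** 2).sum(axis=1))
    n_keep = min(n_keep, len(d))
    order = np.lexsort((np.arange(len(d)), d))[:n_keep]
    return order, d[order]


# ---------------------------------------------------------------------------
# Multinomial logistic model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    """Posterior scenario probabilities and logistic-fit quality per
    retained-set size."""
    n_grid: list[int]
    scenario_ids: list[str]
    probs: pd.DataFrame            # index n, columns scenario
    r2: pd.Series                  # McFadden pseudo-R^2 per n
    prob_ci: pd.DataFrame          # columns (scenario, lo/hi)
    r2_ci: pd.DataFrame            # columns lo/hi
    selected: str
    non_overlapping: bool
    fallback: dict[int, bool]


def _fit_multinomial(z: np.ndarray, labels: np.ndarray, zo: np.ndarray,
                     classes: list[str]):
    """Fit an (unpenalised) multinomial logit; returns (probs at observed in
    *classes* order, McFadden R^2, fallback flag)."""
    present = [c for c in classes if (labels == c).any()]
    freqs = np.array([(labels == c).mean() for c in classes])
    if len(present) < 2:
        return freqs, float("nan"), True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = LogisticRegression(C=np.inf, max_iter=500, tol=1e-6)
            clf.fit(z, labels)
        p_obs = clf.predict_proba(zo[None, :])[0]
        ll = -_log_loss_sum(clf, z, labels)
        ll0 = float(np.sum([np.log(freqs[classes.index(c)]) for c in labels]))
        r2 = 1.0 - ll / ll0 if ll0 != 0 else float("nan")
        out = np.zeros(len(classes))
        for j, c in enumerate(clf.classes_):
            out[classes.index(c)] = p_obs[j]
        return out, float(r2), False
    except Exception:
        return freqs, float("nan"), True


def _log_loss_sum(clf, z, labels):
    proba = clf.predict_proba(z)
    idx = {c: j for j, c in enumerate(clf.classes_)}
    rows = np.arange(len(labels))
    cols = np.array([idx[c] for c in labels])
    return -float(np.sum(np.log(np.maximum(proba[rows, cols], 1e-300))))


def logistic_model_choice(rt: ReferenceTable, observed: np.ndarray,
                          n_grid=DEFAULT_N_GRID, n_boot: int = 500,
                          seed: int = 0) -> ModelChoiceResult:
    """Posterior scenario probabilities by multinomial logistic regression.

    For each retained-set size in *n_grid*, the *n* nearest simulations are
    found by :func:`rejection_rank`, scenario identity is regressed on the
    normalised statistics, and the fitted probability at the observed vector
    is the scenario's posterior probability.  Fit quality per n is McFadden's
    pseudo-R^2; confidence intervals come from bootstrap resampling of the
    retained set.  The selected scenario maximises the posterior probability
    at the largest n; ``non_overlapping`` records whether its bootstrap band
    is clear of the runner-up's there (the non-overlap criterion used to
    star a choice).  Complete separation or a single-scenario retained set
    falls back to within-set scenario frequencies, flagged per n.
    """
    rng = np.random.default_rng(seed)
    classes = list(rt.scenario_ids)
    use = rt.usable_stats
    z_all = rt.normalized_stats()[:, use]
    zo = rt._normalize(np.asarray(observed, float)[None, :])[0, use]
    labels_all = rt.table["scenario"].to_numpy()
    n_grid = sorted(int(n) for n in n_grid)
    probs, r2s, fallback = {}, {}, {}
    prob_ci_rows, r2_ci_rows = [], []
    for n in n_grid:
        idx, _ = rejection_rank(rt, observed, n)
        z, labels = z_all[idx], labels_all[idx]
        p, r2, fb = _fit_multinomial(z, labels, zo, classes)
        probs[n], r2s[n], fallback[n] = p, r2, fb
        if n_boot > 0:
            bp = np.empty((n_boot, len(classes)))
            br = np.empty(n_boot)
            for b in range(n_boot):
                bix = rng.integers(0, len(idx), size=len(idx))
                pb, rb, _ = _fit_multinomial(z[bix], labels[bix], zo, classes)
                bp[b], br[b] = pb, rb
            lo, hi = np.nanpercentile(bp, [2.5, 97.5], axis=0)
            prob_ci_rows.append((n, lo, hi))
            r2lo, r2hi = np.nanpercentile(br, [2.5, 97.5])
            r2_ci_rows.append((n, r2lo, r2hi))
    probs_df = pd.DataFrame(probs, index=classes).T
    r2_s = pd.Series(r2s, name="r2")
    if prob_ci_rows:
        prob_ci = pd.DataFrame(
            {(c, side): [row[1 + k][j] for row in prob_ci_rows]
             for j, c in enumerate(classes)
             for k, side in enumerate(["lo", "hi"])},
            index=[row[0] for row in prob_ci_rows])
        r2_ci = pd.DataFrame([(r[1], r[2]) for r in r2_ci_rows],
                             index=[r[0] for r in r2_ci_rows],
                             columns=["lo", "hi"])
    else:
        prob_ci = pd.DataFrame(index=n_grid)
        r2_ci = pd.DataFrame(index=n_grid, columns=["lo", "hi"])
    n_max = n_grid[-1]
    order = np.argsort(probs_df.loc[n_max].to_numpy())[::-1]
    selected = classes[order[0]]
    runner = classes[order[1]] if len(classes) > 1 else None
    non_overlap = False
    if runner is not None and prob_ci_rows:
        non_overlap = bool(prob_ci.loc[n_max, (selected, "lo")]
                           > prob_ci.loc[n_max, (runner, "hi")])
    return ModelChoiceResult(n_grid, classes, probs_df, r2_s, prob_ci, r2_ci,
                             selected, non_overlap, fallback)


# ---------------------------------------------------------------------------
# Posterior parameter estimation
# ---------------------------------------------------------------------------

def posterior_parameters(rt: ReferenceTable, observed: np.ndarray,
                         scenario: str, n_keep: int = 2000,
                         params: list[str] | None = None,
                         log_transform: bool = True) -> pd.DataFrame:
    """Local-linear regression-adjusted posterior for a chosen scenario.

    Within the *n_keep* retained simulations of *scenario*, each parameter is
    regressed on the normalised statistics with Epanechnikov weights in
    distance; draws are adjusted to the observed vector
    (theta_i - (S_i - s_obs) @ beta) and summarised by the weighted median
    and the weighted 90% interval.  Strictly positive parameters are
    adjusted on the log scale by default (the adjustment then cannot leave
    the support, which markedly improves interval calibration).  A
    rank-deficient regression falls back to the unadjusted rejection
    posterior, flagged in the ``adjusted`` column.
    """
    sub_idx = np.flatnonzero(rt.table["scenario"].to_numpy() == scenario)
    if len(sub_idx) == 0:
        raise ValueError(f"no rows for scenario {scenario!r}")
    sub = ReferenceTable(rt.table.iloc[sub_idx].reset_index(drop=True),
                         rt.stat_names, rt.param_names, [scenario],
                         median=rt.median, mad=rt.mad)
    idx, d = rejection_rank(sub, observed, n_keep)
    use = sub.usable_stats
    z = sub.normalized_stats()[idx][:, use]
    zo = sub._normalize(np.asarray(observed, float)[None, :])[0, use]
    d_max = d.max() if d.max() > 0 else 1.0
    w = 1.0 - (d / d_max) ** 2
    w = np.maximum(w, 1e-8)
    if params is None:
        params = [p for p in rt.param_names
                  if rt.table[p].iloc[sub_idx].notna().all()]
    x = np.column_stack([np.ones(len(idx)), z - zo])
    sw = np.sqrt(w)
    rows = []
    for p in params:
        theta = sub.table[p].to_numpy(dtype=float)[idx]
        use_log = log_transform and (theta > 0).all()
        work = np.log(theta) if use_log else theta
        adjusted = True
        try:
            coef, *_ = np.linalg.lstsq(x * sw[:, None], work * sw, rcond=None)
            rank = np.linalg.matrix_rank(x * sw[:, None])
            if rank < x.shape[1]:
                raise np.linalg.LinAlgError("rank deficient")
            theta_adj = work - (z - zo) @ coef[1:]
            if use_log:
                theta_adj = np.exp(theta_adj)
        except np.linalg.LinAlgError:
            theta_adj = theta
            adjusted = False
        med = _weighted_quantile(theta_adj, w, 0.5)
        lo = _weighted_quantile(theta_adj, w, 0.05)
        hi = _weighted_quantile(theta_adj, w, 0.95)
        rows.append({"param": p, "median": med, "q05": lo, "q95": hi,
                     "adjusted": adjusted})
    return pd.DataFrame(rows).set_index("param")


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cw = np.cumsum(ws)
    cw = (cw - 0.5 * ws) / cw[-1]
    return float(np.interp(q, cw, xs))


# ---------------------------------------------------------------------------
# Prior predictive check
# ---------------------------------------------------------------------------

def prior_predictive_check(rt: ReferenceTable,
                           observed: np.ndarray) -> pd.DataFrame:
    """Percentile of each observed statistic within each scenario's simulated
    prior distribution (midpoint convention for ties); the ``extreme``
    column flags percentiles outside [0.5, 99.5], i.e. observed data the
    scenario essentially never produces."""
    observed = np.asarray(observed, dtype=float)
    if len(rt.table) == 0:
        raise ValueError("empty reference table")
    if observed.shape != (len(rt.stat_names),):
        raise ValueError("observed vector has wrong dimensionality")
    rows = []
    for scen in rt.scenario_ids:
        sub = rt.table[rt.table["scenario"] == scen]
        stats = sub[rt.stat_names].to_numpy(dtype=float)
        for j, name in enumerate(rt.stat_names):
            col = stats[:, j]
            pct = 100.0 * (np.sum(col < observed[j])
                           + 0.5 * np.sum(col == observed[j])) / len(col)
            rows.append({"scenario": scen, "stat": name,
                         "observed": observed[j], "percentile": pct,
                         "extreme": not (0.5 <= pct <= 99.5)})
    df = pd.DataFrame(rows)
    n_extreme = int(df["extreme"].sum())
    if n_extreme:
        warnings.warn(f"{n_extreme} observed statistics fall outside the "
                      "[0.5, 99.5] percentile band of a scenario's prior "
                      "predictive distribution")
    return df
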