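"""Regional gene-flow analyses.

Consumes externally produced mutation-scaled population sizes (theta) and
directed migration rates (M) — e.g. from a structured-coalescent MCMC — and
turns them into effective numbers of immigrants per generation
(ENI = theta_average * M_average / 2), a direction-by-distance linear model
of migration, the East-West gradient of average pairwise F_ST, and
great-circle distance matrices from unit coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "GeneFlowEstimates",
    "eni",
    "read_theta_m",
    "gene_flow_estimates",
    "migration_direction_model",
    "fst_gradient",
    "greatcircle_matrix",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0


def eni(theta_avg: float, m_avg: float) -> float:
    """Effective number of immigrants per generation:
    (theta_average * M_average) / 2.  Inputs must be non-negative and are
    run-averaged *before* the product (averaging order matters and is
    pinned here)."""
    if theta_avg < 0 or m_avg < 0:
        raise ValueError("theta and M must be non-negative")
    return theta_avg * m_avg / 2.0


@dataclass
class GeneFlowEstimates:
    """Directed gene-flow table: one row per ordered deme pair with
    run-averaged theta and M, the derived ENI, great-circle distance and
    longitudinal direction."""
    table: pd.DataFrame   # columns: from, to, theta, M, eni, distance_km, direction

    def eni_matrix(self) -> pd.DataFrame:
        units = sorted(set(self.table["from"]) | set(self.table["to"]))
        mat = pd.DataFrame(0.0, index=units, columns=units)
        for _, r in self.table.iterrows():
            mat.loc[r["from"], r["to"]] = r["eni"]
        return mat


def read_theta_m(path) -> pd.DataFrame:
    """Read the external estimator's output: TSV with header
    ``from to theta_from theta_to M run_id`` (one row per ordered pair per
    replicate run)."""
    df = pd.read_csv(path, sep="\t", dtype={"from": str, "to": str})
    needed = {"from", "to", "theta_from", "theta_to", "M", "run_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"theta/M table lacks columns: {sorted(missing)}")
    return df


def gene_flow_estimates(theta_m: pd.DataFrame,
                        unit_coords: dict[str, tuple[float, float]],
                        theta: str = "to") -> GeneFlowEstimates:
    """Average theta and M across replicate runs, then form ENI per ordered
    pair and attach distance and direction.

    ``theta`` selects which deme's theta enters the product: ``"to"`` (the
    receiving deme, default — immigrants are counted where they arrive) or
    ``"mean"`` of the two ends.  Direction of the ordered pair (i -> j) is
    ``westwards`` iff lon_j < lon_i (meridian crossing not handled; this is
    an archipelago-scale convention).
    """
    rows = []
    for (src, dst), grp in theta_m.groupby(["from", "to"]):
        m_avg = float(grp["M"].mean())
        if theta == "to":
            th_avg = float(grp["theta_to"].mean())
        elif theta == "mean":
            th_avg = float((grp["theta_from"].mean()
                            + grp["theta_to"].mean()) / 2.0)
        else:
            raise ValueError("theta must be 'to' or 'mean'")
        if src not in unit_coords or dst not in unit_coords:
            missing = [u for u in (src, dst) if u not in unit_coords]
            raise ValueError(f"missing coordinates for unit(s): {missing}")
        lon_s, lat_s = unit_coords[src]
        lon_d, lat_d = unit_coords[dst]
        rows.append({
            "from": src, "to": dst, "theta": th_avg, "M": m_avg,
            "eni": eni(th_avg, m_avg),
            "distance_km": haversine_km(lon_s, lat_s, lon_d, lat_d),
            "direction": "westwards" if lon_d < lon_s else "eastwards",
        })
    return GeneFlowEstimates(pd.DataFrame(rows))


def migration_direction_model(g: GeneFlowEstimates | pd.DataFrame):
    """Linear model log(ENI) ~ log(distance) x direction.

    Ordered pairs with ENI = 0 are dropped with a warning (log undefined).
    Returns the fitted statsmodels results object; coefficients, t and p
    values are in its ``summary()``/``params``/``tvalues``/``pvalues``.
    """
    df = g.table if isinstance(g, GeneFlowEstimates) else g.copy()
    if len(df) < 6 or df["direction"].nunique() < 2:
        raise ValueError("need >= 6 ordered pairs covering both directions")
    zero = df["eni"] <= 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} pairs with ENI = 0 "
                      "(log undefined)")
        df = df[~zero]
    df = df.assign(log_eni=np.log(df["eni"]),
                   log_dist=np.log(df["distance_km"]))
    model = smf.ols("log_eni ~ log_dist * C(direction)", data=df)
    return model.fit()


def fst_gradient(fst_matrix: pd.DataFrame | np.ndarray,
                 unit_lons: dict[str, float] | np.ndarray,
                 clamp_negative: bool = True):
    """East-West gradient of average pairwise F_ST.

    Performs (1) a one-way ANOVA of pairwise F_ST values grouped by focal
    unit and (2) a linear regression of per-unit mean pairwise F_ST on the
    west-positive longitudinal axis (x = -longitude).  Negative F_ST values
    are clamped to 0 before averaging (averaging raw negatives biases the
    gradient).  Returns a dict with slope, r2, p (regression), anova_f,
    anova_p and the per-unit means.
    """
    if isinstance(fst_matrix, pd.DataFrame):
        units = list(fst_matrix.index)
        mat = fst_matrix.to_numpy(dtype=float)
        lons = np.array([unit_lons[u] for u in units])
    else:
        mat = np.asarray(fst_matrix, dtype=float)
        lons = np.asarray(unit_lons, dtype=float)
        units = [f"u{i}" for i in range(mat.shape[0])]
    k = mat.shape[0]
    if k < 4:
        raise ValueError("need at least 4 units")
    if clamp_negative:
        mat = np.maximum(mat, 0.0)
    groups = [np.delete(mat[i], i) for i in range(k)]
    means = np.array([g.mean() for g in groups])
    if np.allclose(means, means[0]):
        # constant F_ST: no gradient; R^2 of any regression is 0 and the
        # test statistics are undefined
        return {"slope": 0.0, "r2": 0.0, "p": float("nan"),
                "anova_f": float("nan"), "anova_p": float("nan"),
                "unit_means": pd.Series(means, index=units)}
    anova_f, anova_p = sps.f_oneway(*groups)
    x = sm.add_constant(-lons)   # west-positive axis
    fit = sm.OLS(means, x).fit()
    return {
        "slope": float(fit.params[1]),
        "r2": float(fit.rsquared),
        "p": float(fit.pvalues[1]),
        "anova_f": float(anova_f),
        "anova_p": float(anova_p),
        "unit_means": pd.Series(means, index=units),
        "fit": fit,
    }


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance (haversine, Earth radius 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def greatcircle_matrix(unit_coords: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Symmetric great-circle distance matrix (km) from unit coordinates."""
    units = list(unit_coords)
    bad = [u for u, c in unit_coords.items()
           if c is None or any(v is None or not np.isfinite(v) for v in c)]
    if bad:
        raise ValueError(f"missing coordinates for unit(s): {bad}")
    mat = pd.DataFrame(0.0, index=units, columns=units)
    for i, u in enumerate(units):
        for v in units[i + 1:]:
            d = haversine_km(*unit_coords[u], *unit_coords[v])
            mat.loc[u, v] = mat.loc[v, u] = d
    return mat
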