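"""Results-layer statistics: scale scans, the bell-curve stability model and
two-state equilibrium classification.

Three questions are asked of the proxy table and the multi-scale terrain
attributes:

1. Which terrain attributes correlate with the stability proxies and the
   background factors (meanSOC, meanSWC), and at which smoothing scales?
   Plain Pearson correlations with two-sided p-values, significant at
   p < 0.05, no multiplicity correction (an optional Benjamini-Hochberg
   flag exists but is off by default to match the per-test reporting
   convention of field studies at this n).
2. Does response amplitude peak at intermediate activity?  The bell-curve
   model  rangeRs = a * N(rankRs; mu, sigma)  with N the Gaussian density;
   mu and sigma default to the sample moments of rankRs, leaving the scale
   parameter a as the single free coefficient (closed-form least squares).
3. Which positions sit in an equilibrium state?  State I = persistently
   high-activity positions (rank group L), state II = persistently
   low-activity positions (rank group S); both are resistant (small
   rangeRs).  The M middle group is the resilient remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .terrain import ATTRIBUTE_NAMES

__all__ = [
    "SITE_CLIMATE",
    "REFERENCE_PRECIP_MM",
    "precipitation_anomaly_pct",
    "correlation_scan",
    "classify_scale_dependence",
    "BellCurveFit",
    "fit_bell_curve",
    "classify_states",
]

#: yearly meteorology and net ecosystem exchange of the emulated site
#: (year, mean air temperature degC, precipitation sum mm, NEE g C m-2 yr-1)
SITE_CLIMATE = pd.DataFrame(
    {
        "year": [2012, 2013, 2014, 2015, 2016, 2017, 2018],
        "air_temp_c": [10.7, 10.8, 11.4, 11.2, 10.6, 10.7, 11.7],
        "precip_mm": [431, 590, 813, 523, 584, 654, 578],
        "nee_gc_m2": [37.9, -63.5, -38.4, -79.8, -79.5, -49.8, -39.1],
    }
)

#: fifteen-year mean annual precipitation of the site (mm)
REFERENCE_PRECIP_MM = 585.0


def precipitation_anomaly_pct(annual_mm: float, reference_mm: float = REFERENCE_PRECIP_MM) -> int:
    """Percent deviation of an annual precipitation sum from the long-term mean,
    rounded to the integer percent (e.g. 813 mm vs 585 mm -> +39)."""
    if reference_mm <= 0:
        raise ValueError("reference precipitation must be positive")
    return int(round((annual_mm - reference_mm) / reference_mm * 100.0))


# ----------------------------------------------------------- correlation scan
_BACKGROUND = ("meanSOC", "meanSWC")
_PROXIES = ("rankRs", "rangeRs")


def _subgroup_masks(table: pd.DataFrame) -> dict[str, pd.Series]:
    masks = {"A": pd.Series(True, index=table.index)}
    if "rank_group" in table:
        for g in ("S", "M", "L"):
            masks[g] = table["rank_group"] == g
    if "soc_group" in table:
        for g in ("C1", "C2", "C3", "C4", "C5"):
            masks[g] = table["soc_group"] == g
    return masks


def correlation_scan(
    table: pd.DataFrame,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
    y_vars: tuple[str, ...] = _PROXIES + _BACKGROUND,
    alpha: float = 0.05,
    min_group_size: int = 3,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson r / p for every (variable x terrain attribute x level x subgroup).

    ``table`` is the proxy table merged with the terrain extraction table
    (columns like ``TPI_L3``).  Proxy-vs-background pairs (rankRs vs meanSOC
    etc.) are scanned too and reported with level 0.  Subgroups smaller than
    ``min_group_size`` are skipped with a warning; zero-variance pairs give an
    undefined (NaN) record.
    """
    pairs: list[tuple[str, str, int]] = []
    for y in y_vars:
        for level in levels:
            for attr in ATTRIBUTE_NAMES:
                col = f"{attr}_L{level}"
                if col in table:
                    pairs.append((y, col, level))
    for y in _PROXIES:
        for x in _BACKGROUND:
            if y in table and x in table:
                pairs.append((y, x, 0))

    records = []
    for gname, mask in _subgroup_masks(table).items():
        sub = table[mask]
        if len(sub) < min_group_size:
            warnings.warn(f"subgroup {gname} has {len(sub)} positions; skipped", stacklevel=2)
            continue
        for y, xcol, level in pairs:
            xy = sub[[y, xcol]].dropna()
            attr = xcol.split("_L")[0] if level else xcol
            rec = {
                "variable": y,
                "attribute": attr,
                "level": level,
                "subgroup": gname,
                "n": len(xy),
            }
            if len(xy) < min_group_size or xy[y].nunique() < 2 or xy[xcol].nunique() < 2:
                rec.update(r=np.nan, r2=np.nan, p=np.nan, sign="undefined")
            else:
                r, p = stats.pearsonr(xy[xcol], xy[y])
                rec.update(r=r, r2=r**2, p=p, sign="pos" if r > 0 else "neg")
            records.append(rec)
    out = pd.DataFrame(records)
    if bh_correct and len(out):
        ok = out["p"].notna()
        out.loc[ok, "p_adj"] = _benjamini_hochberg(out.loc[ok, "p"].to_numpy())
        out["significant"] = out.get("p_adj", out["p"]) < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_i, idx in enumerate(order[::-1]):
        k = m - rank_i
        prev = min(prev, p[idx] * m / k)
        adj[idx] = prev
    return adj


def classify_scale_dependence(
    records: pd.DataFrame, levels: tuple[int, ...] = (1, 2, 3, 4, 5)
) -> pd.DataFrame:
    """Label each (variable, attribute, subgroup) by the scale reach of its
    correlation: significant at every level with a consistent sign ->
    ``scale_independent``; significant exactly at the less-smoothed levels
    {1,2} or {1,2,3} -> ``less_smooth_only``; anything else -> ``none``."""
    terr = records[records["level"].isin(levels)]
    out = []
    for (y, attr, grp), chunk in terr.groupby(["variable", "attribute", "subgroup"]):
        have = set(chunk["level"])
        if not set(levels) <= have:
            raise ValueError(
                f"records for {y}-{attr} in {grp} miss levels {sorted(set(levels) - have)}"
            )
        sig = chunk[chunk["significant"].fillna(False)]
        sig_levels = set(sig["level"])
        consistent = sig["sign"].nunique() <= 1
        if sig_levels == set(levels) and consistent:
            cls = "scale_independent"
        elif sig_levels in ({1, 2}, {1, 2, 3}) and consistent:
            cls = "less_smooth_only"
        else:
            cls = "none"
        out.append(
            {
                "variable": y,
                "attribute": attr,
                "subgroup": grp,
                "class": cls,
                "levels_significant": tuple(sorted(sig_levels)),
                "sign": sig["sign"].iloc[0] if len(sig) and consistent else None,
            }
        )
    return pd.DataFrame(out)


# ------------------------------------------------------------------ bell fit
@dataclass
class BellCurveFit:
    """Least-squares fit of rangeRs = a * N(rankRs; mu, sigma)."""

    a: float
    mu: float
    sigma: float
    fixed_moments: bool
    n: int
    ss_res: float
    ss_tot: float
    a_se: float
    f_stat: float
    f_pvalue: float
    a_pvalue: float
    degenerate: bool = False

    @property
    def peak_height(self) -> float:
        """Fitted rangeRs at the mode rankRs = mu."""
        return self.a / (self.sigma * np.sqrt(2 * np.pi))

    def predict(self, rank_rs: np.ndarray) -> np.ndarray:
        return self.a * stats.norm.pdf(np.asarray(rank_rs, float), self.mu, self.sigma)

    def summary(self) -> str:
        mode = "fixed moments" if self.fixed_moments else "free moments"
        lines = [
            f"Bell-curve stability model ({mode}, n = {self.n})",
            f"  a     = {self.a:12.4f}  (SE {self.a_se:.4f}, p = {self.a_pvalue:.3g})",
            f"  mu    = {self.mu:12.4f}",
            f"  sigma = {self.sigma:12.4f}",
            f"  peak rangeRs at mode = {self.peak_height:.3f}",
            f"  F vs constant model  = {self.f_stat:.3f} (p = {self.f_pvalue:.3g})",
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate fit (constant rangeRs)")
        return "\n".join(lines)


def fit_bell_curve(
    rank_rs: np.ndarray, range_rs: np.ndarray, fix_moments: bool = True
) -> BellCurveFit:
    """Fit the Gaussian-shaped amplitude-vs-activity relation.

    With ``fix_moments`` (the default) mu and sigma are the sample mean and SD
    of rankRs and the closed-form least-squares scale is
    a = sum(y_i g_i) / sum(g_i^2) with g_i the Gaussian density at rankRs_i.
    Otherwise all three parameters are fitted by nonlinear least squares
    initialized at the moment solution.  Fit significance is an F-test
    against the constant (mean-only) model; a gets a Wald t-test.
    """
    x = np.asarray(rank_rs, dtype=float)
    y = np.asarray(range_rs, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 positions to fit the bell curve")
    mu0, sigma0 = float(x.mean()), float(x.std(ddof=1))
    if sigma0 <= 0:
        raise ValueError("rankRs has zero variance; sigma undefined")
    degenerate = bool(np.ptp(y) == 0)

    def closed_form_a(mu, sigma):
        g = stats.norm.pdf(x, mu, sigma)
        return float(np.sum(y * g) / np.sum(g**2)), g

    if fix_moments:
        mu, sigma = mu0, sigma0
        a, g = closed_form_a(mu, sigma)
        n_params = 1
    else:
        a0, _ = closed_form_a(mu0, sigma0)

        def model(xx, a_, mu_, sigma_):
            return a_ * stats.norm.pdf(xx, mu_, sigma_)

        popt, _ = optimize.curve_fit(
            model, x, y, p0=[a0, mu0, sigma0], maxfev=20000,
            bounds=([-np.inf, x.min() - 3 * sigma0, 1e-9], [np.inf, x.max() + 3 * sigma0, np.inf]),
        )
        a, mu, sigma = (float(v) for v in popt)
        g = stats.norm.pdf(x, mu, sigma)
        n_params = 3

    resid = y - a * g
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = n - n_params - 1
    s2 = ss_res / max(dof, 1)
    a_se = float(np.sqrt(s2 / np.sum(g**2)))
    a_t = a / a_se if a_se > 0 else np.inf
    a_p = float(2 * stats.t.sf(abs(a_t), max(dof, 1)))
    q = max(n_params, 1)
    if ss_res > 0 and ss_tot > ss_res:
        f = ((ss_tot - ss_res) / q) / (ss_res / max(dof, 1))
        f_p = float(stats.f.sf(f, q, max(dof, 1)))
    elif ss_tot <= ss_res:
        f, f_p = 0.0, 1.0
    else:
        f, f_p = np.inf, 0.0
    return BellCurveFit(
        a=a, mu=mu, sigma=sigma, fixed_moments=fix_moments, n=n,
        ss_res=ss_res, ss_tot=ss_tot, a_se=a_se,
        f_stat=float(f), f_pvalue=f_p, a_pvalue=a_p, degenerate=degenerate,
    )


# ---------------------------------------------------------------- state classes
_STATE_BY_GROUP = {"L": "I", "S": "II", "M": "intermediate"}
_STATE_SUMMARY_VARS = ("rankRs", "rangeRs", "meanSOC", "meanSWC")


def classify_states(
    proxy_table: pd.DataFrame, terrain_table: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-state equilibrium assignment from the rank groups.

    State I: persistently high activity (rank group L; expected at lower
    elevations with high meanSOC / meanSWC).  State II: persistently low
    activity (rank group S; expected on local ridges).  M positions are the
    resilient intermediate pool.  Returns (assignment, per-state summary of
    the proxies, background factors and any terrain attribute columns).
    """
    if "rank_group" not in proxy_table:
        raise ValueError("proxy table lacks rank_group; run compute_proxies first")
    table = proxy_table.copy()
    if terrain_table is not None:
        table = table.merge(
            terrain_table.drop(columns=["x", "y"], errors="ignore"), on="position_id"
        )
    table["state"] = table["rank_group"].map(_STATE_BY_GROUP)
    summary_cols = [c for c in _STATE_SUMMARY_VARS if c in table]
    summary_cols += [
        c
        for c in table.columns
        if any(c.startswith(f"{a}_L") for a in ("mALT", "TPI", "SD", "Sl"))
    ]
    summary = table.groupby("state")[summary_cols].mean()
    summary["n_positions"] = table.groupby("state").size()
    assignment = table[["position_id", "state"]].copy()
    return assignment, summary
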