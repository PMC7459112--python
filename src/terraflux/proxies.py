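"""Rank-based temporal-stability proxies for repeated spatial flux surveys.

Within each measuring campaign the positions are ranked by their soil
respiration flux (rank 1 = smallest).  Two per-position summaries over the
campaigns then separate *where* a position sits in the long-term spatial
pattern from *how much* it moves:

* ``rankRs``  — mean rank over campaigns: the persistent activity level.
* ``rangeRs`` — max rank minus min rank: the response amplitude.  Zero means
  the position held its rank through every campaign (a resistant response);
  a large value means the position swapped places with many others over time
  (a resilient response).

Both proxies are invariant under any strictly monotone transform of the flux
within a campaign, so they compare campaigns made under very different
environmental conditions without any detrending.

Positions are grouped two ways for subgroup analyses: S / M / L by rankRs
relative to mean +/- SD, and C1..C5 by quintiles of the temporal mean soil
organic carbon content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CampaignPanel",
    "rank_campaign",
    "compute_rankRs",
    "compute_rangeRs",
    "compute_temporal_means",
    "assign_rank_groups",
    "assign_soc_quintiles",
    "compute_proxies",
]

_TIE_METHODS = {"average": "average", "min": "min", "ordinal": "ordinal"}


@dataclass
class CampaignPanel:
    """Positions x campaigns measurements of Rs, Ts, SWC and (sparse) SOC.

    ``positions``: DataFrame with position_id, x, y (m).
    ``campaigns``: DataFrame with campaign_id, date.
    ``rs``/``ts``/``swc``/``soc``: wide DataFrames indexed by position_id with
    one column per campaign_id; NaN marks unobserved values (all SOC columns
    outside the SOC campaigns are NaN).
    """

    positions: pd.DataFrame
    campaigns: pd.DataFrame
    rs: pd.DataFrame
    ts: pd.DataFrame
    swc: pd.DataFrame
    soc: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rs.shape[1] < 2:
            raise ValueError("a campaign panel needs at least 2 campaigns")
        if (self.rs.to_numpy() < 0).any():
            raise ValueError("negative Rs values in panel")
        swc = self.swc.to_numpy()
        if np.nanmin(swc) < 0 or np.nanmax(swc) > 100:
            raise ValueError("SWC outside [0, 100] %")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_campaigns(self) -> int:
        return len(self.campaigns)

    # ------------------------------------------------------------------- I/O
    def to_long(self) -> pd.DataFrame:
        """Long-format table: position_id, x, y, campaign, date, rs, ts, swc, soc."""
        recs = []
        dates = dict(zip(self.campaigns["campaign_id"], self.campaigns["date"]))
        pos = self.positions.set_index("position_id")
        for cid in self.rs.columns:
            for pid in self.rs.index:
                recs.append(
                    {
                        "position_id": pid,
                        "x": pos.loc[pid, "x"],
                        "y": pos.loc[pid, "y"],
                        "campaign": cid,
                        "date": dates[cid],
                        "rs": self.rs.loc[pid, cid],
                        "ts": self.ts.loc[pid, cid],
                        "swc": self.swc.loc[pid, cid],
                        "soc": self.soc.loc[pid, cid],
                    }
                )
        return pd.DataFrame(recs)

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "CampaignPanel":
        positions = (
            table[["position_id", "x", "y"]].drop_duplicates("position_id").reset_index(drop=True)
        )
        campaigns = (
            table[["campaign", "date"]]
            .drop_duplicates("campaign")
            .rename(columns={"campaign": "campaign_id"})
            .reset_index(drop=True)
        )
        wide = lambda col: table.pivot(index="position_id", columns="campaign", values=col)
        return cls(positions, campaigns, wide("rs"), wide("ts"), wide("swc"), wide("soc"))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long().to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "CampaignPanel":
        return cls.from_long(pd.read_csv(path))


# ------------------------------------------------------------------ ranking
def rank_campaign(values: np.ndarray, ties: str = "average") -> np.ndarray:
    """Ascending ranks 1..n among non-missing values; ties share the mean rank.

    Missing values stay missing and do not consume a rank, so each campaign
    is ranked within the positions actually measured.
    """
    values = np.asarray(values, dtype=float)
    if ties not in _TIE_METHODS:
        raise ValueError(f"ties must be one of {sorted(_TIE_METHODS)}")
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("cannot rank an all-missing campaign")
    out = np.full(values.shape, np.nan)
    out[finite] = rankdata(values[finite], method=_TIE_METHODS[ties])
    return out


def _rank_matrix(panel: CampaignPanel, ties: str) -> pd.DataFrame:
    ranks = {
        cid: rank_campaign(panel.rs[cid].to_numpy(), ties) for cid in panel.rs.columns
    }
    return pd.DataFrame(ranks, index=panel.rs.index)


def compute_rankRs(panel: CampaignPanel, ties: str = "average") -> pd.Series:
    """Mean of the within-campaign ranks per position, over observed campaigns."""
    rk = _rank_matrix(panel, ties)
    return rk.mean(axis=1, skipna=True).rename("rankRs")


def compute_rangeRs(panel: CampaignPanel, ties: str = "average") -> pd.Series:
    """Max minus min within-campaign rank per position, over observed campaigns."""
    rk = _rank_matrix(panel, ties)
    return (rk.max(axis=1) - rk.min(axis=1)).rename("rangeRs")


def compute_temporal_means(panel: CampaignPanel) -> pd.DataFrame:
    """Per-position meanSOC and meanSWC over the campaigns where each was observed."""
    return pd.DataFrame(
        {
            "meanSOC": panel.soc.mean(axis=1, skipna=True),
            "meanSWC": panel.swc.mean(axis=1, skipna=True),
        }
    )


# ----------------------------------------------------------------- grouping
def assign_rank_groups(rank_rs: pd.Series) -> pd.Series:
    """S / M / L by rankRs below mean-SD / within mean+/-SD / above mean+SD.

    The M interval is closed, so values exactly at a threshold are M.  With
    zero variance every position is M.
    """
    if len(rank_rs) < 3:
        raise ValueError("need at least 3 positions for S/M/L groups")
    mu = rank_rs.mean()
    sd = rank_rs.std(ddof=1)
    out = pd.Series("M", index=rank_rs.index, name="rank_group")
    if sd > 0:
        out[rank_rs < mu - sd] = "S"
        out[rank_rs > mu + sd] = "L"
    out[rank_rs.isna()] = np.nan
    return out


def assign_soc_quintiles(mean_soc: pd.Series) -> pd.Series:
    """C1..C5 by meanSOC quintile, smallest to largest.

    Membership is by ordinal rank: positions are sorted by (meanSOC, position
    order) and position at sort index i of n goes to quintile
    floor(5*i/n) + 1, so ties are broken stably by position index and the
    assignment is invariant under monotone transforms of meanSOC.
    """
    vals = mean_soc.dropna()
    if len(vals) < 5:
        raise ValueError("need at least 5 positions with meanSOC for quintiles")
    if vals.nunique() < 5:
        dupes = vals[vals.duplicated(keep=False)].unique()
        raise ValueError(
            f"fewer than 5 distinct meanSOC values; duplicated values: {sorted(dupes)}"
        )
    order = np.argsort(vals.to_numpy(), kind="stable")
    n = len(vals)
    q = np.empty(n, dtype=int)
    q[order] = np.floor(5 * np.arange(n) / n).astype(int)
    out = pd.Series(np.nan, index=mean_soc.index, dtype=object, name="soc_group")
    out[vals.index] = [f"C{g + 1}" for g in q]
    return out


def compute_proxies(panel: CampaignPanel, ties: str = "average") -> pd.DataFrame:
    """Full per-position proxy table with subgroup labels.

    Columns: position_id, x, y, rankRs, rangeRs, meanSOC, meanSWC,
    rank_group, soc_group.
    """
    out = panel.positions.set_index("position_id")[["x", "y"]].copy()
    out["rankRs"] = compute_rankRs(panel, ties)
    out["rangeRs"] = compute_rangeRs(panel, ties)
    means = compute_temporal_means(panel)
    out["meanSOC"] = means["meanSOC"]
    out["meanSWC"] = means["meanSWC"]
    out["rank_group"] = assign_rank_groups(out["rankRs"])
    out["soc_group"] = assign_soc_quintiles(out["meanSOC"])
    return out.reset_index()
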