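"""Model/Results interface tying the proxy, terrain and analysis layers together.

``SoilRespirationStability`` is constructed from a campaign panel (and
optionally a terrain-attribute extraction); ``fit()`` computes the stability
proxies, subgroup labels, the scale-dependent correlation scan, the
bell-curve model and the two-state classification, returning a
``StabilityResults`` object with a printable ``summary()``.

Example
-------
>>> from terraflux import SoilRespirationStability
>>> model = SoilRespirationStability.from_synthetic(seed=1)
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, proxies as proxies_mod, synthetic, terrain as terrain_mod
from .proxies import CampaignPanel
from .raster import ElevationRaster
from .terrain import TerrainAttributeStack

__all__ = ["SoilRespirationStability", "StabilityResults"]


@dataclass
class StabilityResults:
    """Estimates and diagnostics of a fitted stability analysis."""

    proxy_table: pd.DataFrame
    merged_table: pd.DataFrame
    correlations: pd.DataFrame | None
    scale_classes: pd.DataFrame | None
    bell: analysis.BellCurveFit
    state_assignment: pd.DataFrame
    state_summary: pd.DataFrame
    alpha: float
    n_campaigns: int = 0

    def summary(self) -> str:
        t = self.proxy_table
        lines = [
            "Soil respiration stability analysis",
            "=" * 51,
            f"positions: {len(t)}   campaigns: {self.n_campaigns}",
            f"rankRs  mean {t['rankRs'].mean():7.2f}   SD {t['rankRs'].std(ddof=1):6.2f}",
            f"rangeRs mean {t['rangeRs'].mean():7.2f}   max {t['rangeRs'].max():6.2f}",
            "",
            self.bell.summary(),
            "",
            "State occupancy:",
        ]
        for state, cnt in self.state_assignment["state"].value_counts().items():
            lines.append(f"  state {state:<13} n = {cnt}")
        if self.scale_classes is not None and len(self.scale_classes):
            si = self.scale_classes[self.scale_classes["class"] == "scale_independent"]
            ls = self.scale_classes[self.scale_classes["class"] == "less_smooth_only"]
            lines += [
                "",
                f"Correlations at p < {self.alpha} (terrain levels 1-5):",
                f"  scale-independent pairs : {len(si)}",
                f"  less-smooth-only pairs  : {len(ls)}",
            ]
        return "\n".join(lines)

    def plot_bell(self, ax=None):
        """Scatter of rangeRs vs rankRs with the fitted bell curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.proxy_table
        colors = {"S": "tab:blue", "M": "tab:grey", "L": "tab:red"}
        for grp, chunk in t.groupby("rank_group"):
            ax.scatter(chunk["rankRs"], chunk["rangeRs"], s=18,
                       color=colors.get(grp, "k"), label=grp)
        xs = np.linspace(t["rankRs"].min(), t["rankRs"].max(), 200)
        ax.plot(xs, self.bell.predict(xs), "k-", lw=1.5,
                label=f"a={self.bell.a:.0f}")
        ax.set_xlabel("rankRs (mean campaign rank)")
        ax.set_ylabel("rangeRs (rank range)")
        ax.legend(fontsize=8)
        return ax


class SoilRespirationStability:
    """Rank-based stability model of repeated soil-respiration surveys.

    Parameters
    ----------
    panel : CampaignPanel
        Positions x campaigns measurements.
    terrain_table : DataFrame, optional
        Per-position terrain attributes (columns like ``TPI_L2``); enables
        the correlation scan and richer state summaries.
    ties : {'average', 'min', 'ordinal'}
        Within-campaign rank tie rule.
    fix_moments : bool
        Fix the bell-curve mu/sigma at the sample moments of rankRs.
    alpha : float
        Significance level of the correlation scan.
    """

    def __init__(
        self,
        panel: CampaignPanel,
        terrain_table: pd.DataFrame | None = None,
        ties: str = "average",
        fix_moments: bool = True,
        alpha: float = 0.05,
    ) -> None:
        self.panel = panel
        self.terrain_table = terrain_table
        self.ties = ties
        self.fix_moments = fix_moments
        self.alpha = alpha

    # ---------------------------------------------------------- constructors
    @classmethod
    def from_dataframe(cls, long_table: pd.DataFrame, **kwargs) -> "SoilRespirationStability":
        """Build from a long-format table (position_id, x, y, campaign, date,
        rs, ts, swc, soc)."""
        return cls(CampaignPanel.from_long(long_table), **kwargs)

    @classmethod
    def from_synthetic(
        cls,
        seed: int = 0,
        max_level: int = 5,
        terrain_cfg: synthetic.TerrainConfig | None = None,
        design: synthetic.StudyDesign | None = None,
        params: synthetic.FluxModelParams | None = None,
        **kwargs,
    ) -> "SoilRespirationStability":
        """Generate a full synthetic study (terrain pyramid included)."""
        dem, _, panel = synthetic.generate_dataset(seed, terrain_cfg, design, params)
        stack = terrain_mod.build_pyramid(dem, max_level=max_level)
        extraction = terrain_mod.extract_at_positions(stack, panel.positions)
        obj = cls(panel, extraction, **kwargs)
        obj.dem = dem
        obj.stack = stack
        return obj

    @classmethod
    def from_rasters(
        cls, panel: CampaignPanel, dem: ElevationRaster, max_level: int = 5, **kwargs
    ) -> "SoilRespirationStability":
        stack = terrain_mod.build_pyramid(dem, max_level=max_level)
        extraction = terrain_mod.extract_at_positions(stack, panel.positions)
        obj = cls(panel, extraction, **kwargs)
        obj.dem = dem
        obj.stack = stack
        return obj

    # ------------------------------------------------------------------- fit
    def fit(self, levels: tuple[int, ...] = (1, 2, 3, 4, 5)) -> StabilityResults:
        proxy_table = proxies_mod.compute_proxies(self.panel, ties=self.ties)
        merged = proxy_table
        correlations = None
        scale_classes = None
        if self.terrain_table is not None:
            merged = proxy_table.merge(
                self.terrain_table.drop(columns=["x", "y"], errors="ignore"),
                on="position_id",
            )
            avail = [
                lv for lv in levels
                if any(f"{a}_L{lv}" in merged for a in terrain_mod.ATTRIBUTE_NAMES)
            ]
            correlations = analysis.correlation_scan(
                merged, levels=tuple(avail), alpha=self.alpha
            )
            if avail:
                scale_classes = analysis.classify_scale_dependence(
                    correlations, levels=tuple(avail)
                )
        bell = analysis.fit_bell_curve(
            proxy_table["rankRs"], proxy_table["rangeRs"], fix_moments=self.fix_moments
        )
        assignment, state_summary = analysis.classify_states(
            proxy_table, self.terrain_table
        )
        return StabilityResults(
            proxy_table=proxy_table,
            merged_table=merged,
            correlations=correlations,
            scale_classes=scale_classes,
            bell=bell,
            state_assignment=assignment,
            state_summary=state_summary,
            alpha=self.alpha,
            n_campaigns=self.panel.n_campaigns,
        )
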