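"""Synthetic study generator: undulating grassland terrain and flux campaigns.

Emulates the sampling design of a multi-year soil-respiration survey on a
gently undulating semi-arid grassland: a fine laser-scan DEM (0.2 m cells,
total relief capped at 1.5 m), 78 measuring positions on an 80 x 60 m grid,
15 measuring campaigns spread over spring / summer-drought / autumn
conditions, and soil organic carbon sampled on 6 of those campaigns.

The generative chain is terrain -> static soil fields -> campaign panel:

1. Terrain is correlated Gaussian noise (white noise smoothed with a
   Gaussian kernel at the configured correlation length) rescaled so the
   max-min relief equals ``relief_max`` exactly.
2. Static per-position soil fields follow the terrain: soil organic carbon
   (SOC) decreases with elevation, local elevation SD and slope and
   increases toward north- and east-facing cells; the baseline soil water
   content (SWC) decreases with elevation SD and slope.  Both get
   independent noise, so the terrain correlations are realistic, not exact.
3. Campaigns impose site-wide wetness/temperature regimes on the static
   fields.  Soil respiration responds to SOC (scaling), temperature (Q10)
   and moisture (Gaussian optimum), plus measurement noise.

The flux model is an *emulator* chosen as the minimal mechanism that
reproduces the qualitative field observations (SOC-anchored persistent
ranks, moisture-driven reordering of mid-rank positions); it is not a
calibrated ecosystem model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .proxies import CampaignPanel
from .raster import ElevationRaster
from .terrain import aggregate_dem, compute_attributes

__all__ = [
    "TerrainConfig",
    "StudyDesign",
    "FluxModelParams",
    "CAMPAIGN_DATES",
    "generate_terrain",
    "default_positions",
    "generate_soil_fields",
    "generate_campaigns",
    "generate_dataset",
]

#: the 15 field-campaign dates of the emulated survey (2012-2018, three
#: seasonal windows per year: spring, summer drought, autumn)
CAMPAIGN_DATES = (
    "2012-10-19",
    "2013-05-08",
    "2013-06-26",
    "2013-10-14",
    "2014-05-07",
    "2014-05-28",
    "2014-09-25",
    "2015-06-09",
    "2015-11-20",
    "2016-10-24",
    "2017-06-02",
    "2017-08-24",
    "2017-11-03",
    "2018-05-17",
    "2018-08-16",
)

# site-wide (wetness multiplier, soil temperature degC) per campaign;
# triplet structure mirrors the spring / drought / autumn sampling windows
_DEFAULT_REGIMES = (
    (1.00, 12.0),
    (1.30, 15.0),
    (0.60, 23.0),
    (1.05, 11.0),
    (1.20, 16.0),
    (1.25, 18.0),
    (0.95, 14.0),
    (0.55, 24.0),
    (1.00, 8.0),
    (1.10, 12.0),
    (1.25, 17.0),
    (0.50, 26.0),
    (0.90, 9.0),
    (1.15, 16.0),
    (0.55, 24.0),
)


@dataclass
class TerrainConfig:
    """Geometry and roughness of the synthetic DEM."""

    nx: int = 400
    ny: int = 300
    cell_size: float = 0.2
    relief_max: float = 1.5       # m, total max-min relief after rescaling
    correlation_length: float = 10.0  # m, Gaussian smoothing scale of the field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8 x 8 cells")
        if self.cell_size <= 0 or self.relief_max <= 0 or self.correlation_length <= 0:
            raise ValueError("cell_size, relief_max and correlation_length must be positive")


@dataclass
class StudyDesign:
    """Sampling layout: positions, extent and campaign schedule."""

    n_positions: int = 78
    extent_x: float = 80.0
    extent_y: float = 60.0
    n_campaigns: int = 15
    soc_campaigns: int = 6
    position_spacing: float = 10.0

    def __post_init__(self) -> None:
        if self.n_positions < 3:
            raise ValueError("need at least 3 positions")
        if self.soc_campaigns > self.n_campaigns:
            raise ValueError("soc_campaigns cannot exceed n_campaigns")


@dataclass
class FluxModelParams:
    """Parameters of the soil-respiration emulator."""

    rs_ref: float = 3.0           # umol CO2 m-2 s-1 at 10 degC, optimal moisture
    q10: float = 2.0              # temperature sensitivity
    swc_opt: float = 25.0         # % SWC of maximal activity
    swc_width: float = 18.0       # % width of the moisture response
    soc_weight: float = 0.45      # relative Rs change per SD of SOC
    noise_sd: float = 0.35        # umol CO2 m-2 s-1 measurement noise
    swc_noise_sd: float = 1.5     # % campaign-level SWC noise
    ts_noise_sd: float = 0.6      # degC microsite temperature noise
    campaign_regimes: tuple = _DEFAULT_REGIMES

    def __post_init__(self) -> None:
        if self.rs_ref <= 0:
            raise ValueError("rs_ref must be positive")
        if self.q10 < 1:
            raise ValueError("q10 must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ------------------------------------------------------------------- terrain
def generate_terrain(cfg: TerrainConfig) -> ElevationRaster:
    """Smooth correlated random surface with exactly ``relief_max`` total relief."""
    rng = np.random.default_rng(cfg.seed)
    white = rng.standard_normal((cfg.ny, cfg.nx))
    sigma = cfg.correlation_length / cfg.cell_size
    smooth = ndimage.gaussian_filter(white, sigma, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:  # degenerate only for pathological smoothing scales
        values = np.zeros_like(smooth)
    else:
        values = (smooth - lo) / (hi - lo) * cfg.relief_max
    return ElevationRaster(values, cfg.cell_size, (0.0, 0.0))


def default_positions(design: StudyDesign) -> pd.DataFrame:
    """Measuring positions: a regular lattice at ``position_spacing`` plus
    deterministic in-fill points at lattice-cell midpoints up to n_positions.

    For the default design this is the 9 x 7 = 63-node lattice of an
    80 x 60 m grid at 10 m spacing plus 15 midpoint in-fills, 78 in total.
    """
    sp = design.position_spacing
    xs = np.arange(0.0, design.extent_x + 1e-9, sp)
    ys = np.arange(0.0, design.extent_y + 1e-9, sp)
    lattice = [(x, y) for y in ys for x in xs]
    mids = [
        (x + sp / 2.0, y + sp / 2.0)
        for y in ys[:-1]
        for x in xs[:-1]
    ]
    pts = (lattice + mids)[: design.n_positions]
    if len(pts) < design.n_positions:
        raise ValueError(
            f"extent {design.extent_x} x {design.extent_y} m at {sp} m spacing "
            f"yields only {len(pts)} candidate positions"
        )
    return pd.DataFrame(
        {
            "position_id": [f"P{i + 1:02d}" for i in range(len(pts))],
            "x": [p[0] for p in pts],
            "y": [p[1] for p in pts],
        }
    )


# --------------------------------------------------------------- soil fields
#: standardized-attribute coefficients of the SOC field
#: (elevation, SD, slope, northness, easterness); the aspect terms are
#: strong because wind exposure of south-west-facing slopes is a first-order
#: control on organic-matter accumulation at the emulated site
SOC_COEFFS = (0.80, 0.50, 0.50, 0.80, 0.80)
#: standardized-attribute coefficients of the baseline-SWC field
#: (elevation, SD, slope)
SWC_COEFFS = (2.0, 2.5, 2.5)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _terrain_drivers(dem: ElevationRaster, positions: pd.DataFrame) -> pd.DataFrame:
    """Elevation, SD, slope, northness, easterness sampled at the positions
    from a ~3.2 m smoothing of the DEM (the scale soil processes feel)."""
    factor = max(int(round(3.2 / dem.cell_size)), 1)
    coarse = aggregate_dem(dem, factor) if factor >= 2 else dem
    attrs = compute_attributes(coarse, 3)
    out = positions.copy()
    out["elev"] = [coarse.value_at(x, y) for x, y in zip(out["x"], out["y"])]
    for name in ("SD", "Sl", "North", "East"):
        r = attrs[name]
        out[name] = [r.value_at(x, y) for x, y in zip(out["x"], out["y"])]
    return out


def generate_soil_fields(
    dem: ElevationRaster,
    positions: pd.DataFrame,
    seed: int,
    soc_mean: float = 3.0,
    soc_scale: float = 0.9,
    soc_noise_sd: float = 0.15,
    swc_mean: float = 20.0,
    swc_noise_sd: float = 1.0,
    soc_coeffs: tuple = SOC_COEFFS,
    swc_coeffs: tuple = SWC_COEFFS,
) -> pd.DataFrame:
    """Static per-position SOC (%) and baseline SWC (%) driven by the terrain.

    SOC = soc_mean + soc_scale * (-b1*z(elev) - b2*z(SD) - b3*z(Sl)
    + b4*z(North) + b5*z(East)) + noise, truncated positive; the SWC baseline
    uses negative elevation, SD and slope terms.  Coefficients act on
    z-scored attributes so their magnitudes are comparable.
    """
    rng = np.random.default_rng(seed)
    drv = _terrain_drivers(dem, positions)
    z = {k: _zscore(drv[k].to_numpy()) for k in ("elev", "SD", "Sl", "North", "East")}
    b1, b2, b3, b4, b5 = soc_coeffs
    soc_signal = -b1 * z["elev"] - b2 * z["SD"] - b3 * z["Sl"] + b4 * z["North"] + b5 * z["East"]
    soc = soc_mean + soc_scale * _zscore(soc_signal) + rng.normal(0, soc_noise_sd, len(drv))
    soc = np.clip(soc, 0.05, None)
    c1, c2, c3 = swc_coeffs
    swc_signal = -c1 * z["elev"] - c2 * z["SD"] - c3 * z["Sl"]
    swc = swc_mean + 3.0 * _zscore(swc_signal) + rng.normal(0, swc_noise_sd, len(drv))
    swc = np.clip(swc, 2.0, 60.0)
    out = positions.copy()
    out["soc"] = soc
    out["swc_base"] = swc
    return out


# ----------------------------------------------------------------- campaigns
def generate_campaigns(
    design: StudyDesign,
    soil: pd.DataFrame,
    params: FluxModelParams,
    seed: int,
) -> CampaignPanel:
    """Simulate the positions x campaigns panel of Rs, Ts, SWC and sparse SOC.

    Per campaign c and position i:
    SWC_ic = wetness_c * SWCbase_i + noise (clipped to [0, 100]);
    Ts_ic = campaign temperature + microsite noise;
    Rs_ic = rs_ref * (1 + soc_weight * z(SOC_i)) * q10^((Ts-10)/10)
            * exp(-((SWC - swc_opt) / swc_width)^2) + noise, clipped at 0.

    SOC is reported on ``design.soc_campaigns`` evenly spread campaigns only.
    """
    if len(soil) != design.n_positions:
        raise ValueError(
            f"soil fields cover {len(soil)} positions, design expects {design.n_positions}"
        )
    rng = np.random.default_rng(seed)
    n, m = design.n_positions, design.n_campaigns
    regimes = list(params.campaign_regimes)
    if len(regimes) < m:
        raise ValueError(f"{len(regimes)} campaign regimes for {m} campaigns")
    regimes = regimes[:m]
    dates = list(CAMPAIGN_DATES)[:m]
    while len(dates) < m:
        dates.append(f"c{len(dates) + 1}")
    cids = [f"C{j + 1:02d}" for j in range(m)]

    soc_i = soil["soc"].to_numpy()
    z_soc = _zscore(soc_i)
    base = soil["swc_base"].to_numpy()
    soc_slots = np.unique(np.round(np.linspace(0, m - 1, design.soc_campaigns)).astype(int))

    swc = np.empty((n, m))
    ts = np.empty((n, m))
    rs = np.empty((n, m))
    soc_panel = np.full((n, m), np.nan)
    for j, (wet, temp) in enumerate(regimes):
        swc[:, j] = np.clip(wet * base + rng.normal(0, params.swc_noise_sd, n), 0.0, 100.0)
        ts[:, j] = temp + rng.normal(0, params.ts_noise_sd, n)
        activity = np.clip(1.0 + params.soc_weight * z_soc, 0.05, None)
        moisture = np.exp(-(((swc[:, j] - params.swc_opt) / params.swc_width) ** 2))
        flux = params.rs_ref * activity * params.q10 ** ((ts[:, j] - 10.0) / 10.0) * moisture
        rs[:, j] = np.clip(flux + rng.normal(0, params.noise_sd, n), 0.0, None)
        if j in soc_slots:
            soc_panel[:, j] = np.clip(soc_i + rng.normal(0, 0.05, n), 0.01, None)

    idx = pd.Index(soil["position_id"], name="position_id")
    mk = lambda a: pd.DataFrame(a, index=idx, columns=cids)
    return CampaignPanel(
        positions=soil[["position_id", "x", "y"]].reset_index(drop=True),
        campaigns=pd.DataFrame({"campaign_id": cids, "date": dates}),
        rs=mk(rs),
        ts=mk(ts),
        swc=mk(swc),
        soc=mk(soc_panel),
    )


def generate_dataset(
    seed: int = 0,
    terrain_cfg: TerrainConfig | None = None,
    design: StudyDesign | None = None,
    params: FluxModelParams | None = None,
) -> tuple[ElevationRaster, pd.DataFrame, CampaignPanel]:
    """Full synthetic study for one seed: (dem, soil-field table, campaign panel).

    The three stages consume independent streams spawned from ``seed`` so any
    stage can be regenerated in isolation.
    """
    terrain_cfg = terrain_cfg or TerrainConfig()
    design = design or StudyDesign()
    params = params or FluxModelParams()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    cfg = TerrainConfig(
        nx=terrain_cfg.nx,
        ny=terrain_cfg.ny,
        cell_size=terrain_cfg.cell_size,
        relief_max=terrain_cfg.relief_max,
        correlation_length=terrain_cfg.correlation_length,
        seed=sub[0],
    )
    dem = generate_terrain(cfg)
    positions = default_positions(design)
    soil = generate_soil_fields(dem, positions, seed=sub[1])
    panel = generate_campaigns(design, soil, params, seed=sub[2])
    return dem, soil, panel
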