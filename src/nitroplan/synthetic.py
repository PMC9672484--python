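"""Seeded synthetic fixtures with the statistical structure of the model.

Generates (i) a district x season x crop panel whose land-use shares follow
the logistic share system with known coefficients, (ii) household yield
samples following the arcsinh-linearised Cobb-Douglas yield equation with
known elasticities and district fixed effects, and (iii) small raster stacks
(DEM, land cover, districts, nitrogen loads, retention) with a strictly
monotone drainage structure for the nutrient-transport stage.

The default coefficient values are the estimates a national application of
the model produces (land-use inertia of 2.7-5.2, own net-price-change
responses of -0.07 to 0.42, yield-nitrogen elasticities of 0.05-0.12), so
the synthetic country is generated at realistic magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CROPS,
    IDLE,
    RICE,
    SEASONS,
    ConfigurationError,
    DistrictPanel,
    HouseholdSample,
)

#: kg of nitrogen per kg of urea
UREA_N_FACTOR = 0.46

# Default "true" coefficients of the data-generating process, indexed
# [season-1] or [season-1][crop-1].
DEFAULT_ALPHA = (3.75, 2.68, 5.15)
DEFAULT_BETA = ((-0.066, 0.130), (0.065, 0.027), (0.419, 0.328))
DEFAULT_ETA_ROAD = ((-0.01, 0.46), (6.99, 8.40), (-2.59, -1.59))
DEFAULT_ETA_PRECIP = ((0.21, 0.29), (-0.07, -0.10), (2.72, 13.38))
DEFAULT_RHO = ((0.110, 0.079), (0.120, 0.109), (0.045, 0.118))
DEFAULT_B_LABOR = ((0.571, 0.559), (0.755, 0.615), (0.102, 0.457))
DEFAULT_B_HYBRID = ((0.409, 0.114), (0.700, -0.616), (0.176, 0.328))
DEFAULT_B_HYV = ((0.171, -0.001), (0.492, 0.404), (0.0, -0.131))


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic data-generating process.

    Parameters
    ----------
    seed : int
        Master seed; every fixture is a deterministic function of
        (config, seed).
    n_districts : int
        Number of districts (default 64, the national district count the
        model was built for).
    grid_shape : (rows, cols)
        Raster dimensions for the toy nutrient-transport stage; minimum 3x3.
    true_alpha, true_beta, true_eta_road, true_eta_precip
        Coefficients of the logistic share system (inertia; own
        net-price-change; covariate-change effects), per season / per
        season x crop.
    true_rho, true_b_labor, true_b_hybrid, true_b_hyv
        Yield-equation coefficients per season x crop; ``true_rho`` are the
        yield-nitrogen elasticities and must lie in (0, 1).
    share_noise_sd : float
        S.d. of the share-equation error, entering on the log-odds (linear
        predictor) scale so the share estimator is correctly specified.
    yield_noise_sd : float
        S.d. of the household yield-equation error (arcsinh scale).
    households_per_cell : int
        Households generated per district x season x crop cell.
    zero_input_fraction : float
        Fraction of households whose urea (and, independently, labor) input
        is zero, to exercise the inverse-hyperbolic-sine path.
    winter_rice_all_modern : bool
        If True, winter rice households have hyv_share = 1 - hybrid_share
        (no local varieties), creating the perfect-collinearity situation a
        national sample exhibits.
    n_raster_districts : int or None
        Number of district bands in the toy rasters (default: min(4, cols)
        unless set).
    """

    seed: int = 0
    n_districts: int = 64
    grid_shape: tuple[int, int] = (12, 12)
    true_alpha: tuple = DEFAULT_ALPHA
    true_beta: tuple = DEFAULT_BETA
    true_eta_road: tuple = DEFAULT_ETA_ROAD
    true_eta_precip: tuple = DEFAULT_ETA_PRECIP
    true_rho: tuple = DEFAULT_RHO
    true_b_labor: tuple = DEFAULT_B_LABOR
    true_b_hybrid: tuple = DEFAULT_B_HYBRID
    true_b_hyv: tuple = DEFAULT_B_HYV
    share_noise_sd: float = 0.60
    yield_noise_sd: float = 0.30
    district_effect_sd: float = 0.15
    households_per_cell: int = 8
    zero_input_fraction: float = 0.05
    winter_rice_all_modern: bool = False
    theta_range: tuple[float, float] = (0.05, 0.35)
    n_raster_districts: int | None = None
    # unused surface-buffer constants accepted for config compatibility
    buffer_retention_length_m: float = 200.0
    buffer_retention_efficiency: float = 0.80

    def validate(self) -> None:
        if self.n_districts < 1:
            raise ConfigurationError("n_districts must be >= 1")
        if self.households_per_cell < 1:
            raise ConfigurationError("households_per_cell must be >= 1")
        if self.grid_shape[0] < 3 or self.grid_shape[1] < 3:
            raise ConfigurationError("grid_shape must be at least 3x3")
        if self.share_noise_sd < 0 or self.yield_noise_sd < 0:
            raise ConfigurationError("noise scales must be >= 0")
        if not (0.0 <= self.zero_input_fraction < 1.0):
            raise ConfigurationError("zero_input_fraction must lie in [0, 1)")
        rho = np.asarray(self.true_rho, dtype=float)
        if not ((rho > 0) & (rho < 1)).all():
            raise ConfigurationError("elasticities rho must lie in (0, 1)")
        lo, hi = self.theta_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError("theta_range must be within [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _logistic_shares(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Share triple (idle, rice, non-rice) from log-odds vs idle."""
    u = np.stack([np.zeros_like(u1), u1, u2], axis=-1)
    u = u - u.max(axis=-1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=-1, keepdims=True)


def generate_district_panel(cfg: SyntheticConfig) -> DistrictPanel:
    """Generate a complete district x season x crop panel.

    Land-use shares are drawn from the logistic share system evaluated at
    the true coefficients, with Gaussian noise added on the log-odds scale;
    baseline revenue totals are computed from the generated panel so the
    optimizer's economic constraints are feasible (binding) at baseline.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 101])
    n = cfg.n_districts
    ids = np.arange(1, n + 1)

    # district-level physical cropland (acres), lognormal around ~120k acres
    L_bar = np.exp(rng.normal(np.log(1.2e5), 0.35, size=n))

    cells = []
    seas_rows = []
    for r in SEASONS:
        a = cfg.true_alpha[r - 1]
        # lagged shares: Dirichlet favouring cultivated uses
        lag = rng.dirichlet((1.5, 4.0, 3.0), size=n)  # (idle, rice, non-rice)
        dprice = rng.normal(0.0, 0.8, size=(n, 2))
        droad = rng.normal(0.0, 0.03, size=n)
        dprecip = rng.normal(0.0, 0.05, size=n)
        u = np.empty((n, 2))
        for j in CROPS:
            b = cfg.true_beta[r - 1][j - 1]
            er = cfg.true_eta_road[r - 1][j - 1]
            ep = cfg.true_eta_precip[r - 1][j - 1]
            u[:, j - 1] = (
                (lag[:, j] - lag[:, IDLE]) * a
                + dprice[:, j - 1] * b
                + droad * er
                + dprecip * ep
            )
        if cfg.share_noise_sd > 0:
            u = u + rng.normal(0.0, cfg.share_noise_sd, size=u.shape)
        shares = _logistic_shares(u[:, 0], u[:, 1])

        theta = rng.uniform(*cfg.theta_range, size=n)
        pN = rng.uniform(30.0, 40.0, size=n)
        cultivated = shares[:, 1] + shares[:, 2]
        CIp = np.minimum(1.0, cultivated * (1.0 + rng.uniform(0.05, 0.25, size=n)))
        CIp = np.maximum(CIp, cultivated)  # guard against the cap

        seas_rows.append(
            pd.DataFrame(
                dict(
                    district_id=ids,
                    season=r,
                    theta=theta,
                    CIp=CIp,
                    pN=pN,
                    droad=droad,
                    dprecip=dprecip,
                    share_idle=shares[:, IDLE],
                    lag_share_idle=lag[:, IDLE],
                )
            )
        )
        for j in CROPS:
            price = np.exp(rng.normal(np.log(20.0), 0.20, size=n))
            N_b = rng.uniform(40.0, 120.0, size=n)
            y_b = np.exp(rng.normal(np.log(1600.0), 0.25, size=n))
            cells.append(
                pd.DataFrame(
                    dict(
                        district_id=ids,
                        season=r,
                        crop=j,
                        share=shares[:, j],
                        lag_share=lag[:, j],
                        dprice=dprice[:, j - 1],
                        price=price,
                        N_b=N_b,
                        y_b=y_b,
                    )
                )
            )

    cells_df = pd.concat(cells, ignore_index=True).sort_values(
        ["district_id", "season", "crop"], ignore_index=True
    )
    seasons_df = pd.concat(seas_rows, ignore_index=True).sort_values(
        ["district_id", "season"], ignore_index=True
    )
    # annual cropping intensity: the baseline binds the annual-land constraint
    annual = cells_df.groupby("district_id")["share"].sum()
    districts_df = pd.DataFrame(
        dict(district_id=ids, L_bar=L_bar, CI=annual.reindex(ids).to_numpy(), v_b=0.0)
    )
    panel = DistrictPanel(districts_df, seasons_df, cells_df)
    panel.recompute_baseline_values()
    panel.validate()
    return panel


def generate_household_sample(
    cfg: SyntheticConfig, panel: DistrictPanel
) -> HouseholdSample:
    """Generate household yields from the arcsinh-linear yield equation.

    For each household, asinh(yield) is exactly linear in asinh(urea),
    asinh(labor), the variety shares, a district effect and noise, which for
    the input magnitudes generated here coincides with the Cobb-Douglas form
    yield = delta * urea^rho * labor^b1 * exp(effects) to O(1/x^2).  Zero
    urea/labor values are injected with probability ``zero_input_fraction``
    each, exercising the inverse-hyperbolic-sine path of the estimator.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 202])
    d_effect = rng.normal(0.0, cfg.district_effect_sd, size=cfg.n_districts)
    eff = dict(zip(panel.districts["district_id"], d_effect[: len(panel.districts)]))

    mean_y = panel.cells.groupby(["season", "crop"])["y_b"].mean()
    rows = []
    hid = 0
    for _, cell in panel.cells.iterrows():
        i, r, j = int(cell["district_id"]), int(cell["season"]), int(cell["crop"])
        rho = cfg.true_rho[r - 1][j - 1]
        b1 = cfg.true_b_labor[r - 1][j - 1]
        b2 = cfg.true_b_hybrid[r - 1][j - 1]
        b3 = cfg.true_b_hyv[r - 1][j - 1]
        m = cfg.households_per_cell
        urea = np.exp(
            rng.normal(np.log(cell["N_b"] / UREA_N_FACTOR), 0.40, size=m)
        )
        labor = np.exp(rng.normal(np.log(300.0), 0.40, size=m))
        if cfg.zero_input_fraction > 0:
            urea[rng.random(m) < cfg.zero_input_fraction] = 0.0
            labor[rng.random(m) < cfg.zero_input_fraction] = 0.0
        variety = rng.dirichlet((2.0, 2.0, 1.0), size=m)  # hybrid, hyv, local
        hybrid, hyv = variety[:, 0], variety[:, 1]
        if cfg.winter_rice_all_modern and r == 3 and j == RICE:
            hyv = 1.0 - hybrid
        # cell-level base productivity anchoring yields near the panel mean
        base = (
            np.arcsinh(mean_y.loc[(r, j)])
            - rho * np.arcsinh(cell["N_b"] / UREA_N_FACTOR)
            - b1 * np.arcsinh(300.0)
            - b2 * 0.4
            - b3 * 0.4
        )
        lin = (
            rho * np.arcsinh(urea)
            + b1 * np.arcsinh(labor)
            + b2 * hybrid
            + b3 * hyv
            + base
            + eff[i]
        )
        if cfg.yield_noise_sd > 0:
            lin = lin + rng.normal(0.0, cfg.yield_noise_sd, size=m)
        y = np.sinh(lin)
        rows.append(
            pd.DataFrame(
                dict(
                    household_id=np.arange(hid, hid + m),
                    district_id=i,
                    season=r,
                    crop=j,
                    yield_=y,
                    urea=urea,
                    labor=labor,
                    hybrid_share=hybrid,
                    hyv_share=hyv,
                )
            )
        )
        hid += m
    sample = HouseholdSample(pd.concat(rows, ignore_index=True))
    sample.validate()
    return sample


@dataclass
class ToyRasters:
    """Raster stack for the toy nutrient-transport stage.

    ``dem``: elevation with strictly monotone drainage toward the bottom
    (stream) row; ``landcover``: 0 natural, 1 cropland, 2 stream;
    ``district_map``: district zone id per pixel (>= 2 zones);
    ``load_fertilizer``: fertilizer nitrogen load on cropland pixels (kg);
    ``load_natural``: small background load everywhere (kg);
    ``retention``: per-pixel retention efficiency in [0, 1];
    ``stream_mask``: boolean, the stream pixels;
    ``seasonal_activation``: per-season boolean cropland activation masks
    used to build seasonal fertilizer loads.
    """

    dem: np.ndarray
    landcover: np.ndarray
    district_map: np.ndarray
    load_fertilizer: np.ndarray
    load_natural: np.ndarray
    retention: np.ndarray
    stream_mask: np.ndarray
    seasonal_activation: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def load(self) -> np.ndarray:
        """Total (fertilizer + natural) load."""
        return self.load_fertilizer + self.load_natural

    def seasonal_fertilizer_load(self, season: int) -> np.ndarray:
        mask = self.seasonal_activation[season]
        return self.load_fertilizer * mask


#: per-class retention efficiencies (natural vegetation, cropland, stream)
DEFAULT_RETENTION_BY_CLASS = {0: 0.35, 1: 0.08, 2: 0.0}


def generate_toy_rasters(
    cfg: SyntheticConfig,
    retention_by_class: dict[int, float] | None = None,
) -> ToyRasters:
    """Generate a pit-free DEM, land cover, district zones, loads, retention.

    The DEM is a south-tilted plane with bounded roughness, so every pixel
    has a strictly lower 8-neighbor in the row below; the bottom row is the
    stream.  No pit filling is ever needed by construction.
    """
    cfg.validate()
    if retention_by_class is None:
        retention_by_class = DEFAULT_RETENTION_BY_CLASS
    if any(not (0.0 <= v <= 1.0) for v in retention_by_class.values()):
        raise ConfigurationError("retention efficiencies must lie in [0, 1]")
    rng = np.random.default_rng([cfg.seed, 303])
    rows, cols = cfg.grid_shape

    drop = 1.0
    base = (rows - 1 - np.arange(rows))[:, None] * drop * np.ones((1, cols))
    dem = base + rng.uniform(-0.4 * drop, 0.4 * drop, size=(rows, cols))

    landcover = (rng.random((rows, cols)) < 0.6).astype(np.int8)  # 1 cropland
    landcover[rows - 1, :] = 2  # stream row
    stream_mask = landcover == 2

    nzones = cfg.n_raster_districts or min(4, cols)
    if nzones < 2:
        nzones = 2
    if nzones > cols:
        raise ConfigurationError("more raster districts than grid columns")
    district_map = (
        np.floor(np.arange(cols) / cols * nzones).astype(np.int32) + 1
    ) * np.ones((rows, 1), dtype=np.int32)

    rate = rng.uniform(50.0, 120.0, size=nzones)
    per_pixel_rate = rate[district_map - 1]
    load_fert = np.where(
        landcover == 1,
        per_pixel_rate * rng.uniform(0.8, 1.2, size=(rows, cols)),
        0.0,
    )
    load_nat = rng.uniform(0.5, 2.0, size=(rows, cols))

    retention = np.vectorize(retention_by_class.__getitem__, otypes=[float])(
        landcover
    )

    activation = {}
    act_prob = {1: 0.7, 2: 0.9, 3: 0.8}
    for r in SEASONS:
        activation[r] = (rng.random((rows, cols)) < act_prob[r]) & (landcover == 1)

    return ToyRasters(
        dem=dem,
        landcover=landcover,
        district_map=district_map,
        load_fertilizer=load_fert,
        load_natural=load_nat,
        retention=retention,
        stream_mask=stream_mask,
        seasonal_activation=activation,
    )


def write_fixtures(
    cfg: SyntheticConfig,
    outdir: str | Path,
    panel: DistrictPanel | None = None,
    households: HouseholdSample | None = None,
    rasters: ToyRasters | None = None,
) -> dict[str, str]:
    """Write all synthetic fixtures plus a manifest recording config + seed.

    Returns a name -> path index of everything written.
    """
    from .ndr import write_ascii_grid  # local import avoids a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = panel if panel is not None else generate_district_panel(cfg)
    households = (
        households
        if households is not None
        else generate_household_sample(cfg, panel)
    )
    rasters = rasters if rasters is not None else generate_toy_rasters(cfg)

    index: dict[str, str] = {}
    for p in panel.to_dir(outdir):
        index[p.stem] = str(p)
    index["households"] = str(households.to_csv(outdir / "households.csv"))
    index["share_dataset"] = str(panel.share_dataset().to_csv(outdir / "shares.csv"))
    for name, grid in (
        ("dem", rasters.dem),
        ("landcover", rasters.landcover),
        ("districts", rasters.district_map),
        ("load_fertilizer", rasters.load_fertilizer),
        ("load_natural", rasters.load_natural),
        ("retention", rasters.retention),
        ("streams", rasters.stream_mask.astype(np.int8)),
    ):
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, np.asarray(grid, dtype=float))
        index[name] = str(p)
    manifest = dict(config=cfg.to_dict(), seed=cfg.seed, files=index)
    mpath = outdir / "synthetic_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    index["manifest"] = str(mpath)
    return index
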