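"""Core data containers shared across the modelling pipeline.

The model works on a district x season x land-use panel for a country with
three cropping seasons (spring, summer, winter) and three land uses per
season: rice, non-rice crops, and idle (unsown) cropland.  Idle is the
residual category of the land-use share system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEASONS: tuple[int, ...] = (1, 2, 3)
SEASON_NAMES: dict[int, str] = {1: "spring", 2: "summer", 3: "winter"}
IDLE: int = 0
RICE: int = 1
NON_RICE: int = 2
CROPS: tuple[int, ...] = (RICE, NON_RICE)
USE_NAMES: dict[int, str] = {0: "idle", 1: "rice", 2: "non-rice"}


class ConfigurationError(ValueError):
    """Invalid configuration (non-positive dimension, noise scale, ...)."""


class InputError(ValueError):
    """Invalid or inconsistent input data."""


def _require(cond: bool, msg: str, exc: type[Exception] = InputError) -> None:
    if not cond:
        raise exc(msg)


@dataclass
class DistrictPanel:
    """District x season x crop panel of all baseline parameters.

    Attributes
    ----------
    districts : DataFrame
        One row per district: ``district_id``, ``L_bar`` (physical cropland,
        acres), ``CI`` (baseline annual cropping intensity, harvested area /
        physical area), ``v_b`` (baseline production value, Taka).
    seasons : DataFrame
        One row per district x season: ``district_id``, ``season``, ``theta``
        (fertilizer-nitrogen delivery ratio), ``CIp`` (seasonal
        cropping-intensity potential), ``pN`` (nitrogen input price, Taka/kg),
        ``droad``/``dprecip`` (covariate changes), ``share_idle``,
        ``lag_share_idle``.
    cells : DataFrame
        One row per district x season x crop (rice / non-rice):
        ``district_id``, ``season``, ``crop``, ``share`` (baseline land-use
        share), ``lag_share``, ``dprice`` (net-price change, Taka/kg),
        ``price`` (net crop price, Taka/kg), ``N_b`` (baseline nitrogen rate,
        kg/acre), ``y_b`` (baseline yield, kg/acre).
    complete : bool
        True for a full panel whose shares sum to one per district x season;
        subsets of the crop/season axes clear this flag.
    """

    districts: pd.DataFrame
    seasons: pd.DataFrame
    cells: pd.DataFrame
    complete: bool = True

    # -- derived national baselines ------------------------------------
    @property
    def v_b(self) -> float:
        """National baseline production value (Taka)."""
        return float(self.districts["v_b"].sum())

    @property
    def Y1_b(self) -> float:
        """National baseline rice production (kg)."""
        rice = self.cells[self.cells["crop"] == RICE]
        if rice.empty:
            return 0.0
        lbar = self.districts.set_index("district_id")["L_bar"]
        return float(
            (rice["y_b"] * rice["share"] * rice["district_id"].map(lbar)).sum()
        )

    def baseline_area(self) -> pd.Series:
        """Baseline harvested area per cell (acres), aligned with ``cells``."""
        lbar = self.districts.set_index("district_id")["L_bar"]
        return self.cells["share"] * self.cells["district_id"].map(lbar)

    def recompute_baseline_values(self) -> None:
        """Recompute district and national baseline production values v_b
        from prices, yields and baseline areas (keeps the revenue constraint
        feasible, with equality, at the baseline point)."""
        area = self.baseline_area()
        value = self.cells["price"] * self.cells["y_b"] * area
        by_district = value.groupby(self.cells["district_id"]).sum()
        self.districts["v_b"] = (
            self.districts["district_id"].map(by_district).fillna(0.0).to_numpy()
        )

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        d, s, c = self.districts, self.seasons, self.cells
        _require((d["L_bar"] > 0).all(), "physical cropland areas must be > 0")
        _require((c["price"] > 0).all(), "net prices must be > 0")
        _require((s["pN"] > 0).all(), "nitrogen prices must be > 0")
        _require((c["N_b"] > 0).all(), "baseline nitrogen rates must be > 0")
        _require((c["y_b"] > 0).all(), "baseline yields must be > 0")
        _require(
            s["theta"].between(0.0, 1.0).all(), "delivery ratios must lie in [0, 1]"
        )
        _require(c["share"].between(0.0, 1.0).all(), "shares must lie in [0, 1]")
        crop_sum = c.groupby(["district_id", "season"])["share"].sum()
        key = list(zip(s["district_id"], s["season"]))
        sums = crop_sum.reindex(key).to_numpy()
        if self.complete:
            total = sums + s["share_idle"].to_numpy()
            _require(
                np.allclose(total, 1.0, atol=1e-9),
                "land-use shares must sum to one per district x season",
            )
        _require(
            (s["CIp"].to_numpy() >= sums - 1e-9).all(),
            "seasonal cropping-intensity potential below baseline cultivated share",
        )
        annual = crop_sum.groupby(level=0).sum()
        ci = d.set_index("district_id")["CI"]
        _require(
            (annual <= ci.reindex(annual.index).to_numpy() + 1e-9).all(),
            "baseline annual harvested share exceeds cropping intensity",
        )

    # -- conversions ----------------------------------------------------
    def share_dataset(self) -> "ShareDataset":
        """Long-format land-use share table (including the idle rows) used by
        the econometric land-use model."""
        rows = []
        smap = self.seasons.set_index(["district_id", "season"])
        for _, r in self.cells.iterrows():
            key = (r["district_id"], r["season"])
            rows.append(
                dict(
                    district_id=int(r["district_id"]),
                    season=int(r["season"]),
                    use=int(r["crop"]),
                    share=r["share"],
                    lag_share=r["lag_share"],
                    dprice=r["dprice"],
                    droad=smap.loc[key, "droad"],
                    dprecip=smap.loc[key, "dprecip"],
                )
            )
        for (i, r_), row in smap.iterrows():
            rows.append(
                dict(
                    district_id=int(i),
                    season=int(r_),
                    use=IDLE,
                    share=row["share_idle"],
                    lag_share=row["lag_share_idle"],
                    dprice=0.0,
                    droad=row["droad"],
                    dprecip=row["dprecip"],
                )
            )
        data = pd.DataFrame(rows).sort_values(
            ["district_id", "season", "use"], ignore_index=True
        )
        return ShareDataset(data)

    def subset(
        self,
        districts: list[int] | None = None,
        seasons: list[int] | None = None,
        crops: list[int] | None = None,
    ) -> "DistrictPanel":
        """Restrict the panel to a subset of districts/seasons/crops.

        National and district baseline values (v_b, CI) are recomputed from
        the retained cells so that the baseline allocation remains feasible
        (and revenue-binding) on the subset.
        """
        c = self.cells
        s = self.seasons
        d = self.districts
        if districts is not None:
            c = c[c["district_id"].isin(districts)]
            s = s[s["district_id"].isin(districts)]
            d = d[d["district_id"].isin(districts)]
        if seasons is not None:
            c = c[c["season"].isin(seasons)]
            s = s[s["season"].isin(seasons)]
        if crops is not None:
            c = c[c["crop"].isin(crops)]
        complete = (
            self.complete
            and crops is None
            and seasons is None
        )
        out = DistrictPanel(
            d.reset_index(drop=True).copy(),
            s.reset_index(drop=True).copy(),
            c.reset_index(drop=True).copy(),
            complete=complete,
        )
        annual = out.cells.groupby("district_id")["share"].sum()
        out.districts["CI"] = (
            out.districts["district_id"].map(annual).fillna(0.0).to_numpy()
        )
        out.recompute_baseline_values()
        return out

    # -- I/O -------------------------------------------------------------
    def to_dir(self, path: str | Path) -> list[Path]:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (
            ("districts", self.districts),
            ("seasons", self.seasons),
            ("cells", self.cells),
        ):
            p = path / f"panel_{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        return written

    @classmethod
    def from_dir(cls, path: str | Path) -> "DistrictPanel":
        path = Path(path)
        return cls(
            pd.read_csv(path / "panel_districts.csv"),
            pd.read_csv(path / "panel_seasons.csv"),
            pd.read_csv(path / "panel_cells.csv"),
        )


@dataclass
class ShareDataset:
    """Long-format district x season x use land-use share table.

    Columns: ``district_id``, ``season``, ``use`` (0 idle, 1 rice,
    2 non-rice), ``share``, ``lag_share``, ``dprice`` (0 for idle),
    ``droad``, ``dprecip``.
    """

    data: pd.DataFrame

    def validate(self) -> None:
        g = self.data.groupby(["district_id", "season"])
        _require(
            np.allclose(g["share"].sum(), 1.0, atol=1e-9),
            "current shares must sum to one per district x season",
        )
        _require(
            np.allclose(g["lag_share"].sum(), 1.0, atol=1e-9),
            "lagged shares must sum to one per district x season",
        )
        _require(
            self.data["share"].between(0, 1).all()
            and self.data["lag_share"].between(0, 1).all(),
            "shares must lie in [0, 1]",
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShareDataset":
        return cls(pd.read_csv(path))


@dataclass
class HouseholdSample:
    """Household-level yield sample.

    Columns: ``household_id``, ``district_id``, ``season``, ``crop``,
    ``yield_`` (kg/acre), ``urea`` (kg/acre), ``labor`` (hours/acre),
    ``hybrid_share``, ``hyv_share``.
    """

    data: pd.DataFrame

    def validate(self) -> None:
        d = self.data
        _require((d["yield_"] > 0).all(), "household yields must be > 0")
        _require((d["urea"] >= 0).all() and (d["labor"] >= 0).all(), "inputs >= 0")
        _require(
            d["hybrid_share"].between(0, 1).all()
            and d["hyv_share"].between(0, 1).all(),
            "variety shares must lie in [0, 1]",
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.rename(columns={"yield_": "yield"}).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "HouseholdSample":
        df = pd.read_csv(path).rename(columns={"yield": "yield_"})
        return cls(df)


@dataclass
class SURCoefficients:
    """Estimated coefficients of the six-equation land-use share system.

    ``table`` has one row per free coefficient: ``term`` (one of
    ``inertia``, ``dprice``, ``droad``, ``dprecip``), ``season``, ``crop``
    (NaN for the season-shared inertia coefficient), ``estimate``, ``se``,
    ``tstat``, ``p``, ``significant`` (two-sided 10% level).
    """

    table: pd.DataFrame
    system_r2: float
    sigma: np.ndarray
    n_obs: int
    n_iterations: int
    converged: bool
    n_floored: int = 0

    def _lookup(self, term: str, season: int, crop: int | None) -> pd.Series:
        t = self.table
        m = (t["term"] == term) & (t["season"] == season)
        if crop is not None:
            m &= t["crop"] == crop
        rows = t[m]
        if len(rows) != 1:
            raise KeyError(f"no unique coefficient ({term}, season={season}, crop={crop})")
        return rows.iloc[0]

    def alpha(self, season: int) -> float:
        return float(self._lookup("inertia", season, None)["estimate"])

    def beta(self, season: int, crop: int) -> float:
        return float(self._lookup("dprice", season, crop)["estimate"])

    def beta_significant(self, season: int, crop: int) -> bool:
        return bool(self._lookup("dprice", season, crop)["significant"])

    def eta(self, season: int, crop: int) -> np.ndarray:
        return np.array(
            [
                self._lookup("droad", season, crop)["estimate"],
                self._lookup("dprecip", season, crop)["estimate"],
            ]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


@dataclass
class MarginalEffects:
    """Analytic price marginal effects of the share system at baseline.

    ``table``: one row per district x season x use j x price k with column
    ``effect`` = d s_rj / d x_rk evaluated at the baseline shares; includes
    the derived idle rows (j = 0), whose effects are minus the column sums of
    the crop rows.
    """

    table: pd.DataFrame
    zeroed_insignificant: bool

    def matrix(self, district_id: int, season: int) -> np.ndarray:
        """2x2 array of effects for crops j in {1,2} x instruments k in {1,2}."""
        t = self.table
        m = (
            (t["district_id"] == district_id)
            & (t["season"] == season)
            & (t["use"] > 0)
        )
        sub = t[m].set_index(["use", "wrt_crop"])["effect"]
        return np.array(
            [[sub.loc[(j, k)] for k in CROPS] for j in CROPS]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


@dataclass
class YieldParams:
    """Yield-function estimates and calibrated productivities.

    ``coefficients``: season, crop, term (urea/labor/hybrid/hyv), estimate,
    se, tstat, p, significant; dropped-collinear terms carry NaN estimates.
    ``fit_stats``: season, crop, r2 (within), n_obs, n_districts, dropped.
    ``fixed_effects``: season, crop, district_id, effect.
    ``delta``: district_id, season, crop, delta (calibrated total factor
    productivity), filled by the calibration step.
    """

    coefficients: pd.DataFrame
    fit_stats: pd.DataFrame
    fixed_effects: pd.DataFrame
    delta: pd.DataFrame | None = None

    def rho(self, season: int, crop: int) -> float:
        t = self.coefficients
        row = t[
            (t["season"] == season) & (t["crop"] == crop) & (t["term"] == "urea")
        ]
        if len(row) != 1:
            raise KeyError(f"no elasticity for season={season}, crop={crop}")
        return float(row.iloc[0]["estimate"])

    def rho_table(self) -> pd.DataFrame:
        t = self.coefficients
        out = t[t["term"] == "urea"][["season", "crop", "estimate"]].rename(
            columns={"estimate": "rho"}
        )
        return out.reset_index(drop=True)


@dataclass
class CostBaseline:
    """Baseline nitrogen-cost table: one row per district x season x crop with
    ``pN`` (Taka/kg N), ``N_b`` (kg/acre), ``y_b`` (kg/acre) and
    ``c_b`` = pN * N_b / y_b, the baseline average nitrogen cost per unit
    output (Taka/kg output)."""

    table: pd.DataFrame

    def validate(self) -> None:
        _require((self.table["c_b"] >= 0).all(), "baseline nitrogen costs must be >= 0")


@dataclass
class Solution:
    """Result of one optimization scenario.

    ``decisions``: one row per district x season x crop with optimal ``N``
    (kg/acre) and ``L`` (acres); the integrated scenario adds ``x``
    (net-price change, Taka/kg).  ``constraints`` is the audited constraint
    report (name, value, bound, sense, slack_rel, binding).
    """

    scenario: str
    decisions: pd.DataFrame
    objective: float
    status: str
    success: bool
    constraints: pd.DataFrame | None = None
    n_starts: int = 1
    start_used: int = 0
    seed: int | None = None
    iterations: list[dict] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.decisions.to_csv(path, index=False)
        return path
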