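"""End-to-end orchestration of the three modelling steps.

Step 1 supplies district delivery ratios theta (computed by the toy
nutrient-transport stage, read from a file, or taken from the panel);
Step 2 fits the land-use share system -- only when the integrated scenario
is requested, since only the price-instrument scenario consumes its
marginal effects; Step 3 estimates and calibrates the yield function and
solves the requested optimization scenario(s).  Every run writes its
intermediate artifacts plus a manifest recording the configuration hash,
seed, input checksums and stage timings, so deterministic stages reproduce
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ndr, optimizer, synthetic, yields
from .containers import (
    SEASONS,
    ConfigurationError,
    DistrictPanel,
    InputError,
    Solution,
)
from .landuse import estimate_sur, marginal_effects
from .ndr import DeliveryRatioTable, compute_flow_field, delivery_ratios, run_ndr
from .synthetic import SyntheticConfig

logger = logging.getLogger(__name__)

SCENARIOS = ("seasonal", "seasonal-spatial", "integrated")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Units: areas in acres, nitrogen in kg/acre, money in Taka.  ``scenarios``
    is any subset of {seasonal, seasonal-spatial, integrated}.
    ``theta_source`` selects where delivery ratios come from: "panel" (the
    generated/loaded panel column), "ndr" (computed from the toy rasters),
    or a path to a delimited theta table.
    """

    seed: int = 0
    outdir: str = "run_output"
    scenarios: tuple[str, ...] = ("seasonal", "seasonal-spatial")
    theta_source: str = "panel"
    n_districts: int = 16
    households_per_cell: int = 8
    grid_shape: tuple[int, int] = (12, 12)
    share_noise_sd: float = 0.60
    yield_noise_sd: float = 0.30
    zero_input_fraction: float = 0.05
    zero_insignificant: bool = True
    x_frac: float = optimizer.X_FRAC
    n_min_frac: float = optimizer.N_MIN_FRAC
    n_max_factor: float = optimizer.N_MAX_FACTOR
    n_starts: int = 5
    share_floor: float = 1e-4
    feas_tol: float = optimizer.FEAS_TOL
    urea_n_factor: float = yields.UREA_N_FACTOR
    area_unit: str = "acre"
    nitrogen_unit: str = "kg/acre"
    value_unit: str = "Taka"

    def validate(self) -> None:
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ConfigurationError(f"unknown scenario {s!r}")
        if self.feas_tol <= 0 or self.share_floor <= 0:
            raise ConfigurationError("tolerances must be > 0")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            seed=self.seed,
            n_districts=self.n_districts,
            households_per_cell=self.households_per_cell,
            grid_shape=self.grid_shape,
            share_noise_sd=self.share_noise_sd,
            yield_noise_sd=self.yield_noise_sd,
            zero_input_fraction=self.zero_input_fraction,
        )


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    objectives: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
        return path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def theta_from_rasters(rasters: synthetic.ToyRasters) -> DeliveryRatioTable:
    """District x season delivery ratios from two-run differencing of the
    toy transport model (with-fertilizer minus natural-only)."""
    flow = compute_flow_field(rasters.dem)
    ratios = delivery_ratios(flow, rasters.retention, rasters.stream_mask)
    tables = []
    for r in SEASONS:
        fert = rasters.seasonal_fertilizer_load(r)
        run_f = run_ndr(fert + rasters.load_natural, ratios, rasters.district_map)
        run_n = run_ndr(rasters.load_natural, ratios, rasters.district_map)
        tables.append(ndr.fertilizer_theta(run_f, run_n, season=r).table)
    return DeliveryRatioTable(pd.concat(tables, ignore_index=True))


def _apply_theta(panel: DistrictPanel, theta: DeliveryRatioTable) -> int:
    """Overwrite the panel's theta column with the supplied table, matching
    district ids cyclically when the table covers fewer zones than the panel
    has districts.  Returns the number of panel rows updated."""
    t = theta.table
    if "season" not in t.columns:
        t = t.assign(season=np.nan)
    valid = t[t["valid"]] if "valid" in t.columns else t
    if valid.empty:
        raise InputError("theta table has no valid districts")
    zone_ids = sorted(valid["district_id"].unique())
    n_updated = 0
    for idx, row in panel.seasons.iterrows():
        zone = zone_ids[(int(row["district_id"]) - 1) % len(zone_ids)]
        sub = valid[valid["district_id"] == zone]
        if "season" in valid.columns and sub["season"].notna().any():
            sub2 = sub[sub["season"] == row["season"]]
            if not sub2.empty:
                sub = sub2
        panel.seasons.loc[idx, "theta"] = float(sub["theta"].iloc[0])
        n_updated += 1
    return n_updated


def run_workflow(config: RunConfig) -> RunManifest:
    """Execute the full workflow and write all artifacts to config.outdir.

    Stages: synthesize inputs -> resolve theta -> (land-use fit, only for
    the integrated scenario) -> yield estimation and calibration ->
    optimization per scenario -> audit -> comparison and manifest.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = yaml.safe_dump(asdict(config), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        seed=config.seed,
        version=_pkg_version(),
    )
    (out / "config.yaml").write_text(cfg_yaml)
    manifest.outputs["config"] = str(out / "config.yaml")

    scfg = config.synthetic_config()
    needs_landuse = "integrated" in config.scenarios

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                manifest.stage_seconds[name] = round(dt, 4)
                if exc is not None:
                    logger.error("stage %s: FAILED after %.2fs", name, dt)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    with stage("synthesize"):
        panel = synthetic.generate_district_panel(scfg)
        households = synthetic.generate_household_sample(scfg, panel)
        rasters = (
            synthetic.generate_toy_rasters(scfg)
            if config.theta_source == "ndr"
            else None
        )
        index = synthetic.write_fixtures(
            scfg, out / "inputs", panel=panel, households=households,
            rasters=rasters if rasters is not None
            else synthetic.generate_toy_rasters(scfg),
        )
        manifest.outputs.update({f"input:{k}": v for k, v in index.items()})

    with stage("theta"):
        if config.theta_source == "panel":
            theta = DeliveryRatioTable(
                panel.seasons[["district_id", "season", "theta"]]
                .assign(valid=True)
                .copy()
            )
        elif config.theta_source == "ndr":
            theta = theta_from_rasters(rasters)
            _apply_theta(panel, theta)
        else:
            theta = DeliveryRatioTable.from_csv(config.theta_source)
            _apply_theta(panel, theta)
        manifest.outputs["theta"] = str(theta.to_csv(out / "theta.csv"))

    me = cost = None
    if needs_landuse:
        with stage("landuse_fit"):
            ds = panel.share_dataset()
            coef = estimate_sur(ds, floor=config.share_floor)
            manifest.outputs["sur_coefficients"] = str(
                coef.to_csv(out / "sur_coefficients.csv")
            )
            baseline_shares = panel.cells[
                ["district_id", "season", "crop", "share"]
            ]
            me = marginal_effects(
                coef, baseline_shares,
                zero_insignificant=config.zero_insignificant,
            )
            manifest.outputs["marginal_effects"] = str(
                me.to_csv(out / "marginal_effects.csv")
            )
    else:
        logger.info("land-use fit skipped: no integrated scenario requested")

    with stage("yield_calibration"):
        yparams = yields.estimate_elasticities(households)
        yields.calibrate_delta(panel, yparams)
        yparams.coefficients.to_csv(out / "yield_coefficients.csv", index=False)
        yparams.delta.to_csv(out / "yield_delta.csv", index=False)
        manifest.outputs["yield_coefficients"] = str(out / "yield_coefficients.csv")
        manifest.outputs["yield_delta"] = str(out / "yield_delta.csv")
        cost = yields.cost_baseline(panel)

    solutions: list[Solution] = []
    warm = None
    for scen in config.scenarios:
        with stage(f"optimize:{scen}"):
            common = dict(
                seed=config.seed, n_starts=config.n_starts,
                n_min_frac=config.n_min_frac, n_max_factor=config.n_max_factor,
            )
            if scen == "seasonal":
                sol = optimizer.solve_seasonal(panel, yparams, **common)
                warm = sol.decisions
            elif scen == "seasonal-spatial":
                sol = optimizer.solve_seasonal_spatial(
                    panel, yparams,
                    extra_starts=[warm] if warm is not None else None,
                    **common,
                )
            else:
                sol = optimizer.solve_integrated(
                    panel, me, cost, yparams, x_frac=config.x_frac, **common
                )
            kw = dict(me=me, cost=cost) if scen == "integrated" else {}
            report = optimizer.audit_solution(
                panel, sol, yparams, tol=config.feas_tol, **kw
            )
            if not report.feasible:
                raise RuntimeError(f"audit failed for scenario {scen}")
            sol.to_csv(out / f"solution_{scen}.csv")
            (out / f"report_{scen}.json").write_text(
                json.dumps(report.to_dict(), indent=2)
            )
            manifest.outputs[f"solution:{scen}"] = str(out / f"solution_{scen}.csv")
            manifest.outputs[f"report:{scen}"] = str(out / f"report_{scen}.json")
            manifest.objectives[scen] = sol.objective
            solutions.append(sol)

    with stage("compare"):
        table = compare_scenarios(solutions, panel)
        table.to_csv(out / "scenario_comparison.csv", index=False)
        manifest.outputs["comparison"] = str(out / "scenario_comparison.csv")
        per_district = district_export_table(panel, solutions)
        per_district.to_csv(out / "district_exports.csv", index=False)
        manifest.outputs["district_exports"] = str(out / "district_exports.csv")

    manifest.objectives["baseline"] = optimizer.baseline_export(panel)
    for key, path in manifest.outputs.items():
        manifest.checksums[key] = _sha256(path)
    manifest.to_json(out / "manifest.json")
    return manifest


def compare_scenarios(
    solutions: list[Solution], panel: DistrictPanel
) -> pd.DataFrame:
    """Scenario comparison table: objective (kg N exported), % reduction
    versus the baseline export, and the binding constraints."""
    if not solutions:
        raise InputError("at least one solution is required")
    base = optimizer.baseline_export(panel)
    rows = [
        dict(scenario="baseline", objective=base, pct_reduction=0.0,
             n_binding=np.nan, binding="")
    ]
    for sol in solutions:
        binding = (
            list(sol.constraints.loc[sol.constraints["binding"], "name"])
            if sol.constraints is not None
            else []
        )
        rows.append(
            dict(
                scenario=sol.scenario,
                objective=sol.objective,
                pct_reduction=100.0 * (1.0 - sol.objective / base),
                n_binding=len(binding),
                binding=";".join(binding[:12]),
            )
        )
    return pd.DataFrame(rows)


def district_export_table(
    panel: DistrictPanel, solutions: list[Solution]
) -> pd.DataFrame:
    """Per-district, per-season per-acre nitrogen export (theta * N averaged
    over crops, weighted by area), for the baseline and each solution --
    the seasonal comparison is the meaningful axis of this table."""
    theta = panel.seasons.set_index(["district_id", "season"])["theta"]

    def per_acre(df, ncol, lcol):
        th = [
            theta.loc[(int(i), int(r))]
            for i, r in zip(df["district_id"], df["season"])
        ]
        d = df.assign(_th=th)
        d["_exp"] = d["_th"] * d[ncol] * d[lcol]
        g = d.groupby(["district_id", "season"]).agg(
            _exp=("_exp", "sum"), _area=(lcol, "sum")
        )
        return (g["_exp"] / g["_area"].where(g["_area"] > 0)).rename("kg_per_acre")

    base_df = panel.cells.copy()
    lbar = panel.districts.set_index("district_id")["L_bar"]
    base_df["L"] = base_df["share"] * base_df["district_id"].map(lbar)
    base_df = base_df.rename(columns={"N_b": "N"})
    out = per_acre(base_df, "N", "L").reset_index()
    out["scenario"] = "baseline"
    frames = [out]
    for sol in solutions:
        f = per_acre(sol.decisions, "N", "L").reset_index()
        f["scenario"] = sol.scenario
        frames.append(f)
    return pd.concat(frames, ignore_index=True)[
        ["scenario", "district_id", "season", "kg_per_acre"]
    ]


def _pkg_version() -> str:
    try:
        from importlib.metadata import version

        return version("nitroplan")
    except Exception:  # pragma: no cover
        return "unknown"
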