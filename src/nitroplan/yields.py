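"""Cobb-Douglas yield function: elasticity estimation and calibration.

Yield responds to nitrogen as y = delta * N^rho with rho in (0, 1).  The
elasticities rho_rj are estimated from household samples by regressing
asinh(yield) on asinh(urea), asinh(labor) and the hybrid/HYV variety shares
with district fixed effects, separately for each season x crop cell; the
inverse hyperbolic sine behaves like the logarithm away from zero while
remaining defined at zero inputs.  The district productivities delta_irj
are then calibrated so the function reproduces every baseline yield
exactly, and the nitrogen-cost-change function feeding the integrated
optimization scenario is built from the same pieces.

Household urea rates are treated as the nitrogen-input variable; because an
elasticity is invariant to a multiplicative unit change, the estimated rho
applies to nitrogen directly, and the kg-N-per-kg-urea factor (default
0.46) only matters where absolute rates and prices meet.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    CROPS,
    SEASONS,
    CostBaseline,
    DistrictPanel,
    HouseholdSample,
    InputError,
    YieldParams,
)
from .landuse import SIGNIFICANCE_LEVEL, EstimationError

logger = logging.getLogger(__name__)

#: kg of nitrogen per kg of urea (configurable unit bridge)
UREA_N_FACTOR = 0.46

_REGRESSORS = ("urea", "labor", "hybrid", "hyv")


def ihs(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)): log-like, exact at 0."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise InputError("ihs requires finite input")
    return np.arcsinh(x)


def urea_to_n(urea, factor: float = UREA_N_FACTOR):
    """Convert a urea application rate to a nitrogen rate."""
    return np.asarray(urea, dtype=float) * factor


def _fit_cell(sub: pd.DataFrame, min_per_district: int = 2):
    """Within-district (fixed-effects) least squares for one season x crop
    cell.  Returns a dict of results; collinear regressors are dropped with
    a logged warning."""
    counts = sub.groupby("district_id")["yield_"].size()
    keep = counts[counts >= min_per_district].index
    dropped_districts = len(counts) - len(keep)
    if dropped_districts:
        logger.warning(
            "dropping %d districts with < %d households", dropped_districts,
            min_per_district,
        )
    sub = sub[sub["district_id"].isin(keep)]
    if sub.empty:
        raise EstimationError("no districts with enough households")

    y = ihs(sub["yield_"].to_numpy())
    X = np.column_stack(
        [
            ihs(sub["urea"].to_numpy()),
            ihs(sub["labor"].to_numpy()),
            sub["hybrid_share"].to_numpy(),
            sub["hyv_share"].to_numpy(),
        ]
    )
    d_codes, d_index = pd.factorize(sub["district_id"], sort=True)
    n_d = len(d_index)

    # absorb district fixed effects by within-demeaning
    def demean(v):
        means = np.bincount(d_codes, weights=v) / np.bincount(d_codes)
        return v - means[d_codes], means

    yd, _ = demean(y)
    Xd = np.empty_like(X)
    for c in range(X.shape[1]):
        Xd[:, c], _ = demean(X[:, c])

    # drop regressors that are collinear after demeaning (QR pivot scan)
    kept: list[int] = []
    for c in range(Xd.shape[1]):
        cand = Xd[:, kept + [c]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == len(
            kept
        ) + 1:
            kept.append(c)
        else:
            logger.warning(
                "dropping collinear regressor %r (perfectly explained by "
                "district effects and retained regressors)", _REGRESSORS[c],
            )
    if not kept:
        raise EstimationError("all regressors perfectly collinear")

    Xk = Xd[:, kept]
    beta, _, _, _ = np.linalg.lstsq(Xk, yd, rcond=None)
    resid = yd - Xk @ beta
    n = len(yd)
    dof = n - len(kept) - n_d
    if dof <= 0:
        raise EstimationError("not enough degrees of freedom")
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xk.T @ Xk)
    se = np.sqrt(np.diag(cov))
    tss = float(yd @ yd)
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan

    # district effects: mean of (y - X beta) within district
    full_beta = np.zeros(X.shape[1])
    full_beta[kept] = beta
    fe_resid = y - X @ full_beta
    fe = np.bincount(d_codes, weights=fe_resid) / np.bincount(d_codes)

    from scipy import stats

    res = dict(estimates={}, fe=dict(zip(d_index, fe)), r2=r2, n=n, n_districts=n_d)
    for pos, c in enumerate(kept):
        est, s = beta[pos], se[pos]
        t = est / s if s > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(t), df=dof) if s > 0 else 0.0
        res["estimates"][_REGRESSORS[c]] = (est, s, t, p)
    res["dropped"] = [_REGRESSORS[c] for c in range(X.shape[1]) if c not in kept]
    return res


def estimate_elasticities(
    hh: HouseholdSample, min_per_district: int = 2
) -> YieldParams:
    """Estimate the yield equation separately for each season x crop cell.

    asinh(yield) ~ asinh(urea) + asinh(labor) + hybrid + hyv with district
    fixed effects absorbed by within-demeaning.  The coefficient on urea is
    the yield-nitrogen elasticity rho_rj.  Collinear regressors (e.g. a
    variety share that is constant given the others) are dropped with a
    logged warning and carry NaN estimates.
    """
    df = hh.data
    coef_rows, stat_rows, fe_rows = [], [], []
    for r in SEASONS:
        for j in CROPS:
            sub = df[(df["season"] == r) & (df["crop"] == j)]
            if sub.empty:
                raise EstimationError(f"no households for season={r}, crop={j}")
            res = _fit_cell(sub, min_per_district)
            for term in _REGRESSORS:
                if term in res["estimates"]:
                    est, se, t, p = res["estimates"][term]
                    coef_rows.append(
                        dict(
                            season=r, crop=j, term=term, estimate=est, se=se,
                            tstat=t, p=p, significant=p < SIGNIFICANCE_LEVEL,
                        )
                    )
                else:
                    coef_rows.append(
                        dict(
                            season=r, crop=j, term=term, estimate=np.nan,
                            se=np.nan, tstat=np.nan, p=np.nan, significant=False,
                        )
                    )
            stat_rows.append(
                dict(
                    season=r, crop=j, r2=res["r2"], n_obs=res["n"],
                    n_districts=res["n_districts"],
                    dropped=",".join(res["dropped"]),
                )
            )
            for d, e in res["fe"].items():
                fe_rows.append(dict(season=r, crop=j, district_id=d, effect=e))
    return YieldParams(
        coefficients=pd.DataFrame(coef_rows),
        fit_stats=pd.DataFrame(stat_rows),
        fixed_effects=pd.DataFrame(fe_rows),
    )


# ---------------------------------------------------------------------------
# calibration and the yield / cost functions
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    pass


def yield_at(delta, rho, N):
    """Cobb-Douglas yield delta * N^rho (kg/acre); 0 at N = 0 for rho > 0."""
    N = np.asarray(N, dtype=float)
    if (N < 0).any():
        raise InputError("nitrogen rates must be >= 0")
    return np.asarray(delta, dtype=float) * N ** np.asarray(rho, dtype=float)


def calibrate_delta(panel: DistrictPanel, params: YieldParams) -> pd.DataFrame:
    """Calibrate delta_irj = y_b / N_b^rho for every panel cell, so that the
    yield function reproduces the baseline yields exactly.  The resulting
    table is also stored on ``params.delta``."""
    cells = panel.cells
    bad = (cells["N_b"] <= 0) & (cells["y_b"] > 0)
    if bad.any():
        idx = cells[bad].iloc[0]
        raise CalibrationError(
            "zero baseline nitrogen with positive yield at district "
            f"{int(idx['district_id'])}, season {int(idx['season'])}, "
            f"crop {int(idx['crop'])}"
        )
    rho_map = {
        (r["season"], r["crop"]): r["rho"]
        for _, r in params.rho_table().iterrows()
    }
    rho = np.array(
        [rho_map[(r, j)] for r, j in zip(cells["season"], cells["crop"])]
    )
    delta = cells["y_b"].to_numpy() / cells["N_b"].to_numpy() ** rho
    out = pd.DataFrame(
        dict(
            district_id=cells["district_id"],
            season=cells["season"],
            crop=cells["crop"],
            rho=rho,
            delta=delta,
        )
    ).reset_index(drop=True)
    params.delta = out
    return out


def cost_baseline(panel: DistrictPanel) -> CostBaseline:
    """Baseline average nitrogen cost per unit output,
    c_b = pN * N_b / y_b (Taka per kg of output)."""
    cells = panel.cells.merge(
        panel.seasons[["district_id", "season", "pN"]],
        on=["district_id", "season"],
    )
    table = cells[["district_id", "season", "crop", "pN", "N_b", "y_b"]].copy()
    table["c_b"] = table["pN"] * table["N_b"] / table["y_b"]
    cb = CostBaseline(table)
    cb.validate()
    return cb


def cost_change(c_b, pN, delta, rho, N):
    """Change in average nitrogen cost per unit output at nitrogen rate N:
    Delta c = pN * N / y(N) - c_b.  Zero at the baseline rate; strictly
    increasing in N for rho < 1."""
    y = yield_at(delta, rho, N)
    if np.any(np.asarray(y) <= 0):
        raise CalibrationError("yield is zero at the requested nitrogen rate")
    return np.asarray(pN, dtype=float) * np.asarray(N, dtype=float) / y - np.asarray(
        c_b, dtype=float
    )
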