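"""Econometric land-use share system.

A logistic share system over three seasonal land uses (rice, non-rice,
idle) is linearised by taking log-odds against the idle (residual)
category:

    ln(s_rj / s_r0) = (s0_rj - s0_r0) * alpha_r + x_rj * beta_rj + z_r' eta_rj

for seasons r = 1..3 and crops j = 1, 2 -- six linear equations estimated
jointly by iterated feasible-GLS seemingly unrelated regression (SUR), with
the inertia coefficient alpha_r restricted to be equal across the two crop
equations of a season.  Analytic price marginal effects of the logistic
system, evaluated at baseline shares, feed the integrated optimization
scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CROPS,
    IDLE,
    SEASONS,
    InputError,
    MarginalEffects,
    ShareDataset,
    SURCoefficients,
)

logger = logging.getLogger(__name__)

#: two-sided significance level used to zero price coefficients downstream
SIGNIFICANCE_LEVEL = 0.10

#: default floor applied to zero shares before the log-odds transform
SHARE_FLOOR = 1e-4


class EstimationError(RuntimeError):
    """The share system (or one of its equations) cannot be estimated."""


# ---------------------------------------------------------------------------
# logistic <-> log-odds
# ---------------------------------------------------------------------------

def shares_from_logodds(logodds: np.ndarray) -> np.ndarray:
    """Share triples (idle, rice, non-rice) from log-odds vs idle.

    ``logodds``: array (..., 2) of (u_r1, u_r2).  Overflow-safe: the idle
    logit 0 is appended and a max-shift softmax applied, so arbitrarily
    large inputs saturate instead of overflowing.
    """
    u = np.asarray(logodds, dtype=float)
    if u.shape[-1] != 2:
        raise InputError("logodds must have a trailing dimension of 2")
    full = np.concatenate([np.zeros(u.shape[:-1] + (1,)), u], axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _floor_shares(s: np.ndarray, floor: float) -> tuple[np.ndarray, int]:
    """Clip share triples at ``floor`` and renormalise; returns the floored
    array and the number of triples that needed flooring."""
    n_floored = int((s < floor).any(axis=-1).sum())
    out = np.maximum(s, floor)
    out = out / out.sum(axis=-1, keepdims=True)
    return out, n_floored


def logodds_transform(
    data: ShareDataset, floor: float = SHARE_FLOOR
) -> tuple[pd.DataFrame, int]:
    """Stacked regression table for the six log-odds equations.

    Returns (table, n_floored).  One row per district x season x crop with
    the response ``y`` = ln(s_rj / s_r0) and the regressors ``inertia`` =
    s0_rj - s0_r0, ``dprice``, ``droad``, ``dprecip``.  Zero shares are
    floored at ``floor`` (with renormalisation) before taking logs; the
    count of floored district x season triples is logged and returned.
    """
    df = data.data
    wide_s = df.pivot_table(
        index=["district_id", "season"], columns="use", values="share"
    )
    wide_l = df.pivot_table(
        index=["district_id", "season"], columns="use", values="lag_share"
    )
    s, nf1 = _floor_shares(wide_s[[0, 1, 2]].to_numpy(), floor)
    s0, nf2 = _floor_shares(wide_l[[0, 1, 2]].to_numpy(), floor)
    n_floored = nf1 + nf2
    if n_floored:
        logger.info("floored %d share triples at %g before log-odds", n_floored, floor)
    idx = wide_s.index
    covs = df[df["use"] != IDLE].set_index(["district_id", "season", "use"])
    rows = []
    for j in CROPS:
        y = np.log(s[:, j] / s[:, IDLE])
        inertia = s0[:, j] - s0[:, IDLE]
        sub = covs.xs(j, level="use").reindex(idx)
        rows.append(
            pd.DataFrame(
                dict(
                    district_id=idx.get_level_values(0),
                    season=idx.get_level_values(1),
                    crop=j,
                    y=y,
                    inertia=inertia,
                    dprice=sub["dprice"].to_numpy(),
                    droad=sub["droad"].to_numpy(),
                    dprecip=sub["dprecip"].to_numpy(),
                )
            )
        )
    table = pd.concat(rows, ignore_index=True).sort_values(
        ["season", "crop", "district_id"], ignore_index=True
    )
    if not np.isfinite(table["y"]).all():
        raise EstimationError("non-finite log-odds after flooring")
    return table, n_floored


# ---------------------------------------------------------------------------
# iterated feasible-GLS for a linear system with cross-equation restrictions
# ---------------------------------------------------------------------------

@dataclass
class FglsResult:
    params: np.ndarray
    se: np.ndarray
    sigma: np.ndarray
    n_iterations: int
    converged: bool
    system_r2: float
    dof: int


def fgls_system(
    X_blocks: list[np.ndarray],
    y_blocks: list[np.ndarray],
    col_maps: list[np.ndarray],
    n_params: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FglsResult:
    """Iterated feasible-GLS for a multi-equation linear system.

    Equation e regresses ``y_blocks[e]`` (length n) on ``X_blocks[e]``
    (n x k_e); ``col_maps[e]`` maps each local column to a global parameter
    index, which is how cross-equation equality restrictions (a shared
    column index) are imposed.  The cross-equation error covariance is
    estimated from first-stage (joint OLS) residuals with a residual
    degrees-of-freedom correction and iterated to convergence.

    When the regressor matrices are identical across equations and no
    restriction links equations, the GLS estimate collapses to
    equation-by-equation OLS for any error covariance (the classical SUR
    equivalence), which this implementation reproduces.
    """
    m = len(X_blocks)
    n = len(y_blocks[0])

    def _inv(S):
        # near-singular covariances (few observations, or a noiseless fit)
        # fall back to the pseudo-inverse
        if np.linalg.cond(S) > 1e12:
            return np.linalg.pinv(S)
        return np.linalg.inv(S)
    for e in range(m):
        if len(y_blocks[e]) != n or X_blocks[e].shape[0] != n:
            raise EstimationError("all equations must share the observation count")
        k_e = X_blocks[e].shape[1]
        if n < k_e + 2:
            raise EstimationError(f"equation {e}: too few observations ({n})")
        if np.linalg.matrix_rank(X_blocks[e]) < k_e:
            raise EstimationError(f"equation {e}: singular regressor matrix")

    def solve_weighted(W: np.ndarray) -> np.ndarray:
        A = np.zeros((n_params, n_params))
        b = np.zeros(n_params)
        for e in range(m):
            for f in range(m):
                w = W[e, f]
                if w == 0.0:
                    continue
                xtx = X_blocks[e].T @ X_blocks[f]
                A[np.ix_(col_maps[e], col_maps[f])] += w * xtx
                b[col_maps[e]] += w * (X_blocks[e].T @ y_blocks[f])
        try:
            params = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise EstimationError("singular system design matrix") from exc
        return params, A

    def residual_matrix(params: np.ndarray) -> np.ndarray:
        E = np.empty((n, m))
        for e in range(m):
            E[:, e] = y_blocks[e] - X_blocks[e] @ params[col_maps[e]]
        return E

    # stage 1: joint OLS (identity weighting)
    params, _ = solve_weighted(np.eye(m))
    k_eq = np.array([X.shape[1] for X in X_blocks], dtype=float)
    dof_corr = n - k_eq.mean()
    E = residual_matrix(params)
    sigma = E.T @ E / dof_corr

    converged = False
    it = 0
    A = None
    if sigma.diagonal().max() < 1e-24:
        # noiseless system: OLS is exact, covariance degenerate
        converged = True
        W = np.eye(m)
        _, A = solve_weighted(W)
        se = np.zeros(n_params)
    else:
        for it in range(1, max_iter + 1):
            W = _inv(sigma)
            params, A = solve_weighted(W)
            E = residual_matrix(params)
            sigma_new = E.T @ E / dof_corr
            if np.max(np.abs(sigma_new - sigma)) < tol:
                sigma = sigma_new
                converged = True
                break
            sigma = sigma_new
        W = _inv(sigma)
        params, A = solve_weighted(W)
        cov = np.linalg.inv(A)
        se = np.sqrt(np.diag(cov))

    # McElroy's system R^2: 1 - e'(S^-1 x I)e / yd'(S^-1 x I)yd
    if sigma.diagonal().max() < 1e-24:
        system_r2 = 1.0
    else:
        W = _inv(sigma)
        E = residual_matrix(params)
        Yd = np.column_stack([y - y.mean() for y in y_blocks])
        num = float(np.einsum("ne,ef,nf->", E, W, E))
        den = float(np.einsum("ne,ef,nf->", Yd, W, Yd))
        system_r2 = 1.0 - num / den if den > 0 else np.nan
    dof = n * m - n_params
    return FglsResult(params, se, sigma, it, converged, system_r2, dof)


def estimate_sur(
    data: ShareDataset,
    floor: float = SHARE_FLOOR,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SURCoefficients:
    """Estimate the six-equation land-use share system by iterated FGLS SUR.

    The inertia coefficient alpha_r is restricted to be equal across the two
    crop equations of each season; each equation also carries its own price
    coefficient beta_rj and covariate-change effects eta_rj (road density,
    precipitation).  Significance flags use a two-sided 10% t-test.
    """
    stacked, n_floored = logodds_transform(data, floor)

    # global parameter layout: 3 alphas, then (beta, eta_road, eta_precip)
    # per (season, crop) in equation order
    param_index: dict[tuple, int] = {}
    for r in SEASONS:
        param_index[("inertia", r, None)] = len(param_index)
    for r in SEASONS:
        for j in CROPS:
            for term in ("dprice", "droad", "dprecip"):
                param_index[(term, r, j)] = len(param_index)
    n_params = len(param_index)

    X_blocks, y_blocks, col_maps, eq_labels = [], [], [], []
    for r in SEASONS:
        for j in CROPS:
            sub = stacked[(stacked["season"] == r) & (stacked["crop"] == j)]
            sub = sub.sort_values("district_id")
            X = sub[["inertia", "dprice", "droad", "dprecip"]].to_numpy()
            y = sub["y"].to_numpy()
            cmap = np.array(
                [
                    param_index[("inertia", r, None)],
                    param_index[("dprice", r, j)],
                    param_index[("droad", r, j)],
                    param_index[("dprecip", r, j)],
                ]
            )
            X_blocks.append(X)
            y_blocks.append(y)
            col_maps.append(cmap)
            eq_labels.append((r, j))

    res = fgls_system(X_blocks, y_blocks, col_maps, n_params, tol, max_iter)

    rows = []
    for (term, r, j), idx in param_index.items():
        est, se = res.params[idx], res.se[idx]
        if se > 0:
            t = est / se
            p = 2.0 * stats.t.sf(abs(t), df=res.dof)
        else:
            t, p = np.inf if est != 0 else 0.0, 0.0
        rows.append(
            dict(
                term=term,
                season=r,
                crop=j if j is not None else np.nan,
                estimate=est,
                se=se,
                tstat=t,
                p=p,
                significant=p < SIGNIFICANCE_LEVEL,
            )
        )
    table = pd.DataFrame(rows)
    return SURCoefficients(
        table=table,
        system_r2=res.system_r2,
        sigma=res.sigma,
        n_obs=len(y_blocks[0]),
        n_iterations=res.n_iterations,
        converged=res.converged,
        n_floored=n_floored,
    )


# ---------------------------------------------------------------------------
# prediction and marginal effects
# ---------------------------------------------------------------------------

def linear_predictors(coef: SURCoefficients, data: ShareDataset) -> pd.DataFrame:
    """Fitted log-odds u_rj per district x season (columns u1, u2)."""
    stacked, _ = logodds_transform(data)
    out = []
    for r in SEASONS:
        for j in CROPS:
            sub = stacked[(stacked["season"] == r) & (stacked["crop"] == j)]
            u = (
                sub["inertia"].to_numpy() * coef.alpha(r)
                + sub["dprice"].to_numpy() * coef.beta(r, j)
                + sub[["droad", "dprecip"]].to_numpy() @ coef.eta(r, j)
            )
            out.append(
                pd.DataFrame(
                    dict(
                        district_id=sub["district_id"].to_numpy(),
                        season=r,
                        crop=j,
                        u=u,
                    )
                )
            )
    long = pd.concat(out, ignore_index=True)
    wide = long.pivot_table(
        index=["district_id", "season"], columns="crop", values="u"
    ).rename(columns={1: "u1", 2: "u2"})
    return wide.reset_index()


def predict_shares(coef: SURCoefficients, data: ShareDataset) -> pd.DataFrame:
    """Predicted share triples via the logistic transform of the fitted
    log-odds; every row is a probability vector by construction."""
    lp = linear_predictors(coef, data)
    shares = shares_from_logodds(lp[["u1", "u2"]].to_numpy())
    out = lp[["district_id", "season"]].copy()
    out["s_idle"] = shares[:, 0]
    out["s_rice"] = shares[:, 1]
    out["s_nonrice"] = shares[:, 2]
    return out


def marginal_effects(
    coef: SURCoefficients,
    baseline_shares: pd.DataFrame,
    zero_insignificant: bool = True,
) -> MarginalEffects:
    """Analytic price marginal effects of the logistic share system.

    ``baseline_shares``: district_id, season, crop, share (crop rows only).
    Own effect d s_rj / d x_rj = s_rj (1 - s_rj) beta_rj; cross effect
    d s_rj / d x_rk = -s_rj s_rk beta_rk (j != k).  Price coefficients that
    are statistically insignificant at the 10% level are set to zero when
    ``zero_insignificant`` is on.  Idle rows (use 0) are the derived
    responses -sum_j d s_rj / d x_rk.
    """
    beta = {}
    for r in SEASONS:
        for k in CROPS:
            b = coef.beta(r, k)
            if zero_insignificant and not coef.beta_significant(r, k):
                b = 0.0
            beta[(r, k)] = b
    wide = baseline_shares.pivot_table(
        index=["district_id", "season"], columns="crop", values="share"
    )
    rows = []
    for (i, r), srow in wide.iterrows():
        s = {j: float(srow[j]) for j in CROPS}
        for k in CROPS:
            col_sum = 0.0
            for j in CROPS:
                eff = s[j] * ((1.0 if j == k else 0.0) - s[k]) * beta[(r, k)]
                col_sum += eff
                rows.append(
                    dict(district_id=i, season=r, use=j, wrt_crop=k, effect=eff)
                )
            rows.append(
                dict(district_id=i, season=r, use=IDLE, wrt_crop=k, effect=-col_sum)
            )
    table = pd.DataFrame(rows).sort_values(
        ["district_id", "season", "use", "wrt_crop"], ignore_index=True
    )
    return MarginalEffects(table=table, zeroed_insignificant=zero_insignificant)
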