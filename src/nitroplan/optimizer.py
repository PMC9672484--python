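"""Nitrogen-export minimization programs.

Minimize national nitrogen export  sum_irj theta_ir N_irj L_irj  over
per-acre nitrogen rates N and harvested areas L (or net-price instruments
x in the integrated scenario), subject to

* an economic constraint: production revenue at least the baseline value,
  imposed per district (seasonal scenario) or nationally (seasonal-spatial
  and integrated scenarios);
* a food-security constraint: national rice production at least baseline;
* seasonal land availability: cropped area per district x season no more
  than the agroecological seasonal potential CIp_ir * L_bar_i;
* annual land availability: harvested area per district no more than
  CI_i * L_bar_i.

Yields follow the calibrated Cobb-Douglas function y = delta N^rho.  The
integrated scenario replaces L by the linearised share response to price
changes and prices revenue at p + x + Delta_c(N).  Problems are solved with
multistart SLSQP from the (always feasible) baseline point; an independent
audit re-evaluates every constraint from the raw decision values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .containers import (
    CROPS,
    RICE,
    CostBaseline,
    DistrictPanel,
    InputError,
    MarginalEffects,
    Solution,
    YieldParams,
)

logger = logging.getLogger(__name__)

#: default decision-variable bounds: N in [N_MIN_FRAC * N_b, N_MAX_FACTOR *
#: district max baseline]; |x| at most X_FRAC of the baseline price
N_MIN_FRAC = 0.05
N_MAX_FACTOR = 2.0
X_FRAC = 0.25

FEAS_TOL = 1e-6  # relative feasibility tolerance (audit and incumbent choice)


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# panel -> flat arrays
# ---------------------------------------------------------------------------

@dataclass
class _Model:
    cells: pd.DataFrame
    n_c: int
    d_of_c: np.ndarray      # district index per cell
    ir_of_c: np.ndarray     # (district, season) pair index per cell
    theta: np.ndarray
    price: np.ndarray
    Nb: np.ndarray
    yb: np.ndarray
    delta: np.ndarray
    rho: np.ndarray
    s_b: np.ndarray
    Lbar_c: np.ndarray      # district physical cropland per cell
    pN: np.ndarray
    is_rice: np.ndarray
    district_ids: np.ndarray
    Lbar_i: np.ndarray
    CI_i: np.ndarray
    vb_i: np.ndarray
    n_ir: int
    CIp_ir: np.ndarray
    d_of_ir: np.ndarray
    ir_keys: list[tuple[int, int]]
    v_b: float
    Y1_b: float
    u_max: np.ndarray


def _delta_table(panel: DistrictPanel, yparams: YieldParams | pd.DataFrame) -> pd.DataFrame:
    if isinstance(yparams, pd.DataFrame):
        return yparams
    if yparams.delta is None:
        from .yields import calibrate_delta

        calibrate_delta(panel, yparams)
    return yparams.delta


def _build_model(
    panel: DistrictPanel,
    yparams: YieldParams | pd.DataFrame,
    n_min_frac: float = N_MIN_FRAC,
    n_max_factor: float = N_MAX_FACTOR,
) -> _Model:
    delta = _delta_table(panel, yparams)
    cells = (
        panel.cells.merge(
            panel.seasons[["district_id", "season", "theta", "CIp", "pN"]],
            on=["district_id", "season"],
        )
        .merge(delta, on=["district_id", "season", "crop"])
        .sort_values(["district_id", "season", "crop"], ignore_index=True)
    )
    if len(cells) != len(panel.cells):
        raise InputError(
            "theta/delta tables do not cover every panel cell "
            f"({len(cells)} of {len(panel.cells)} matched)"
        )
    d = panel.districts.sort_values("district_id", ignore_index=True)
    d_ids = d["district_id"].to_numpy()
    d_pos = {int(i): k for k, i in enumerate(d_ids)}
    d_of_c = np.array([d_pos[int(i)] for i in cells["district_id"]])
    ir_keys = sorted(
        {(int(i), int(r)) for i, r in zip(cells["district_id"], cells["season"])}
    )
    ir_pos = {k: n for n, k in enumerate(ir_keys)}
    ir_of_c = np.array(
        [ir_pos[(int(i), int(r))] for i, r in zip(cells["district_id"], cells["season"])]
    )
    smap = panel.seasons.set_index(["district_id", "season"])
    CIp_ir = np.array([smap.loc[k, "CIp"] for k in ir_keys])
    d_of_ir = np.array([d_pos[k[0]] for k in ir_keys])

    Nb = cells["N_b"].to_numpy()
    nb_max_d = np.zeros(len(d_ids))
    np.maximum.at(nb_max_d, d_of_c, Nb)
    u_max = n_max_factor * nb_max_d[d_of_c] / Nb

    return _Model(
        cells=cells,
        n_c=len(cells),
        d_of_c=d_of_c,
        ir_of_c=ir_of_c,
        theta=cells["theta"].to_numpy(),
        price=cells["price"].to_numpy(),
        Nb=Nb,
        yb=cells["y_b"].to_numpy(),
        delta=cells["delta"].to_numpy(),
        rho=cells["rho"].to_numpy(),
        s_b=cells["share"].to_numpy(),
        Lbar_c=d["L_bar"].to_numpy()[d_of_c],
        pN=cells["pN"].to_numpy(),
        is_rice=(cells["crop"] == RICE).to_numpy(),
        district_ids=d_ids,
        Lbar_i=d["L_bar"].to_numpy(),
        CI_i=d["CI"].to_numpy(),
        vb_i=d["v_b"].to_numpy(),
        n_ir=len(ir_keys),
        CIp_ir=CIp_ir,
        d_of_ir=d_of_ir,
        ir_keys=ir_keys,
        v_b=panel.v_b,
        Y1_b=panel.Y1_b,
        u_max=np.maximum(u_max, n_min_frac + 1e-9),
    )


def baseline_export(panel: DistrictPanel) -> float:
    """Total nitrogen export (kg) at the baseline allocation:
    sum_irj theta_ir * N_b_irj * s_b_irj * L_bar_i."""
    cells = panel.cells.merge(
        panel.seasons[["district_id", "season", "theta"]],
        on=["district_id", "season"],
    )
    lbar = panel.districts.set_index("district_id")["L_bar"]
    area = cells["share"] * cells["district_id"].map(lbar)
    return float((cells["theta"] * cells["N_b"] * area).sum())


# ---------------------------------------------------------------------------
# seasonal / seasonal-spatial scenarios: decisions (N, L)
# ---------------------------------------------------------------------------

def _group_matrix(idx: np.ndarray, n_groups: int, n_vars: int, offset: int) -> np.ndarray:
    """0/1 aggregation matrix M (n_groups x n_vars) with M[idx[c], offset+c]=1."""
    M = np.zeros((n_groups, n_vars))
    M[idx, offset + np.arange(len(idx))] = 1.0
    return M


def _solve_nl(
    panel: DistrictPanel,
    yparams,
    revenue_scope: str,
    scenario: str,
    seed: int = 0,
    n_starts: int = 5,
    revenue_target: float | np.ndarray | None = None,
    rice_target: float | None = None,
    fix_land: bool = False,
    n_min_frac: float = N_MIN_FRAC,
    n_max_factor: float = N_MAX_FACTOR,
    extra_starts: list[pd.DataFrame] | None = None,
    maxiter: int = 400,
) -> Solution:
    m = _build_model(panel, yparams, n_min_frac, n_max_factor)
    n = m.n_c
    nv = 2 * n  # z = [u (N / N_b), ell (L / L_bar)]

    if revenue_scope == "district":
        v_t = m.vb_i.copy() if revenue_target is None else np.broadcast_to(
            np.asarray(revenue_target, dtype=float), m.vb_i.shape
        ).copy()
    else:
        v_t = float(m.v_b if revenue_target is None else revenue_target)
    Y1_t = float(m.Y1_b if rice_target is None else rice_target)
    have_rice = bool(m.is_rice.any()) and Y1_t > 0

    def split(z):
        return z[:n], z[n:]

    f_scale = max(baseline_export(panel), 1e-12)

    def objective(z):
        u, ell = split(z)
        return float(np.sum(m.theta * m.Nb * u * m.Lbar_c * ell)) / f_scale

    def objective_grad(z):
        u, ell = split(z)
        g = np.empty(nv)
        g[:n] = m.theta * m.Nb * m.Lbar_c * ell
        g[n:] = m.theta * m.Nb * u * m.Lbar_c
        return g / f_scale

    def cell_revenue(u, ell):
        return ell * m.Lbar_c * m.price * m.delta * (m.Nb * u) ** m.rho

    # revenue constraint(s)
    if revenue_scope == "district":
        n_d = len(m.district_ids)

        def rev_fun(z):
            u, ell = split(z)
            val = np.zeros(n_d)
            np.add.at(val, m.d_of_c, cell_revenue(u, ell))
            return val / v_t - 1.0

        def rev_jac(z):
            u, ell = split(z)
            raw = m.Lbar_c * m.price * m.delta * (m.Nb * u) ** m.rho
            J = np.zeros((n_d, nv))
            J[m.d_of_c, np.arange(n)] = m.rho * raw * ell / u
            J[m.d_of_c, n + np.arange(n)] = raw
            return J / v_t[:, None]
    else:
        def rev_fun(z):
            u, ell = split(z)
            return np.array([np.sum(cell_revenue(u, ell)) / v_t - 1.0])

        def rev_jac(z):
            u, ell = split(z)
            raw = m.Lbar_c * m.price * m.delta * (m.Nb * u) ** m.rho
            J = np.zeros((1, nv))
            J[0, :n] = m.rho * raw * ell / u
            J[0, n:] = raw
            return J / v_t

    def rice_fun(z):
        u, ell = split(z)
        prod = ell * m.Lbar_c * m.delta * (m.Nb * u) ** m.rho
        return np.array([np.sum(prod[m.is_rice]) / Y1_t - 1.0])

    def rice_jac(z):
        u, ell = split(z)
        prod = ell * m.Lbar_c * m.delta * (m.Nb * u) ** m.rho
        J = np.zeros((1, nv))
        J[0, :n] = np.where(m.is_rice, m.rho * prod / u, 0.0)
        raw = m.Lbar_c * m.delta * (m.Nb * u) ** m.rho
        J[0, n:] = np.where(m.is_rice, raw, 0.0)
        return J / Y1_t

    # seasonal land (7d): CIp_ir - sum_j ell >= 0 (linear)
    A_ir = _group_matrix(m.ir_of_c, m.n_ir, nv, offset=n)
    # annual land (7e): CI_i - sum_rj ell >= 0 (linear)
    A_i = _group_matrix(m.d_of_c, len(m.district_ids), nv, offset=n)

    have_revenue = (
        bool(np.all(v_t > 0)) if revenue_scope == "district" else v_t > 0
    )
    constraints = [
        dict(
            type="ineq",
            fun=lambda z: m.CIp_ir - A_ir @ z,
            jac=lambda z: -A_ir,
        ),
        dict(
            type="ineq",
            fun=lambda z: m.CI_i - A_i @ z,
            jac=lambda z: -A_i,
        ),
    ]
    if have_rice:
        constraints.insert(0, dict(type="ineq", fun=rice_fun, jac=rice_jac))
    if have_revenue:
        constraints.insert(0, dict(type="ineq", fun=rev_fun, jac=rev_jac))

    if fix_land:
        ell_lo = ell_hi = m.s_b
    else:
        ell_lo, ell_hi = np.zeros(n), m.CIp_ir[m.ir_of_c]
    bounds = list(zip(np.full(n, n_min_frac), m.u_max)) + list(zip(ell_lo, ell_hi))

    def max_violation(z):
        worst = 0.0
        for con in constraints:
            worst = max(worst, float(-np.min(con["fun"](z))))
        u, ell = split(z)
        worst = max(worst, float(np.max(n_min_frac - u)), float(np.max(u - m.u_max)))
        worst = max(worst, float(np.max(ell_lo - ell)), float(np.max(ell - ell_hi)))
        return worst

    z_base = np.concatenate([np.ones(n), m.s_b])
    rng = np.random.default_rng([seed, 7701])
    starts = [z_base]
    for _ in range(max(0, n_starts - 1)):
        jit = z_base * (1.0 + 0.1 * rng.standard_normal(nv))
        jit[:n] = np.clip(jit[:n], n_min_frac, m.u_max)
        jit[n:] = np.clip(jit[n:], ell_lo, ell_hi)
        starts.append(jit)
    for df in extra_starts or []:
        zs = _decisions_to_z(df, m, n_min_frac)
        zs[:n] = np.clip(zs[:n], n_min_frac, m.u_max)
        zs[n:] = np.clip(zs[n:], ell_lo, ell_hi)
        starts.append(zs)

    candidates = [(objective(z_base), z_base, "baseline incumbent", -1)]
    log = []
    for k, z0 in enumerate(starts):
        res = minimize(
            objective,
            z0,
            jac=objective_grad,
            bounds=bounds,
            constraints=constraints,
            method="SLSQP",
            options=dict(maxiter=maxiter, ftol=1e-12),
        )
        viol = max_violation(res.x)
        feasible = viol <= FEAS_TOL
        log.append(
            dict(start=k, objective=float(res.fun), status=res.message,
                 feasible=feasible, violation=viol)
        )
        if feasible:
            candidates.append((float(res.fun), res.x, res.message, k))

    candidates.sort(key=lambda t: t[0])
    fbest, zbest, msg, kbest = candidates[0]
    u, ell = split(zbest)
    decisions = m.cells[["district_id", "season", "crop"]].copy()
    decisions["N"] = m.Nb * u
    decisions["L"] = m.Lbar_c * ell
    sol = Solution(
        scenario=scenario,
        decisions=decisions,
        objective=fbest * f_scale,
        status=msg,
        success=True,
        n_starts=len(starts),
        start_used=kbest,
        seed=seed,
        iterations=log,
    )
    report = audit_solution(
        panel, sol, yparams,
        revenue_target=revenue_target, rice_target=rice_target,
    )
    sol.constraints = report.constraints
    if not report.feasible:  # pragma: no cover - baseline is always feasible
        sol.success = False
        sol.status = f"no feasible point found (best violation reported); {msg}"
    return sol


def _decisions_to_z(df: pd.DataFrame, m: _Model, n_min_frac: float) -> np.ndarray:
    merged = m.cells[["district_id", "season", "crop"]].merge(
        df, on=["district_id", "season", "crop"], how="left"
    )
    if merged["N"].isna().any() or merged["L"].isna().any():
        raise InputError("warm-start decisions do not cover the panel cells")
    u = merged["N"].to_numpy() / m.Nb
    ell = merged["L"].to_numpy() / m.Lbar_c
    return np.concatenate([u, ell])


def solve_seasonal(panel: DistrictPanel, yparams, **kw) -> Solution:
    """Seasonal scenario: optimize (N, L) with the revenue floor imposed in
    every district separately (farmers in each district no worse off)."""
    return _solve_nl(panel, yparams, revenue_scope="district",
                     scenario="seasonal", **kw)


def solve_seasonal_spatial(panel: DistrictPanel, yparams, **kw) -> Solution:
    """Seasonal-spatial scenario: as seasonal, but with a single national
    revenue floor (the country's farmers as a whole no worse off); its
    feasible set contains the seasonal scenario's."""
    return _solve_nl(panel, yparams, revenue_scope="national",
                     scenario="seasonal-spatial", **kw)


# ---------------------------------------------------------------------------
# integrated scenario: decisions (N, x)
# ---------------------------------------------------------------------------

def solve_integrated(
    panel: DistrictPanel,
    me: MarginalEffects,
    cost: CostBaseline,
    yparams,
    seed: int = 0,
    n_starts: int = 5,
    x_frac: float = X_FRAC,
    revenue_target: float | None = None,
    rice_target: float | None = None,
    n_min_frac: float = N_MIN_FRAC,
    n_max_factor: float = N_MAX_FACTOR,
    maxiter: int = 400,
) -> Solution:
    """Integrated scenario: optimize per-acre nitrogen and the net-price
    instruments (x_ir1, x_ir2); areas follow the linearised share response
    L_irj(x) = L_bar_i (s_b_irj + sum_k me_irjk x_irk), with the implied
    shares constrained to [0, 1] explicitly.  Revenue is priced at
    p + x + Delta_c(N), the net price adjusted for the instrument and the
    nitrogen-cost change.

    If every marginal effect is zero (all price coefficients insignificant),
    the instruments are fixed at zero: prices that cannot reallocate land
    would only inflate the revenue constraint.
    """
    if not panel.complete:
        raise InputError("integrated scenario requires a complete panel")
    m = _build_model(panel, yparams, n_min_frac, n_max_factor)
    n = m.n_c
    n_x = 2 * m.n_ir  # x_irk, k in {1, 2}

    # per-cell marginal-effect rows a_ck = d s_rj / d x_rk at district i
    me_tab = me.table[me.table["use"] > 0].set_index(
        ["district_id", "season", "use", "wrt_crop"]
    )["effect"]
    a = np.zeros((n, 2))
    for c in range(n):
        i = int(m.cells.loc[c, "district_id"])
        r = int(m.cells.loc[c, "season"])
        j = int(m.cells.loc[c, "crop"])
        for k in CROPS:
            a[c, k - 1] = me_tab.loc[(i, r, j, k)]
    # x index of (cell's (i,r), k) in the x block, and the cell's own x
    x_idx = np.empty((n, 2), dtype=int)
    for c in range(n):
        x_idx[c, 0] = 2 * m.ir_of_c[c]
        x_idx[c, 1] = 2 * m.ir_of_c[c] + 1
    own_x = np.array(
        [x_idx[c, int(m.cells.loc[c, "crop"]) - 1] for c in range(n)]
    )
    # price scale for the x variables: baseline price of the instrument crop
    p_x = np.empty(n_x)
    for c in range(n):
        k = int(m.cells.loc[c, "crop"])
        p_x[x_idx[c, k - 1]] = m.price[c]

    cb = cost.table.set_index(["district_id", "season", "crop"])["c_b"]
    c_b = np.array(
        [
            cb.loc[(int(row["district_id"]), int(row["season"]), int(row["crop"]))]
            for _, row in m.cells.iterrows()
        ]
    )

    all_zero = not np.any(a != 0.0)
    if all_zero:
        # price instruments that cannot move any area are dropped from the
        # problem (they would only act on the revenue constraint)
        logger.info(
            "all price marginal effects are zero: fixing the instruments at 0"
        )
    wmax = 0.0 if all_zero else x_frac
    nv = n if all_zero else n + n_x

    def split(zv):
        if all_zero:
            return zv[:n], np.zeros(n_x)
        return zv[:n], zv[n:]

    def x_of(w):
        return w * p_x

    def L_of(w):
        x = x_of(w)
        s = m.s_b + a[:, 0] * x[x_idx[:, 0]] + a[:, 1] * x[x_idx[:, 1]]
        return m.Lbar_c * s, s

    # dL_c/dw_q = Lbar_c * a_ck * p_x[q] for q = x_idx[c, k]
    dL_dw = np.zeros((n, n_x))
    for c in range(n):
        for k in (0, 1):
            dL_dw[c, x_idx[c, k]] += m.Lbar_c[c] * a[c, k] * p_x[x_idx[c, k]]

    f_scale = max(baseline_export(panel), 1e-12)

    def objective(zv):
        u, w = split(zv)
        L, _ = L_of(w)
        return float(np.sum(m.theta * m.Nb * u * L)) / f_scale

    def objective_grad(zv):
        u, w = split(zv)
        L, _ = L_of(w)
        g = np.empty(nv)
        g[:n] = m.theta * m.Nb * L
        if not all_zero:
            g[n:] = (m.theta * m.Nb * u) @ dL_dw
        return g / f_scale

    v_t = float(m.v_b if revenue_target is None else revenue_target)
    Y1_t = float(m.Y1_b if rice_target is None else rice_target)
    have_rice = bool(m.is_rice.any()) and Y1_t > 0

    def pieces(zv):
        u, w = split(zv)
        L, s = L_of(w)
        y = m.delta * (m.Nb * u) ** m.rho
        dc = m.pN * m.Nb * u / y - c_b
        x_cell = x_of(w)[own_x]
        return u, w, L, s, y, dc, x_cell

    def rev_fun(zv):
        u, w, L, s, y, dc, x_cell = pieces(zv)
        return np.array(
            [float(np.sum(L * y * (m.price + x_cell + dc))) / v_t - 1.0]
        )

    def rev_jac(zv):
        u, w, L, s, y, dc, x_cell = pieces(zv)
        J = np.zeros((1, nv))
        ptot = m.price + x_cell + dc
        J[0, :n] = L * (m.rho * y / u * ptot + m.pN * m.Nb * (1.0 - m.rho))
        if not all_zero:
            J[0, n:] = (y * ptot) @ dL_dw
            for c in range(n):
                J[0, n + own_x[c]] += L[c] * y[c] * p_x[own_x[c]]
        return J / v_t

    def rice_fun(zv):
        u, w, L, s, y, dc, x_cell = pieces(zv)
        return np.array([float(np.sum((L * y)[m.is_rice])) / Y1_t - 1.0])

    def rice_jac(zv):
        u, w, L, s, y, dc, x_cell = pieces(zv)
        J = np.zeros((1, nv))
        J[0, :n] = np.where(m.is_rice, m.rho * L * y / u, 0.0)
        if not all_zero:
            J[0, n:] = np.where(m.is_rice, y, 0.0) @ dL_dw
        return J / Y1_t

    # linear constraints in w: implied shares, seasonal and annual land
    dS_dw = dL_dw / m.Lbar_c[:, None]  # shares
    A_ir_s = np.zeros((m.n_ir, n_x))
    b_ir = np.zeros(m.n_ir)
    A_i_s = np.zeros((len(m.district_ids), n_x))
    b_i = np.zeros(len(m.district_ids))
    np.add.at(b_ir, m.ir_of_c, m.s_b)
    np.add.at(b_i, m.d_of_c, m.s_b)
    for c in range(n):
        A_ir_s[m.ir_of_c[c]] += dS_dw[c]
        A_i_s[m.d_of_c[c]] += dS_dw[c]

    def share_lo_fun(zv):   # s_c(x) >= 0
        _, w = split(zv)
        _, s = L_of(w)
        return s

    def share_hi_fun(zv):   # s_c(x) <= 1
        _, w = split(zv)
        _, s = L_of(w)
        return 1.0 - s

    constraints = [dict(type="ineq", fun=rev_fun, jac=rev_jac)]
    if have_rice:
        constraints.append(dict(type="ineq", fun=rice_fun, jac=rice_jac))
    if not all_zero:
        # constraints that move only through the instruments; at w = 0 they
        # reduce to baseline feasibility and are dropped in that case
        constraints += [
            dict(type="ineq", fun=share_lo_fun,
                 jac=lambda zv: np.hstack([np.zeros((n, n)), dS_dw])),
            dict(type="ineq", fun=share_hi_fun,
                 jac=lambda zv: np.hstack([np.zeros((n, n)), -dS_dw])),
            dict(type="ineq",
                 fun=lambda zv: m.CIp_ir - (b_ir + A_ir_s @ zv[n:]),
                 jac=lambda zv: np.hstack([np.zeros((m.n_ir, n)), -A_ir_s])),
            dict(type="ineq",
                 fun=lambda zv: m.CI_i - (b_i + A_i_s @ zv[n:]),
                 jac=lambda zv: np.hstack(
                     [np.zeros((len(m.district_ids), n)), -A_i_s])),
        ]

    bounds = list(zip(np.full(n, n_min_frac), m.u_max))
    if not all_zero:
        bounds += [(-wmax, wmax)] * n_x

    def max_violation(zv):
        worst = 0.0
        for con in constraints:
            worst = max(worst, float(-np.min(con["fun"](zv))))
        u, w = split(zv)
        worst = max(worst, float(np.max(n_min_frac - u)),
                    float(np.max(u - m.u_max)))
        if not all_zero:
            worst = max(worst, float(np.max(np.abs(w) - wmax)))
        return worst

    z_base = (
        np.ones(n) if all_zero else np.concatenate([np.ones(n), np.zeros(n_x)])
    )
    rng = np.random.default_rng([seed, 7702])
    starts = [z_base]
    for _ in range(max(0, n_starts - 1)):
        jit = z_base.copy()
        jit[:n] = np.clip(1.0 + 0.1 * rng.standard_normal(n), n_min_frac, m.u_max)
        if not all_zero:
            jit[n:] = rng.uniform(-0.5 * wmax, 0.5 * wmax, size=n_x)
        starts.append(jit)

    candidates = [(objective(z_base), z_base, "baseline incumbent", -1)]
    log = []
    for k, z0 in enumerate(starts):
        res = minimize(
            objective, z0, jac=objective_grad, bounds=bounds,
            constraints=constraints, method="SLSQP",
            options=dict(maxiter=maxiter, ftol=1e-12),
        )
        viol = max_violation(res.x)
        feasible = viol <= FEAS_TOL
        log.append(dict(start=k, objective=float(res.fun), status=res.message,
                        feasible=feasible, violation=viol))
        if feasible:
            candidates.append((float(res.fun), res.x, res.message, k))

    candidates.sort(key=lambda t: t[0])
    fbest, zbest, msg, kbest = candidates[0]
    u, w = split(zbest)
    L, s = L_of(w)
    x = x_of(w)
    decisions = m.cells[["district_id", "season", "crop"]].copy()
    decisions["N"] = m.Nb * u
    decisions["L"] = L
    decisions["x"] = x[own_x]
    sol = Solution(
        scenario="integrated",
        decisions=decisions,
        objective=fbest * f_scale,
        status=msg,
        success=True,
        n_starts=len(starts),
        start_used=kbest,
        seed=seed,
        iterations=log,
    )
    report = audit_solution(
        panel, sol, yparams, me=me, cost=cost,
        revenue_target=revenue_target, rice_target=rice_target,
    )
    sol.constraints = report.constraints
    return sol


# ---------------------------------------------------------------------------
# independent audit
# ---------------------------------------------------------------------------

@dataclass
class AuditReport:
    """Independent feasibility check of a solution: every constraint
    re-evaluated from the raw decision values with plain per-row arithmetic,
    plus an independent recomputation of the objective."""

    constraints: pd.DataFrame
    objective: float
    objective_solver: float
    objective_rel_err: float
    feasible: bool
    binding: list[str] = field(default_factory=list)
    tol: float = FEAS_TOL

    def to_dict(self) -> dict:
        return dict(
            feasible=self.feasible,
            objective=self.objective,
            objective_solver=self.objective_solver,
            objective_rel_err=self.objective_rel_err,
            binding=self.binding,
            tol=self.tol,
            constraints=self.constraints.to_dict(orient="records"),
        )


def audit_solution(
    panel: DistrictPanel,
    sol: Solution,
    yparams,
    me: MarginalEffects | None = None,
    cost: CostBaseline | None = None,
    revenue_target=None,
    rice_target: float | None = None,
    tol: float = FEAS_TOL,
    binding_tol: float = 1e-6,
) -> AuditReport:
    """Re-verify a solution with an independent code path.

    Walks the decision rows one by one with scalar arithmetic (no shared
    vectorised machinery with the solvers), re-evaluates every scenario
    constraint, computes relative slacks and binding flags, and recomputes
    the objective.  The audit, not the solver, is the source of truth.
    """
    delta = _delta_table(panel, yparams).set_index(
        ["district_id", "season", "crop"]
    )
    smap = panel.seasons.set_index(["district_id", "season"])
    dmap = panel.districts.set_index("district_id")
    cellmap = panel.cells.set_index(["district_id", "season", "crop"])
    integrated = sol.scenario == "integrated"
    if integrated and (me is None or cost is None):
        raise InputError("auditing an integrated solution needs me and cost")
    me_tab = (
        me.table.set_index(["district_id", "season", "use", "wrt_crop"])["effect"]
        if integrated
        else None
    )
    cb_tab = (
        cost.table.set_index(["district_id", "season", "crop"])["c_b"]
        if integrated
        else None
    )

    objective = 0.0
    revenue_by_d: dict[int, float] = {}
    land_ir: dict[tuple[int, int], float] = {}
    land_i: dict[int, float] = {}
    rice_total = 0.0
    revenue_total = 0.0

    x_lookup = None
    if integrated:
        x_lookup = {
            (int(r["district_id"]), int(r["season"]), int(r["crop"])): float(r["x"])
            for _, r in sol.decisions.iterrows()
        }

    rows_aux = []
    for _, row in sol.decisions.iterrows():
        i, r, j = int(row["district_id"]), int(row["season"]), int(row["crop"])
        N = float(row["N"])
        key = (i, r, j)
        drow = delta.loc[key]
        y = float(drow["delta"]) * math.pow(N, float(drow["rho"]))
        theta = float(smap.loc[(i, r), "theta"])
        Lbar = float(dmap.loc[i, "L_bar"])
        if integrated:
            s = float(cellmap.loc[key, "share"])
            for k in (1, 2):
                s += float(me_tab.loc[(i, r, j, k)]) * x_lookup[(i, r, k)]
            L = Lbar * s
            rows_aux.append((i, r, j, s))
            dc = (
                float(smap.loc[(i, r), "pN"]) * N / y - float(cb_tab.loc[key])
                if y > 0
                else float("inf")
            )
            price_eff = float(cellmap.loc[key, "price"]) + x_lookup[(i, r, j)] + dc
            rev = L * y * price_eff
        else:
            L = float(row["L"])
            rev = L * y * float(cellmap.loc[key, "price"])
        objective += theta * N * L
        revenue_by_d[i] = revenue_by_d.get(i, 0.0) + rev
        revenue_total += rev
        land_ir[(i, r)] = land_ir.get((i, r), 0.0) + L
        land_i[i] = land_i.get(i, 0.0) + L
        if j == RICE:
            rice_total += L * y

    records = []

    def add(name, value, bound, sense):
        denom = max(1.0, abs(bound))
        slack = (value - bound) / denom if sense == "ge" else (bound - value) / denom
        records.append(
            dict(name=name, value=value, bound=bound, sense=sense,
                 slack_rel=slack, binding=abs(slack) < binding_tol)
        )

    if sol.scenario == "seasonal":
        d_sorted = sorted(revenue_by_d)
        if revenue_target is None:
            targets = {i: float(dmap.loc[i, "v_b"]) for i in d_sorted}
        else:
            arr = np.broadcast_to(
                np.asarray(revenue_target, dtype=float), (len(d_sorted),)
            )
            targets = dict(zip(d_sorted, arr))
        for i in d_sorted:
            if targets[i] > 0:
                add(f"revenue[{i}]", revenue_by_d[i], targets[i], "ge")
    else:
        target = panel.v_b if revenue_target is None else float(revenue_target)
        if target > 0:
            add("revenue", revenue_total, target, "ge")

    Y1_t = panel.Y1_b if rice_target is None else float(rice_target)
    if Y1_t > 0:
        add("rice", rice_total, Y1_t, "ge")

    for (i, r), v in sorted(land_ir.items()):
        cap = float(smap.loc[(i, r), "CIp"]) * float(dmap.loc[i, "L_bar"])
        add(f"land_seasonal[{i},{r}]", v, cap, "le")
    for i, v in sorted(land_i.items()):
        cap = float(dmap.loc[i, "CI"]) * float(dmap.loc[i, "L_bar"])
        add(f"land_annual[{i}]", v, cap, "le")
    if integrated:
        for i, r, j, s in rows_aux:
            add(f"share_lo[{i},{r},{j}]", s, 0.0, "ge")
            add(f"share_hi[{i},{r},{j}]", s, 1.0, "le")

    constraints = pd.DataFrame(records)
    feasible = bool((constraints["slack_rel"] >= -tol).all())
    rel_err = abs(objective - sol.objective) / max(1.0, abs(objective))
    return AuditReport(
        constraints=constraints,
        objective=objective,
        objective_solver=sol.objective,
        objective_rel_err=rel_err,
        feasible=feasible,
        binding=list(constraints.loc[constraints["binding"], "name"]),
        tol=tol,
    )


# ---------------------------------------------------------------------------
# exhaustive grid oracle (verification on tiny instances)
# ---------------------------------------------------------------------------

def grid_oracle(
    panel: DistrictPanel,
    scenario: str,
    yparams,
    n_points: int = 7,
    refine_rounds: int = 5,
    revenue_target=None,
    rice_target: float | None = None,
    n_min_frac: float = N_MIN_FRAC,
    n_max_factor: float = N_MAX_FACTOR,
    max_grid_points: int = 200_000,
) -> Solution:
    """Verification oracle for tiny (N, L) instances.

    Exhaustively enumerates a grid over the nitrogen rates N; at every grid
    point the areas L enter the objective and every constraint linearly, so
    the inner problem is solved exactly as a linear program.  Optional
    refinement rounds re-grid the nitrogen axes around the incumbent (the
    best value found so far is kept, so refining never worsens the
    objective).  The nitrogen grid always contains the baseline rates and
    the baseline areas are always feasible for the inner program, so a
    feasible point always exists.  Intended for instances of at most
    2 districts x 2 seasons.
    """
    from scipy.optimize import linprog

    if scenario not in ("seasonal", "seasonal-spatial"):
        raise InputError("grid oracle supports the (N, L) scenarios")
    m = _build_model(panel, yparams, n_min_frac, n_max_factor)
    n = m.n_c
    if n_points**n > max_grid_points:
        raise InputError(
            f"nitrogen grid of {n_points}^{n} points exceeds the budget"
        )

    u_lo = np.full(n, n_min_frac)
    u_hi = m.u_max
    ell_hi = m.CIp_ir[m.ir_of_c]

    if scenario == "seasonal":
        v_t = m.vb_i.copy() if revenue_target is None else np.broadcast_to(
            np.asarray(revenue_target, dtype=float), m.vb_i.shape
        )
    else:
        v_t = float(m.v_b if revenue_target is None else revenue_target)
    Y1_t = float(m.Y1_b if rice_target is None else rice_target)
    have_rice = bool(m.is_rice.any()) and Y1_t > 0
    n_d = len(m.district_ids)

    def inner_lp(u):
        """Exact minimum over areas for fixed nitrogen rates; None if the
        inner program is infeasible at these rates."""
        y = m.delta * (m.Nb * u) ** m.rho
        c = m.theta * m.Nb * u * m.Lbar_c
        A_ub, b_ub = [], []
        rev_row = m.Lbar_c * m.price * y
        if scenario == "seasonal":
            for di in range(n_d):
                row = np.where(m.d_of_c == di, rev_row, 0.0)
                A_ub.append(-row)
                b_ub.append(-v_t[di])
        else:
            A_ub.append(-rev_row)
            b_ub.append(-v_t)
        if have_rice:
            A_ub.append(-np.where(m.is_rice, m.Lbar_c * y, 0.0))
            b_ub.append(-Y1_t)
        for g in range(m.n_ir):
            A_ub.append((m.ir_of_c == g).astype(float))
            b_ub.append(m.CIp_ir[g])
        for di in range(n_d):
            A_ub.append((m.d_of_c == di).astype(float))
            b_ub.append(m.CI_i[di])
        res = linprog(
            c,
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            bounds=list(zip(np.zeros(n), ell_hi)),
            method="highs",
        )
        if not res.success:
            return None, None
        return float(c @ res.x), res.x

    def axes_around(center, halfwidth):
        axes = []
        for d in range(n):
            a = np.linspace(
                max(u_lo[d], center[d] - halfwidth[d]),
                min(u_hi[d], center[d] + halfwidth[d]),
                n_points,
            )
            axes.append(np.unique(np.append(a, np.clip(center[d], u_lo[d], u_hi[d]))))
        return axes

    seen: dict[bytes, tuple] = {}

    def sweep(axes):
        """Evaluate the full product grid; returns the evaluated points
        sorted by objective (feasible only).  Points are memoized, so
        overlapping refinement windows cost nothing extra."""
        grids = np.meshgrid(*axes, indexing="ij")
        U = np.column_stack([g.ravel() for g in grids])
        hits = []
        for u in U:
            key = u.tobytes()
            if key in seen:
                cached = seen[key]
            else:
                val, ell = inner_lp(u)
                cached = (val, u.copy(), ell.copy() if ell is not None else None)
                seen[key] = cached
            if cached[0] is not None:
                hits.append(cached)
        hits.sort(key=lambda t: t[0])
        return hits

    # round 0: coarse grid over the full box, anchored at the baseline rates
    base = np.ones(n)
    halfwidth0 = (u_hi - u_lo) / 2.0 + np.abs(base - (u_lo + u_hi) / 2.0)
    hits = sweep(axes_around(base, halfwidth0))
    if not hits:  # pragma: no cover - baseline is always feasible
        raise SolverError("no feasible grid point")
    best_val, best_u, best_ell = hits[0]
    steps0 = (2.0 * halfwidth0) / max(n_points - 1, 1)

    # refinement: beam of the best few points, windows of +-2 previous
    # steps (shrinking slowly enough to track a correlated valley)
    beam_width = 4
    centers = [h[1] for h in hits[:beam_width]]
    halfwidth = 2.0 * steps0
    for _ in range(refine_rounds):
        merged = []
        for center in centers:
            merged.extend(sweep(axes_around(center, halfwidth)))
        if merged:
            merged.sort(key=lambda t: t[0])
            if merged[0][0] < best_val:
                best_val, best_u, best_ell = merged[0]
            centers = [m_[1] for m_ in merged[:beam_width]]
        halfwidth = halfwidth * (2.0 / (n_points - 1))

    decisions = m.cells[["district_id", "season", "crop"]].copy()
    decisions["N"] = m.Nb * best_u
    decisions["L"] = m.Lbar_c * best_ell
    return Solution(
        scenario=f"grid-{scenario}",
        decisions=decisions,
        objective=best_val,
        status=f"nitrogen-grid enumeration with exact inner LP, "
               f"{refine_rounds} refinement rounds",
        success=True,
    )
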