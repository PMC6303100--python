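"""Two-point boundary-value solvers for the cleft transport system.

Two independent routes solve the same nonlinear system:

* :func:`solve_relaxation` — damped Newton iteration on a second-order
  midpoint (box) finite-difference discretization of the nondimensionalized
  equations, with the mesh graded toward the open end to resolve the
  boundary layer of width ``y_inh``.  Works in every regime.
* :func:`solve_shooting` — treats the inlet concentration ``c(0)`` as the
  single unknown, integrates the ODEs forward with a high-order adaptive
  integrator and brackets the root of ``c(L) - c4``.  Forward deviations grow
  roughly like ``exp((L/y_inh)^2)``, so this route refuses clefts with
  ``L/y_inh > 3``; within its range it is an independent oracle for the
  relaxation solver.

:func:`solve` dispatches: shooting for short clefts, relaxation otherwise.
Everything is deterministic; no randomness is consumed anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from . import model
from .params import MM_TO_CGS, UM_TO_CM, Parameters, DerivedScales, derived_scales

__all__ = [
    "ConvergenceError",
    "SolverOptions",
    "SolverMeta",
    "CleftProfile",
    "make_mesh",
    "solve_relaxation",
    "solve_shooting",
    "solve",
]

#: largest L/y_inh ratio the forward-shooting route accepts
SHOOTING_MAX_RATIO = 3.0


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the last residual report if any."""

    def __init__(self, message: str, residual_report=None):
        super().__init__(message)
        self.residual_report = residual_report


@dataclass
class SolverOptions:
    """Numerical options shared by both solvers.

    ``tol`` is the dimensionless residual tolerance a profile must meet to be
    flagged converged; ``refinement`` is the grading exponent of the mesh near
    the open end (1 = uniform, larger = stronger clustering); ``continuation``
    optionally lists intermediate parameter sets to walk through when the
    direct Newton solve fails.
    """

    method: str = "auto"            # auto | relaxation | shooting
    n_mesh: int = 512               # number of mesh intervals
    tol: float = 1e-6
    max_iter: int = 50
    refinement: float = 2.0
    continuation: list | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_mesh < 64:
            raise ValueError("n_mesh must be at least 64")
        if self.method not in ("auto", "relaxation", "shooting"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class SolverMeta:
    method: str
    iterations: int
    n_mesh: int
    converged: bool
    message: str = ""


@dataclass(eq=False)
class CleftProfile:
    """Discretized solution c(y), v(y) on [0, L] with diagnostics (CGS)."""

    y: np.ndarray
    c: np.ndarray
    v: np.ndarray
    residual_report: model.ResidualReport
    solver_meta: SolverMeta
    scales: DerivedScales

    @property
    def c0(self) -> float:
        return float(self.c[0])

    @property
    def v0(self) -> float:
        return float(self.v[0])

    @property
    def vL(self) -> float:
        return float(self.v[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y_um": self.y / UM_TO_CM,
                "c_mM": self.c / MM_TO_CGS,
                "v_cm_per_s": self.v,
            }
        )

    def summary(self) -> str:
        r = self.residual_report
        m = self.solver_meta
        lines = [
            "CleftProfile",
            f"  method      : {m.method} ({m.iterations} iterations, "
            f"{m.n_mesh} intervals, converged={m.converged})",
            f"  regime      : {self.scales.regime} "
            f"(y_inh = {self.scales.y_inh / UM_TO_CM:.3g} um)",
            f"  c(0)        : {self.c0 / MM_TO_CGS:.4g} mM "
            f"(c_hom = {self.scales.c_hom / MM_TO_CGS:.4g} mM)",
            f"  v(0)        : {self.v0:.4g} cm/s (TJ)",
            f"  v(L)        : {self.vL:.4g} cm/s (open end)",
            f"  residuals   : ion {r.ion_flux_residual:.2e}, "
            f"volume {r.volume_residual:.2e}",
        ]
        return "\n".join(lines)


def make_mesh(L: float, y_inh: float, n: int, refinement: float = 2.0) -> np.ndarray:
    """Mesh on [0, L] with n intervals, graded toward the open end.

    Points within ~2*y_inh of y = L (capped at 0.6 L so some uniform inlet
    section always remains) are clustered with grading exponent ``refinement``
    to resolve the outlet boundary layer; the rest of the cleft is meshed
    uniformly.  Without a finite y_inh (no pumping) the mesh is uniform.
    """
    if not math.isfinite(y_inh) or refinement <= 1.0:
        return np.linspace(0.0, L, n + 1)
    w = min(2.0 * y_inh, 0.6 * L)
    n_in = n // 2
    n_out = n - n_in
    outer = np.linspace(0.0, L - w, n_out + 1)
    s = np.linspace(0.0, 1.0, n_in + 1)[1:]
    inner = L - w * (1.0 - s) ** refinement
    return np.concatenate([outer, inner])


def _initial_guess(params: Parameters, y: np.ndarray, scales: DerivedScales):
    """Regime-appropriate analytical starting profile for Newton."""
    from . import approximations  # local import: approximations.fit_C0 uses solvers

    regime = scales.regime
    if params.j == 0 or params.f_aq == 0:
        c = np.full_like(y, params.c4)
        v = np.full_like(y, model.tj_velocity(params.c4, params))
        return c, v
    if regime == "long":
        ap = approximations.long_cleft_profile(params, y)
    elif regime == "short":
        ap = approximations.short_cleft_profile(params, y, variant=2)
    else:
        ap_long = approximations.long_cleft_profile(params, y)
        ap_short = approximations.short_cleft_profile(params, y, variant=2)
        t = min(max(params.L / scales.y_inh, 0.0), 1.0)
        return (
            t * ap_long.c + (1 - t) * ap_short.c,
            t * ap_long.v + (1 - t) * ap_short.v,
        )
    return ap.c.copy(), ap.v.copy()


def _clip_positive(c: np.ndarray, floor: float) -> np.ndarray:
    return np.maximum(c, floor)


def _newton_system(C, V, Y, g: model.NondimensionalGroups):
    """Residual vector and sparse Jacobian of the box-scheme equations."""
    n = Y.size
    h = np.diff(Y)
    Cm = 0.5 * (C[1:] + C[:-1])
    Vm = 0.5 * (V[1:] + V[:-1])
    Ym = 0.5 * (Y[1:] + Y[:-1])

    RF = (C[1:] - C[:-1]) - h * (Vm * Cm - g.alpha * Ym)
    RG = (V[1:] - V[:-1]) - h * g.beta * (Cm - 1.0)
    RB0 = V[0] - g.gamma * (C[0] - g.c1r)
    RB1 = C[-1] - g.c4r
    R = np.concatenate([[RB0], RF, RG, [RB1]])

    # unknown ordering: x = [C_0..C_{n-1}, V_0..V_{n-1}]
    rows, cols, vals = [], [], []

    def add(r, c_, v_):
        rows.append(r)
        cols.append(c_)
        vals.append(v_)

    add(0, 0, -g.gamma)        # dRB0/dC0
    add(0, n, 1.0)             # dRB0/dV0
    i = np.arange(n - 1)
    # RF rows 1..n-1
    rF = 1 + i
    dF_dCi = -1.0 - 0.5 * h * Vm
    dF_dCip = 1.0 - 0.5 * h * Vm
    dF_dVi = -0.5 * h * Cm
    for r_idx, c_idx, v_arr in (
        (rF, i, dF_dCi),
        (rF, i + 1, dF_dCip),
        (rF, n + i, dF_dVi),
        (rF, n + i + 1, dF_dVi),
    ):
        rows.extend(r_idx.tolist())
        cols.extend(np.asarray(c_idx).tolist())
        vals.extend(np.asarray(v_arr).tolist())
    # RG rows n..2n-2
    rG = n + i
    dG_dC = -0.5 * h * g.beta
    for r_idx, c_idx, v_arr in (
        (rG, i, dG_dC),
        (rG, i + 1, dG_dC),
        (rG, n + i, np.full(n - 1, -1.0)),
        (rG, n + i + 1, np.full(n - 1, 1.0)),
    ):
        rows.extend(r_idx.tolist())
        cols.extend(np.asarray(c_idx).tolist())
        vals.extend(np.asarray(v_arr).tolist())
    add(2 * n - 1, n - 1, 1.0)  # dRB1/dC_{n-1}

    J = coo_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n)).tocsc()
    return R, J


def _scaled_residual_norm(R, Y, g) -> float:
    n = Y.size
    h = np.diff(Y)
    scale = np.empty_like(R)
    scale[0] = 1.0 + abs(g.gamma) * (1.0 + g.c1r)
    scale[1:n] = h * (1.0 + g.alpha)
    scale[n:2 * n - 1] = h * (1.0 + g.beta)
    scale[2 * n - 1] = 1.0 + g.c4r
    return float(np.max(np.abs(R) / scale))


def _relax_once(params, y, C, V, options) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Damped Newton on the nondimensional box scheme; returns (C, V, iters, ok)."""
    g = model.nondimensional_groups(params)
    Y = y / params.L
    newton_tol = min(1e-10, options.tol * 1e-3)
    floor = 1e-6  # nondimensional concentration floor during iteration
    it = 0
    for it in range(1, options.max_iter + 1):
        R, J = _newton_system(C, V, Y, g)
        norm0 = _scaled_residual_norm(R, Y, g)
        if norm0 < newton_tol:
            return C, V, it - 1, True
        try:
            dx = spsolve(J, -R)
        except Exception:
            return C, V, it, False
        if not np.all(np.isfinite(dx)):
            return C, V, it, False
        dC, dV = dx[: Y.size], dx[Y.size:]
        t = 1.0
        ok_step = False
        for _ in range(20):
            Ct = C + t * dC
            Vt = V + t * dV
            if np.any(Ct <= floor):
                t *= 0.5
                continue
            Rt, _ = _newton_system(Ct, Vt, Y, g)
            if _scaled_residual_norm(Rt, Y, g) < norm0:
                C, V = Ct, Vt
                ok_step = True
                break
            t *= 0.5
        if not ok_step:
            # stalled: accept a tiny positive-preserving step and keep trying
            Ct = _clip_positive(C + t * dC, floor)
            C, V = Ct, V + t * dV
    R, _ = _newton_system(C, V, Y, g)
    return C, V, it, _scaled_residual_norm(R, Y, g) < newton_tol


def _profile_from_nondim(params, y, C, V, meta: SolverMeta) -> CleftProfile:
    c = C * params.c3
    v = V * params.D / params.L
    report = model.residuals(y, c, v, params)
    return CleftProfile(
        y=y, c=c, v=v, residual_report=report, solver_meta=meta,
        scales=derived_scales(params),
    )


def solve_relaxation(
    params: Parameters,
    options: SolverOptions | None = None,
    initial: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> CleftProfile:
    """Solve the full nonlinear BVP by damped Newton relaxation.

    ``initial`` may provide a warm-start profile as (y, c, v) arrays in CGS
    (e.g. the previous point of a parameter sweep); otherwise a
    regime-appropriate analytical approximation seeds the iteration.  If the
    direct solve fails, continuation in cleft length from a short cleft is
    attempted before raising :class:`ConvergenceError`.
    """
    options = options or SolverOptions()
    scales = derived_scales(params)
    y = make_mesh(params.L, scales.y_inh, options.n_mesh, options.refinement)

    if initial is not None:
        y0, c0, v0 = initial
        c_init = np.interp(y, y0, c0)
        v_init = np.interp(y, y0, v0)
    else:
        c_init, v_init = _initial_guess(params, y, scales)
    C = _clip_positive(c_init / params.c3, 1e-6)
    V = v_init * params.L / params.D

    C, V, iters, ok = _relax_once(params, y, C, V, options)
    total_iters = iters

    if not ok:
        # continuation: grow the cleft from a comfortably short length
        steps = options.continuation
        if steps is None and math.isfinite(scales.y_inh) and params.L > 0.5 * scales.y_inh:
            L_start = max(0.3 * scales.y_inh, 2.0 * params.b)
            Ls = np.geomspace(L_start, params.L, 8)
            steps = [params.replace(L=float(Lk)) for Lk in Ls]
        if steps:
            prev = None
            for pk in steps:
                sk = derived_scales(pk)
                yk = make_mesh(pk.L, sk.y_inh, options.n_mesh, options.refinement)
                if prev is None:
                    ck, vk = _initial_guess(pk, yk, sk)
                else:
                    yp, cp, vp = prev
                    ck = np.interp(yk, yp / yp[-1] * yk[-1], cp)
                    vk = np.interp(yk, yp / yp[-1] * yk[-1], vp)
                Ck = _clip_positive(ck / pk.c3, 1e-6)
                Vk = vk * pk.L / pk.D
                Ck, Vk, itk, ok = _relax_once(pk, yk, Ck, Vk, options)
                total_iters += itk
                if not ok:
                    break
                prev = (yk, Ck * pk.c3, Vk * pk.D / pk.L)
            if ok and prev is not None:
                y, C, V = prev[0], prev[1] / params.c3, prev[2] * params.L / params.D

    meta = SolverMeta(
        method="relaxation", iterations=total_iters, n_mesh=options.n_mesh,
        converged=False,
    )
    profile = _profile_from_nondim(params, y, C, V, meta)
    r = profile.residual_report
    conc_scale = max(params.c3, params.c4)
    vel_scale = max(abs(profile.vL), scales.v_hom_L, params.D / params.L)
    meta.converged = bool(
        ok
        and r.max_dimensionless() < options.tol
        and r.bc_outlet < options.tol * conc_scale
        and r.bc_inlet_velocity < options.tol * vel_scale
    )
    if not meta.converged:
        raise ConvergenceError(
            f"relaxation failed to converge after {total_iters} iterations "
            f"(ion {r.ion_flux_residual:.2e}, volume {r.volume_residual:.2e})",
            residual_report=r,
        )
    return profile


def solve_shooting(
    params: Parameters, options: SolverOptions | None = None
) -> CleftProfile:
    """Solve the BVP by shooting on the inlet concentration c(0).

    The inlet velocity follows from the TJ condition, the ODEs are integrated
    with DOP853 at tight tolerance, and the outlet mismatch ``c(L) - c4`` is
    driven to zero by bracketed root-finding over
    ``c0 in [min(c1, c3, c4)/10, 10*c_hom]``.  Refuses long clefts
    (L/y_inh > 3), where forward deviations grow explosively — use the
    relaxation solver there.
    """
    options = options or SolverOptions()
    scales = derived_scales(params)
    if math.isfinite(scales.y_inh) and params.L / scales.y_inh > SHOOTING_MAX_RATIO:
        raise ValueError(
            f"shooting refused: L/y_inh = {params.L / scales.y_inh:.2f} > "
            f"{SHOOTING_MAX_RATIO:g}; forward deviations grow ~exp((L/y_inh)^2), "
            "use the relaxation solver instead"
        )
    g = model.nondimensional_groups(params)

    def rhs_nd(Yv, x):
        Cc, Vv = x
        return (Vv * Cc - g.alpha * Yv, g.beta * (Cc - 1.0))

    def hit_zero(Yv, x):
        return x[0] - 1e-9

    hit_zero.terminal = True
    hit_zero.direction = -1

    c_big = 1e3 * max(g.c4r, 10.0 * scales.c_hom / params.c3)

    def hit_big(Yv, x):
        return x[0] - c_big

    hit_big.terminal = True
    hit_big.direction = 1

    nfev = 0

    def outlet_mismatch(C0r: float) -> float:
        """c(L) - c4, with monotone penalties when c hits 0 or blows up."""
        nonlocal nfev
        nfev += 1
        sol = solve_ivp(
            rhs_nd, (0.0, 1.0), (C0r, g.gamma * (C0r - g.c1r)),
            method="DOP853", rtol=1e-12, atol=1e-14, events=(hit_zero, hit_big),
        )
        if sol.t[-1] < 1.0:
            if sol.t_events[0].size:  # hit zero: later escape -> smaller penalty
                return -g.c4r * (1.0 + (1.0 - sol.t[-1]))
            return (c_big - g.c4r) * (1.0 + (1.0 - sol.t[-1]))  # blow-up
        return float(sol.y[0, -1]) - g.c4r

    lo = min(params.c1, params.c3, params.c4) / 10.0 / params.c3
    hi = 10.0 * scales.c_hom / params.c3
    grid = np.geomspace(lo, hi, 16)
    res = np.array([outlet_mismatch(x) for x in grid])
    # the outlet concentration must respond monotonically to the inlet guess,
    # otherwise bracketing is not trustworthy
    if np.any(np.diff(res) < -1e-8 * (1.0 + np.max(np.abs(res)))):
        raise ConvergenceError(
            "outlet mismatch is not monotone in c(0); bracketing invalid"
        )
    sign_change = np.where(np.sign(res[:-1]) * np.sign(res[1:]) <= 0)[0]
    if sign_change.size == 0:
        raise ConvergenceError(
            f"no sign change of c(L) - c4 in the bracket "
            f"[{lo * params.c3 / MM_TO_CGS:.3g}, {hi * params.c3 / MM_TO_CGS:.3g}] mM"
        )
    k = int(sign_change[0])
    C0r = brentq(outlet_mismatch, grid[k], grid[k + 1], xtol=1e-14, rtol=1e-14)

    # forward evaluation is cheap per node; sample 4x as finely as the
    # relaxation mesh so the reported midpoint-operator defect stays below
    # tolerance even at the steepest admissible layers (L/y_inh near 3)
    n_out = 4 * options.n_mesh
    y = make_mesh(params.L, scales.y_inh, n_out, options.refinement)
    sol = solve_ivp(
        rhs_nd, (0.0, 1.0), (C0r, g.gamma * (C0r - g.c1r)),
        method="DOP853", rtol=1e-12, atol=1e-14, dense_output=True,
    )
    vals = sol.sol(y / params.L)
    meta = SolverMeta(
        method="shooting", iterations=nfev, n_mesh=n_out, converged=False,
    )
    profile = _profile_from_nondim(params, y, vals[0], vals[1], meta)
    r = profile.residual_report
    conc_scale = max(params.c3, params.c4)
    meta.converged = bool(
        r.max_dimensionless() < options.tol and r.bc_outlet < options.tol * conc_scale
    )
    if not meta.converged:
        raise ConvergenceError(
            f"shooting profile residuals exceed tolerance "
            f"(ion {r.ion_flux_residual:.2e}, volume {r.volume_residual:.2e})",
            residual_report=r,
        )
    return profile


def solve(
    params: Parameters,
    options: SolverOptions | None = None,
    initial: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> CleftProfile:
    """Solve the BVP with the method best suited to the regime.

    Short clefts go to the fast, independent shooting solver; everything else
    (including any cleft with L/y_inh > 3) goes to Newton relaxation.  An
    explicit ``options.method`` overrides the dispatch.
    """
    options = options or SolverOptions()
    if options.method == "relaxation":
        return solve_relaxation(params, options, initial=initial)
    if options.method == "shooting":
        return solve_shooting(params, options)
    scales = derived_scales(params)
    ratio = params.L / scales.y_inh if math.isfinite(scales.y_inh) else 0.0
    if scales.regime == "short" and ratio <= SHOOTING_MAX_RATIO:
        return solve_shooting(params, options)
    return solve_relaxation(params, options, initial=initial)
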