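"""Weighted static optimization: per-frame muscle redundancy resolution.

At every frame the muscle redundancy problem is resolved by the convex
quadratic program

    minimize    sum_i w_i * a_i**2   (+ rho * sum_d r_d**2 with reserves)
    subject to  sum_i R[d, i] * a_i * f_max_i (+ r_d) = tau_d   for each DOF d
                0 <= a_i <= 1

where ``a`` are muscle activations, ``R`` the signed moment-arm matrix,
``tau`` the joint torques and ``w`` the per-muscle weights (the "neural
strategy").  All weights equal to 1 is standard static optimization.  The
EMG-constrained variant additionally boxes each measured muscle's activation
within +-delta of its normalized EMG envelope.

Muscles are ideal force generators (F_i = a_i * f_max_i); with strictly
positive weights the objective is strictly convex, so the solution is the
unique global optimum.  Because the Hessian is diagonal, the QP is solved
exactly by maximizing its low-dimensional dual with a damped semismooth
Newton iteration (see :func:`_solve_qp_dual`), warm-started across frames;
SciPy's SLSQP serves as a general-purpose fallback, its result verified by
an explicit KKT check.  Per-DOF torque residuals are checked after every
solve; ``converged`` reflects that check, not just an exit status.

Reserve actuators (per-DOF torque slack ``r_d``, quadratically penalized)
are disabled by default and engaged only to rescue an infeasible frame when
``reserve_enabled`` is set; their activation is logged at WARNING level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import InfeasibleFrameError, InfeasibleTrialError, ParameterError
from .model import FrameGeometry, LinkageModel, TrialData

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightVector:
    """One neural strategy: per-muscle weights drawn from the model's levels."""

    w: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        if self.w.ndim != 1 or np.any(self.w <= 0):
            raise ParameterError("weights must be a 1-D positive vector")

    @classmethod
    def ones(cls, m: int) -> "WeightVector":
        return cls(np.ones(m))

    def validate_against(self, model: LinkageModel,
                         require_levels: bool = False) -> None:
        """Check length against the model; optionally also lattice membership.

        The solver itself accepts any positive weights (the optimum is
        invariant to a common positive rescaling); chain-sampled strategies
        are additionally required to sit on the model's weight levels.
        """
        if self.w.shape != (model.m,):
            raise ParameterError(
                f"weight vector length {self.w.shape[0]} != m={model.m}")
        if require_levels:
            levels = np.asarray(model.weight_levels)
            if not np.all(np.isin(self.w, levels)):
                raise ParameterError(
                    f"weights must be drawn from levels {model.weight_levels}")


@dataclass
class SolverOptions:
    """Numerical knobs for the per-frame QP.

    ``residual_tolerance`` is relative: a frame counts as converged when
    every DOF's torque residual satisfies |res| <= tol * max(1, |tau|).
    ``emg_tolerance`` (delta) is the half-width, in activation units, of the
    tracking box around each measured muscle's envelope.  ``reserve_weight``
    penalizes squared reserve torque (per (N m)^2) and is deliberately large
    so reserves stay near zero whenever muscles suffice.
    """

    activation_bounds: tuple[float, float] = (0.0, 1.0)
    residual_tolerance: float = 1e-6
    reserve_enabled: bool = False
    reserve_weight: float = 1000.0
    emg_tolerance: float = 0.05
    qp_ftol: float = 1e-12
    qp_maxiter: int = 300

    def __post_init__(self):
        if self.emg_tolerance < 0:
            raise ParameterError("emg_tolerance must be >= 0")
        if self.residual_tolerance <= 0 or self.qp_ftol <= 0:
            raise ParameterError("tolerances must be > 0")


@dataclass
class FrameSolution:
    """Solution of a single frame's QP."""

    activations: np.ndarray        # (m,)
    reserves: np.ndarray           # (n_dof,)
    cost: float                    # sum w a^2 (+ reserve penalty)
    residuals: np.ndarray          # (n_dof,) N*m
    converged: bool
    used_reserves: bool = False
    dual: np.ndarray | None = None


@dataclass
class ActivationSolution:
    """Frame-wise solution over a trial's stance window.

    Arrays run over the stance frames (inclusive window recorded in
    ``frame_window``).  ``muscle_forces = activations * f_max`` elementwise.
    """

    activations: np.ndarray        # (n_stance, m)
    muscle_forces: np.ndarray      # (n_stance, m) N
    reserve_torques: np.ndarray    # (n_stance, n_dof) N*m
    cost: np.ndarray               # (n_stance,)
    residuals: np.ndarray          # (n_stance, n_dof) N*m
    converged: np.ndarray          # (n_stance,) bool
    frame_window: tuple[int, int]
    weights: WeightVector

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())


def _solve_qp_dual(G, tau, w, lb, ub, abs_tol, rho=None, lam0=None,
                   max_iter=100):
    """Exact dual solve of min a'diag(w)a s.t. G a (+ r) = tau, lb<=a<=ub.

    With a diagonal Hessian the box-constrained Lagrangian minimizer is
    separable and closed-form: a_i(lam) = clip(g_i'lam / (2 w_i), lb_i, ub_i).
    The dual is maximized by solving the monotone piecewise-linear system
    G a(lam) (+ lam/(2 rho)) = tau for the n_dof multipliers lam with a
    damped semismooth Newton iteration.  On convergence the KKT conditions
    hold, so a(lam) is the unique global optimum.  Returns
    (a, r, lam, converged); ``r`` is the reserve torque (zero without rho).
    """
    n_dof, m = G.shape
    inv2w = 1.0 / (2.0 * w)
    lam = np.zeros(n_dof) if lam0 is None else np.asarray(lam0, dtype=float)
    rho_inv = 0.0 if rho is None else 1.0 / (2.0 * rho)
    abs_tol = np.asarray(abs_tol) * np.ones(n_dof)
    eye = np.eye(n_dof)

    def evaluate(lam):
        """Clipped primal point, dual value q(lam) and residual F = -grad q."""
        z = (G.T @ lam) * inv2w
        a = np.clip(z, lb, ub)
        q = (np.dot(w, a * a) + np.dot(lam, tau - G @ a)
             - 0.5 * rho_inv * np.dot(lam, lam))
        return a, z, q, G @ a + rho_inv * lam - tau

    a, z, q, F = evaluate(lam)
    # The dual is concave, piecewise quadratic and C^1; the Levenberg-damped
    # Newton direction is an ascent direction for it, so Armijo backtracking
    # on q converges globally whenever the primal is (strictly) feasible.
    mu = 1e-10
    for _ in range(max_iter):
        if np.all(np.abs(F) <= abs_tol):
            return a, rho_inv * lam, lam, True
        free = (z > lb) & (z < ub)
        Gf = G[:, free]
        J = (Gf * inv2w[free]) @ Gf.T + rho_inv * eye
        d = np.linalg.solve(J + mu * eye, -F)       # grad q = -F
        slope = -float(np.dot(F, d))                # d'grad q > 0
        t = 1.0
        for _ in range(50):
            a_new, z_new, q_new, F_new = evaluate(lam + t * d)
            if q_new >= q + 1e-4 * t * slope:
                break
            t *= 0.5
        else:
            return a, rho_inv * lam, lam, False
        lam = lam + t * d
        a, z, q, F = a_new, z_new, q_new, F_new
        mu = 1e-10 if t == 1.0 else min(mu * 10.0, 1.0)
    return a, rho_inv * lam, lam, bool(np.all(np.abs(F) <= abs_tol))


def _solve_qp(G, tau, w, lb, ub, options, x0=None, with_reserves=False):
    """Solve min a'diag(w)a (+ rho r'r) s.t. G a (+ r) = tau, lb<=a<=ub.

    Returns (a, r, success).  ``G`` is the (n_dof x m) gain matrix
    (moment arms times f_max).
    """
    n_dof, m = G.shape
    rho = options.reserve_weight

    if with_reserves:
        w_full = np.concatenate([w, np.full(n_dof, rho)])
        G_full = np.hstack([G, np.eye(n_dof)])
        lo = np.concatenate([lb, np.full(n_dof, -np.inf)])
        hi = np.concatenate([ub, np.full(n_dof, np.inf)])
    else:
        w_full, G_full, lo, hi = w, G, lb, ub
    n = G_full.shape[1]

    if x0 is None:
        x0 = np.where(np.isfinite(lo) & np.isfinite(hi), (lo + hi) / 2.0, 0.0)
    else:
        if with_reserves and x0.shape[0] == m:
            x0 = np.concatenate([x0, np.zeros(n_dof)])
        x0 = np.clip(x0, lo, hi)

    def fun(x):
        return float(np.dot(w_full, x * x))

    def jac(x):
        return 2.0 * w_full * x

    res = optimize.minimize(
        fun, x0, jac=jac, method="SLSQP",
        bounds=optimize.Bounds(lo, hi),
        constraints=[{"type": "eq",
                      "fun": lambda x: G_full @ x - tau,
                      "jac": lambda x: G_full}],
        options={"ftol": options.qp_ftol, "maxiter": options.qp_maxiter})
    x = np.clip(res.x, lo, hi)
    a, r = (x[:m], x[m:]) if with_reserves else (x, np.zeros(n_dof))
    return a, r, bool(res.success)


def _kkt_optimal(G, tau, w, a, r, lb, ub, rho=None, rtol=1e-5):
    """Post-hoc KKT verification for a candidate box-QP solution.

    Used to accept fallback solutions whose solver exit status is
    inconclusive: equality feasibility is checked by the caller; here we
    verify stationarity and dual feasibility.  With reserves the torque
    multipliers are known exactly (lam = 2 rho r); otherwise they are
    estimated from the free variables' stationarity by least squares.
    """
    eps = 1e-9
    free = (a > lb + eps) & (a < ub - eps)
    target = 2.0 * w * a
    if rho is not None:
        lam = 2.0 * rho * r
    elif free.any():
        lam, *_ = np.linalg.lstsq(G[:, free].T, target[free], rcond=None)
    else:
        lam, *_ = np.linalg.lstsq(G.T, target, rcond=None)
    g = G.T @ lam
    scale = np.maximum(1.0, np.abs(target) + np.abs(g))
    stationary = np.abs(target - g) <= rtol * scale
    at_lb = np.abs(a - lb) <= eps
    at_ub = np.abs(ub - a) <= eps
    ok_lb = g <= 2.0 * w * lb + rtol * scale
    ok_ub = g >= 2.0 * w * ub - rtol * scale
    ok = np.where(at_lb, ok_lb | stationary,
                  np.where(at_ub, ok_ub | stationary, stationary))
    return bool(np.all(ok))


def _emg_bounds(model, options, envelope_row):
    """Activation bounds with EMG tracking boxes applied to measured muscles."""
    lb = np.full(model.m, options.activation_bounds[0])
    ub = np.full(model.m, options.activation_bounds[1])
    delta = options.emg_tolerance
    for c, i in enumerate(model.emg_measured_indices):
        e = envelope_row[c]
        lb[i] = max(lb[i], e - delta)
        ub[i] = min(ub[i], e + delta)
    return lb, ub


def solve_frame(geometry: FrameGeometry, torques, model: LinkageModel,
                weights: WeightVector, options: SolverOptions | None = None,
                emg_row=None, x0=None, lam0=None,
                frame_index: int | None = None,
                raise_infeasible: bool = True) -> FrameSolution:
    """Solve the weighted static-optimization QP at one frame.

    ``emg_row`` (normalized envelopes for the measured muscles, in model
    order) switches on EMG tracking constraints.  ``x0`` warm-starts the
    solver, typically with the previous frame's activations.  An infeasible
    frame raises :class:`InfeasibleFrameError` naming the worst DOF unless
    ``raise_infeasible`` is false (batch drivers flag it instead).
    """
    options = options or SolverOptions()
    weights.validate_against(model)
    tau = np.asarray(torques, dtype=float)
    G = geometry.moment_arms * model.f_max[np.newaxis, :]

    if emg_row is None:
        lb = np.full(model.m, options.activation_bounds[0])
        ub = np.full(model.m, options.activation_bounds[1])
    else:
        lb, ub = _emg_bounds(model, options, np.asarray(emg_row, dtype=float))

    scale = np.maximum(1.0, np.abs(tau))
    tol = options.residual_tolerance * scale

    def attempt(with_reserves):
        rho = options.reserve_weight if with_reserves else None
        a, r, lam, ok = _solve_qp_dual(G, tau, weights.w, lb, ub,
                                       0.01 * tol, rho=rho, lam0=lam0)
        if not ok and lam0 is not None:  # warm start can mislead: retry cold
            a, r, lam, ok = _solve_qp_dual(G, tau, weights.w, lb, ub,
                                           0.01 * tol, rho=rho, lam0=None)
        if not ok:  # fall back to the general-purpose SLSQP path; its exit
            # flag is inconclusive near kinks, so verify KKT explicitly
            a, r, slsqp_ok = _solve_qp(G, tau, weights.w, lb, ub, options,
                                       x0=x0, with_reserves=with_reserves)
            ok = slsqp_ok or _kkt_optimal(G, tau, weights.w, a, r, lb, ub,
                                          rho=rho)
            lam = None
        resid = G @ a + r - tau
        conv = ok and bool(np.all(np.abs(resid) <= tol))
        return a, r, lam, resid, conv

    a, r, lam, resid, conv = attempt(False)
    used_reserves = False
    if not conv and options.reserve_enabled:
        log.warning("frame %s: engaging reserve actuators to restore "
                    "feasibility", frame_index)
        a, r, lam, resid, conv = attempt(True)
        used_reserves = True

    if not conv and raise_infeasible:
        worst = int(np.argmax(np.abs(resid) / scale))
        raise InfeasibleFrameError(
            f"frame {frame_index}: no feasible activations (worst residual "
            f"{resid[worst]:.3g} N m on DOF {model.dof_names[worst]!r})",
            frame=frame_index, worst_dof=model.dof_names[worst])
    cost = float(np.dot(weights.w, a * a))
    if used_reserves:
        cost += float(options.reserve_weight * np.dot(r, r))
    return FrameSolution(a, r, cost, resid, conv, used_reserves, dual=lam)


def _solve_frames(trial: TrialData, model: LinkageModel, weights: WeightVector,
                  options: SolverOptions, use_emg: bool) -> ActivationSolution:
    s, e = trial.stance_window
    frames = range(s, e + 1)
    n = e + 1 - s
    m, nd = model.m, model.n_dof
    if use_emg and trial.emg is None:
        raise ParameterError("trial has no EMG data for a constrained solve")

    acts = np.zeros((n, m))
    reserves = np.zeros((n, nd))
    cost = np.zeros(n)
    residuals = np.zeros((n, nd))
    converged = np.zeros(n, dtype=bool)
    x0 = lam0 = None
    for k, t in enumerate(frames):
        emg_row = trial.emg[t] if use_emg else None
        sol = solve_frame(trial.geometry[t], trial.torques[t], model, weights,
                          options, emg_row=emg_row, x0=x0, lam0=lam0,
                          frame_index=t, raise_infeasible=False)
        acts[k] = sol.activations
        reserves[k] = sol.reserves
        cost[k] = sol.cost
        residuals[k] = sol.residuals
        converged[k] = sol.converged
        if sol.converged:
            x0, lam0 = sol.activations, sol.dual
        else:
            x0 = lam0 = None

    solution = ActivationSolution(
        activations=acts,
        muscle_forces=acts * model.f_max[np.newaxis, :],
        reserve_torques=reserves,
        cost=cost,
        residuals=residuals,
        converged=converged,
        frame_window=(s, e),
        weights=weights,
    )
    if not converged.all():
        failing = (np.flatnonzero(~converged) + s).tolist()
        raise InfeasibleTrialError(
            f"{len(failing)} frame(s) failed to solve: {failing[:10]}"
            f"{'...' if len(failing) > 10 else ''}",
            failing_frames=failing, partial_solution=solution)
    return solution


def solve_trial(trial: TrialData, model: LinkageModel, weights: WeightVector,
                options: SolverOptions | None = None) -> ActivationSolution:
    """Weighted static optimization over the trial's stance window."""
    return _solve_frames(trial, model, weights, options or SolverOptions(),
                         use_emg=False)


def solve_trial_emg_constrained(trial: TrialData, model: LinkageModel,
                                weights: WeightVector,
                                options: SolverOptions | None = None
                                ) -> ActivationSolution:
    """Weighted static optimization with EMG-tracking box constraints.

    Each measured muscle's activation is confined to
    ``[max(0, e - delta), min(1, e + delta)]`` around its envelope ``e``;
    unmeasured muscles keep the plain [0, 1] bounds.  Because the feasible
    set is a subset of the unconstrained one, the optimal cost is never
    smaller than the unconstrained optimum for the same weights.
    """
    return _solve_frames(trial, model, weights, options or SolverOptions(),
                         use_emg=True)
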