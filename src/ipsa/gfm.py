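"""Green's function matrix and impulse parametric sensitivity analysis (iPSA).

The Green's function matrix (GFM) S^x(t, tau) maps an infinitesimal state
perturbation at time tau to the state change at a later time t; it solves the
variational system dS^x/dt = (df/dx)(x(t)) S^x with S^x(tau, tau) = I on the
nominal trajectory.

The iPSA coefficient iS_{i,j}(t, tau) is the response of x_i(t) to a Dirac
impulse on parameter p_j at time tau.  An impulse on a kinetic parameter acts
only at tau, instantaneously kicking the state by (df/dp_j) dtau, after which
the unperturbed dynamics propagate the kick:

    iS(t, tau) = S^x(t, tau) · (df/dp)(x(tau), p, tau)

so iS(tau, tau) = df/dp evaluated on the nominal trajectory at tau.  Resolving
the perturbation time separates *when* a parameter matters from *whether* it
matters — information a persistent-perturbation (classical PSA) coefficient
integrates away.  The classical field is recovered by superposing impulses:
S(t, tau) = ∫_tau^t iS(t, sigma) d sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .errors import GridMismatchError, SimulationError, ValidationError
from .model import OdeModel, Trajectory, simulate
from .psa import NORMALIZATION_FLOOR, SensitivityField, psa_direct

__all__ = [
    "GreensFunction",
    "ImpulseField",
    "greens_function",
    "ipsa",
    "ipsa_pulse_oracle",
    "normalize_ipsa",
    "psa_ipsa_consistency",
    "export_heatmap",
]

#: warn when a dense two-time array would exceed this many entries
MEMORY_GUARD_ENTRIES = 10_000_000

_EPS = 1e-12


@dataclass
class GreensFunction:
    """Two-time state-to-state sensitivity matrices S^x(t, tau).

    ``data`` has shape (len(t_grid), len(tau_grid), n, n); entries with
    t < tau are NaN (an effect cannot precede its cause).
    """

    tau_grid: np.ndarray
    t_grid: np.ndarray
    data: np.ndarray
    state_names: list[str]

    @property
    def n(self) -> int:
        return len(self.state_names)

    def at(self, t: float, tau: float) -> np.ndarray:
        """S^x(t, tau) for grid points; S^x(tau, tau) = I exactly."""
        if abs(t - tau) <= _EPS:
            return np.eye(self.n)
        it = np.argmin(np.abs(self.t_grid - t))
        ik = np.argmin(np.abs(self.tau_grid - tau))
        if abs(self.t_grid[it] - t) > _EPS or abs(self.tau_grid[ik] - tau) > _EPS:
            raise ValidationError(f"(t={t:g}, tau={tau:g}) not on the stored grid")
        M = self.data[it, ik]
        if not np.all(np.isfinite(M)):
            raise ValidationError(f"S^x undefined for t={t:g} < tau={tau:g}")
        return M


@dataclass
class ImpulseField:
    """iPSA coefficients iS_{i,j}(t, tau) on a two-time grid.

    ``raw`` has shape (len(t_grid), len(tau_grid), n, m+n).  Entries with
    t < tau are NaN.  Initial-condition columns are defined only at
    tau = t0 (an impulse on an initial condition at a later tau is just a
    state perturbation, i.e. a GFM column); elsewhere they are NaN.
    """

    tau_grid: np.ndarray
    t_grid: np.ndarray
    raw: np.ndarray
    param_labels: list[str]
    state_names: list[str]
    nominal: np.ndarray
    m: int  # number of kinetic parameters (leading columns)
    trajectory: Trajectory | None = None
    normalized: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.state_names)


def _check_guard(entries: int) -> None:
    if entries > MEMORY_GUARD_ENTRIES:
        warnings.warn(
            f"two-time sensitivity storage holds {entries:.2e} entries; "
            "consider coarser grids",
            RuntimeWarning,
            stacklevel=3,
        )


def greens_function(
    model: OdeModel,
    traj: Trajectory,
    tau_grid: np.ndarray,
    t_grid: np.ndarray,
    rtol: float | None = None,
    atol: float | None = None,
) -> GreensFunction:
    """Compute S^x(t, tau) for every grid pair with t >= tau.

    Per perturbation time tau, the n² variational equations are integrated
    forward from the identity, with the Jacobian evaluated on a cubic Hermite
    interpolant of the stored nominal trajectory (no state re-integration).
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(tau_grid) <= 0) or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("tau_grid and t_grid must be strictly increasing")
    if tau_grid[0] < traj.times[0] - _EPS or t_grid[-1] > traj.times[-1] + _EPS:
        raise ValidationError("grids must lie within the trajectory span")
    rtol = model.simulation.rtol if rtol is None else rtol
    atol = model.simulation.atol if atol is None else atol

    n = model.n
    _check_guard(len(t_grid) * len(tau_grid) * n * n)
    x_of = traj.interpolant()
    k = traj.params[: model.m]

    def rhs_S(t, Svec):
        Jx = model.jac_x(x_of(t), k, t)
        return (Jx @ Svec.reshape(n, n)).ravel()

    data = np.full((len(t_grid), len(tau_grid), n, n), np.nan)
    eye = np.eye(n).ravel()
    for ik, tau in enumerate(tau_grid):
        sel = t_grid >= tau - _EPS
        t_eval = t_grid[sel]
        if len(t_eval) == 0:
            continue
        at_tau = np.abs(t_eval - tau) <= _EPS
        t_run = t_eval[~at_tau]
        if len(t_run):
            sol = solve_ivp(
                rhs_S,
                (tau, t_run[-1]),
                eye,
                method=model.simulation.method,
                t_eval=t_run,
                rtol=rtol,
                atol=atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"GFM integration failed for tau={tau:g}: {sol.message}",
                    time=float(sol.t[-1]) if len(sol.t) else tau,
                )
            mats = sol.y.T.reshape(len(t_run), n, n)
        else:
            mats = np.empty((0, n, n))
        idx = np.flatnonzero(sel)
        data[idx[at_tau], ik] = np.eye(n)
        data[idx[~at_tau], ik] = mats
    return GreensFunction(
        tau_grid=tau_grid, t_grid=t_grid, data=data, state_names=list(model.state_names)
    )


def ipsa(model: OdeModel, traj: Trajectory, gfm: GreensFunction) -> ImpulseField:
    """Impulse sensitivities iS(t, tau) = S^x(t, tau) · (df/dp)(x(tau)).

    Kinetic-parameter columns are defined on the whole lower triangle
    t >= tau; initial-condition columns only at tau = t0, where they equal
    the corresponding GFM columns (state-perturbation equivalence).
    """
    if gfm.state_names != list(model.state_names):
        raise GridMismatchError("GFM was built for a different model")
    if gfm.tau_grid[0] < traj.times[0] - _EPS or gfm.t_grid[-1] > traj.times[-1] + _EPS:
        raise GridMismatchError("GFM grids exceed the trajectory span")
    n, m, P = model.n, model.m, model.augmented_dim
    _check_guard(len(gfm.t_grid) * len(gfm.tau_grid) * n * P)
    x_of = traj.interpolant()
    k = traj.params[:m]

    raw = np.full((len(gfm.t_grid), len(gfm.tau_grid), n, P), np.nan)
    t0 = traj.times[0]
    for ik, tau in enumerate(gfm.tau_grid):
        Jp = model.jac_p(x_of(tau), k, tau)  # (n, m)
        sel = gfm.t_grid >= tau - _EPS
        mats = gfm.data[sel, ik]  # (T_k, n, n)
        raw[sel, ik, :, :m] = np.einsum("tij,jk->tik", mats, Jp)
        if abs(tau - t0) <= _EPS:
            raw[sel, ik, :, m:] = mats
    return ImpulseField(
        tau_grid=gfm.tau_grid,
        t_grid=gfm.t_grid,
        raw=raw,
        param_labels=model.augmented_labels,
        state_names=list(model.state_names),
        nominal=traj.params.copy(),
        m=m,
        trajectory=traj,
    )


def ipsa_pulse_oracle(
    model: OdeModel,
    tau: float,
    delta_tau: float,
    delta_p_rel: float,
    t_grid: np.ndarray,
    rtol: float | None = None,
    atol: float | None = None,
) -> ImpulseField:
    """Finite-pulse approximation of the impulse sensitivities at one tau.

    For each kinetic parameter j the model is re-simulated with p_j raised by
    (delta_p_rel · p_j)/delta_tau on [tau, tau + delta_tau] only, then
    restored; the quotient (x_pert − x_nom)/(delta_p_rel · p_j) converges to
    iS(t, tau) as delta_tau, delta_p → 0 (first order in delta_tau).

    Returns an :class:`ImpulseField` with a single tau; initial-condition
    columns are NaN.
    """
    if not (0 <= delta_p_rel <= 0.01):
        raise ValidationError("delta_p_rel must be in [0, 0.01]")
    if delta_tau <= 0:
        raise ValidationError("delta_tau must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid[0] - _EPS <= tau <= t_grid[-1] - delta_tau):
        raise ValidationError("pulse [tau, tau+delta_tau] must fit inside t_grid")
    rtol = model.simulation.rtol if rtol is None else rtol
    atol = model.simulation.atol if atol is None else atol

    n, m, P = model.n, model.m, model.augmented_dim
    nominal = simulate(model, t_grid, rtol=rtol, atol=atol)
    raw = np.full((len(t_grid), 1, n, P), np.nan)
    after = t_grid >= tau - _EPS
    raw[~after, 0, :, :m] = np.nan
    raw[after, 0, :, :m] = 0.0

    if delta_p_rel == 0:
        out = raw  # zero-height pulse: identically zero field on t >= tau
    else:
        k_nom = model.param_values

        def _solve(x0, kinetic, t_span, t_eval):
            sol = solve_ivp(
                lambda t, x: model.rhs(x, kinetic, t),
                t_span,
                x0,
                method=model.simulation.method,
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
                jac=lambda t, x: model.jac_x(x, kinetic, t),
            )
            if not sol.success:
                raise SimulationError(
                    f"pulse simulation failed ({sol.message}); try a larger delta_tau",
                    time=float(sol.t[-1]) if len(sol.t) else t_span[0],
                )
            return sol

        x_tau = nominal.interpolant()(tau)
        for j in range(m):
            if k_nom[j] == 0:
                raw[after, 0, :, j] = 0.0
                continue
            delta_p = delta_p_rel * k_nom[j]
            k_pulse = k_nom.copy()
            k_pulse[j] += delta_p / delta_tau
            # pulse leg
            during = (t_grid > tau + _EPS) & (t_grid < tau + delta_tau - _EPS)
            sol_pulse = _solve(x_tau, k_pulse, (tau, tau + delta_tau), None)
            x_end = sol_pulse.y[:, -1]
            if during.any():
                d = _solve(x_tau, k_pulse, (tau, tau + delta_tau), t_grid[during])
                raw[during, 0, :, j] = (d.y.T - nominal.states[during]) / delta_p
            # restored leg
            tail = t_grid >= tau + delta_tau - _EPS
            if tail.any():
                t_tail = t_grid[tail]
                sol_tail = _solve(
                    x_end, k_nom, (tau + delta_tau, max(t_tail[-1], tau + delta_tau)), t_tail
                )
                raw[tail, 0, :, j] = (sol_tail.y.T - nominal.states[tail]) / delta_p
            raw[np.abs(t_grid - tau) <= _EPS, 0, :, j] = model.jac_p(x_tau, k_nom, tau)[:, j]
        out = raw
    return ImpulseField(
        tau_grid=np.array([tau]),
        t_grid=t_grid,
        raw=out,
        param_labels=model.augmented_labels,
        state_names=list(model.state_names),
        nominal=nominal.params.copy(),
        m=m,
        trajectory=nominal,
    )


def normalize_ipsa(field: ImpulseField, traj: Trajectory) -> ImpulseField:
    """Relative impulse sensitivities: multiply by p_j / x_i(t).

    Same contract as the PSA normalization: the state value at the
    *observation* time scales each row, entries with |x_i(t)| below the floor
    are NaN, and p_j = 0 columns are exactly zero (where defined).
    """
    if traj.times[0] > field.t_grid[0] + _EPS or traj.times[-1] < field.t_grid[-1] - _EPS:
        raise GridMismatchError("trajectory does not cover the field's observation grid")
    x = traj.interpolant()(field.t_grid)  # (T, n)
    floor = NORMALIZATION_FLOOR * np.maximum(np.max(np.abs(traj.states), axis=0), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = field.raw * (field.nominal[None, None, None, :] / x[:, None, :, None])
    undefined = np.abs(x)[:, None, :, None] < floor[None, None, :, None]
    scaled = np.where(undefined, np.nan, scaled)
    zero_p = field.nominal == 0
    defined = np.isfinite(field.raw)
    scaled[..., zero_p] = np.where(defined[..., zero_p], 0.0, np.nan)
    return replace(field, normalized=scaled)


def psa_ipsa_consistency(
    model: OdeModel,
    traj: Trajectory,
    tau: float,
    n_sigma: int = 201,
    n_check: int = 9,
) -> float:
    """Max relative residual of the superposition identity
    S(t, tau) = ∫_tau^t iS(t, sigma) d sigma (kinetic parameters).

    The classical field comes from the direct method; the integral is a
    trapezoidal quadrature of impulse sensitivities over a sigma grid of
    ``n_sigma`` points, evaluated at ``n_check`` observation times.  The
    residual is scaled by the largest |S| over the compared entries.
    """
    if n_sigma < 2:
        raise ValidationError("n_sigma must be at least 2")
    t_end = traj.times[-1]
    if not (traj.times[0] - _EPS <= tau < t_end):
        raise ValidationError("tau must lie inside the trajectory span")
    n, m = model.n, model.m
    k = traj.params[:m]
    x_of = traj.interpolant()

    t_check = np.linspace(tau, t_end, n_check + 1)[1:]  # observation times, t > tau
    sigma = np.linspace(tau, t_end, n_sigma)
    gfm = greens_function(model, traj, sigma, t_check)
    field = ipsa(model, traj, gfm)

    S_direct = psa_direct(model, np.concatenate([[tau], t_check]), tau)
    S_ref = S_direct.raw[1:, :, :m]  # (n_check, n, m)

    residual = 0.0
    scale = max(np.max(np.abs(S_ref)), 1e-300)
    for it, t in enumerate(t_check):
        sel = sigma <= t + _EPS
        sig = sigma[sel]
        vals = field.raw[it, sel, :, :m]  # (K_t, n, m)
        if abs(sig[-1] - t) > _EPS:
            # close the quadrature interval at sigma = t, where iS = df/dp
            sig = np.append(sig, t)
            vals = np.concatenate([vals, model.jac_p(x_of(t), k, t)[None]], axis=0)
        Q = np.trapezoid(vals, sig, axis=0)
        residual = max(residual, float(np.max(np.abs(S_ref[it] - Q))) / scale)
    return residual


def export_heatmap(
    field: ImpulseField,
    state: int | str,
    parameter: str,
    out: str | Path,
) -> "pd.DataFrame":
    """Write the (t × tau) matrix of one state/parameter pair as CSV.

    Rows are observation times, columns perturbation times; the upper
    triangle (t < tau) is written as NA.  Normalized values are used when
    present, raw otherwise.  Returns the frame that was written.
    """
    import pandas as pd

    if isinstance(state, str):
        try:
            i_state = field.state_names.index(state)
        except ValueError:
            raise ValidationError(f"unknown state {state!r}") from None
    else:
        i_state = int(state)
    try:
        j = field.param_labels.index(parameter)
    except ValueError:
        raise ValidationError(f"unknown parameter {parameter!r}") from None
    data = field.normalized if field.normalized is not None else field.raw
    M = data[:, :, i_state, j]
    frame = pd.DataFrame(M, index=field.t_grid, columns=field.tau_grid)
    frame.index.name = "t"
    # repr-precision floats so the CSV round-trips bit-exactly
    frame.to_csv(out, na_rep="NA", float_format=lambda v: repr(float(v)))
    return frame
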