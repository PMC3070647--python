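"""Classical local parametric sensitivity analysis (direct method).

The sensitivity coefficient S_{i,j}(t, tau) = dx_i(t)/dp_j is the response of
state ``x_i`` at observation time ``t`` to an infinitesimal *persistent* (step)
perturbation of the augmented parameter ``p_j`` applied at time ``tau``.  It is
computed by the direct method: the variational equations

    dS/dt = (df/dx) S + [df/dp, 0],    S(tau, tau) = [0^{n x m}  I^{n x n}]

are integrated together with the model states.  A step-perturbation
finite-difference oracle is provided as an independent ground truth, plus
normalization and the four consolidated ranking metrics (infinite norm, FIM
diagonal, time integral, magnitude at a time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import GridMismatchError, SimulationError, ValidationError
from .model import OdeModel, Trajectory, simulate

__all__ = [
    "SensitivityField",
    "RankingTable",
    "psa_direct",
    "psa_fd_oracle",
    "normalize",
    "consolidate",
    "METRICS",
]

METRICS = ("inf", "fim", "int", "at_time")

#: relative floor below which |x_i(t)| makes normalized sensitivities undefined
NORMALIZATION_FLOOR = 1e-12


@dataclass
class SensitivityField:
    """PSA coefficients S_{i,j}(t, tau) for one perturbation time tau.

    ``raw`` has shape (len(times), n, m+n); columns follow the augmented
    ordering [kinetic parameters, initial conditions].  ``normalized`` holds
    p_j/x_i(t)-scaled values with NaN marking undefined entries (state below
    the normalization floor).
    """

    times: np.ndarray
    tau: float
    raw: np.ndarray
    param_labels: list[str]
    state_names: list[str]
    nominal: np.ndarray  # augmented vector the field was computed at
    normalized: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_labels)


@dataclass
class RankingTable:
    """Per-parameter consolidated scores for one state, sorted descending."""

    metric_name: str
    state_index: int
    state_name: str
    param_labels: list[str]
    values: np.ndarray
    order: np.ndarray  # parameter indices, best first
    flags: list[str]  # labels whose column was entirely undefined

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "parameter": [self.param_labels[j] for j in self.order],
                "metric": self.metric_name,
                "value": self.values[self.order],
            }
        )


def _state_at(model: OdeModel, tau: float, t0: float, rtol: float, atol: float) -> np.ndarray:
    """Nominal state at tau, integrating from the initial conditions if needed."""
    if abs(tau - t0) <= 1e-14 * max(1.0, abs(t0)):
        return model.initial_conditions.copy()
    seg = simulate(model, np.array([t0, tau]), rtol=rtol, atol=atol)
    return seg.states[-1]


def psa_direct(
    model: OdeModel,
    t_grid: np.ndarray,
    tau: float,
    rtol: float | None = None,
    atol: float | None = None,
) -> SensitivityField:
    """Direct-method PSA: integrate states + variational equations from tau.

    Returns the raw field on ``t_grid``; entries at t < tau are exactly zero
    (the perturbation has not been applied yet), and at t = tau the kinetic
    block is zero while the initial-condition block is the identity.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be strictly increasing")
    if not (t_grid[0] - 1e-12 <= tau <= t_grid[-1] + 1e-12):
        raise ValidationError(f"tau={tau:g} outside t_grid span")
    rtol = model.simulation.rtol if rtol is None else rtol
    atol = model.simulation.atol if atol is None else atol

    n, m, P = model.n, model.m, model.augmented_dim
    k = model.param_values
    x_tau = _state_at(model, tau, t_grid[0], rtol, atol)

    S0 = np.zeros((n, P))
    S0[:, m:] = np.eye(n)
    y0 = np.concatenate([x_tau, S0.ravel()])

    def rhs_aug(t, y):
        x = y[:n]
        S = y[n:].reshape(n, P)
        f = model.rhs(x, k, t)
        Jx = model.jac_x(x, k, t)
        dS = Jx @ S
        dS[:, :m] += model.jac_p(x, k, t)
        return np.concatenate([f, dS.ravel()])

    after = t_grid >= tau - 1e-12
    t_eval = t_grid[after]
    raw = np.zeros((len(t_grid), n, P))
    if len(t_eval):
        sol = solve_ivp(
            rhs_aug,
            (tau, max(t_eval[-1], tau)),
            y0,
            method=model.simulation.method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if len(sol.t) else tau
            raise SimulationError(f"sensitivity integration failed: {sol.message}", time=t_fail)
        S_all = sol.y[n:].T.reshape(len(t_eval), n, P)
        raw[after] = S_all
        # exact initial blocks where the grid hits tau
        at_tau = np.abs(t_grid - tau) <= 1e-12
        raw[at_tau] = S0
    return SensitivityField(
        times=t_grid,
        tau=float(tau),
        raw=raw,
        param_labels=model.augmented_labels,
        state_names=list(model.state_names),
        nominal=model.augmented_values(),
    )


def psa_fd_oracle(
    model: OdeModel,
    t_grid: np.ndarray,
    tau: float,
    delta: float = 1e-5,
    rtol: float | None = None,
    atol: float | None = None,
) -> SensitivityField:
    """Step-perturbation finite-difference ground truth for the PSA field.

    For each augmented parameter j the model is re-simulated with p_j stepped
    by ±delta·p_j from time tau onward (initial-condition parameters: the
    corresponding state is jumped at tau) and the central-difference quotient
    is returned.  Costs O(m+n) pairs of simulations.

    Difference quotients amplify integrator error by 1/step, so the default
    tolerances here are tighter than the model's simulation settings.
    """
    if not (0 < delta <= 0.1):
        raise ValidationError("delta must be in (0, 0.1]")
    t_grid = np.asarray(t_grid, dtype=float)
    if not (t_grid[0] - 1e-12 <= tau <= t_grid[-1] + 1e-12):
        raise ValidationError(f"tau={tau:g} outside t_grid span")
    rtol = min(model.simulation.rtol, 1e-10) if rtol is None else rtol
    atol = min(model.simulation.atol, 1e-12) if atol is None else atol

    n, m, P = model.n, model.m, model.augmented_dim
    aug = model.augmented_values()
    x_tau = _state_at(model, tau, t_grid[0], rtol, atol)
    after = t_grid >= tau - 1e-12
    t_after = t_grid[after]
    raw = np.zeros((len(t_grid), n, P))

    def _segment(x_start: np.ndarray, kinetic: np.ndarray) -> np.ndarray:
        """States on t_after for an integration started at tau from x_start."""
        if len(t_after) == 1 and abs(t_after[0] - tau) <= 1e-12:
            return x_start[None, :]
        sol = solve_ivp(
            lambda t, x: model.rhs(x, kinetic, t),
            (tau, t_after[-1]),
            x_start,
            method=model.simulation.method,
            t_eval=t_after,
            rtol=rtol,
            atol=atol,
            jac=lambda t, x: model.jac_x(x, kinetic, t),
        )
        if not sol.success:
            raise SimulationError(
                f"oracle integration failed: {sol.message}",
                time=float(sol.t[-1]) if len(sol.t) else tau,
            )
        out = sol.y.T
        if abs(t_after[0] - tau) <= 1e-12:
            out[0] = x_start
        return out

    for j in range(P):
        h = delta * abs(aug[j]) if aug[j] != 0 else delta
        if j < m:
            kp, km_ = model.param_values.copy(), model.param_values.copy()
            kp[j] += h
            km_[j] -= h
            xp = _segment(x_tau, kp)
            xm = _segment(x_tau, km_)
        else:
            e = np.zeros(n)
            e[j - m] = h
            xp = _segment(x_tau + e, model.param_values)
            xm = _segment(x_tau - e, model.param_values)
        raw[after, :, j] = (xp - xm) / (2 * h)
    return SensitivityField(
        times=t_grid,
        tau=float(tau),
        raw=raw,
        param_labels=model.augmented_labels,
        state_names=list(model.state_names),
        nominal=aug,
    )


def normalize(field: SensitivityField, traj: Trajectory) -> SensitivityField:
    """Scale to relative sensitivities S̄ = (p_j / x_i(t)) · S.

    Entries where |x_i(t)| falls below ``NORMALIZATION_FLOOR`` times the
    state's trajectory maximum are marked NaN (undefined) rather than allowed
    to blow up; columns with p_j = 0 are exactly zero.
    """
    if len(traj.times) != len(field.times) or not np.allclose(
        traj.times, field.times, rtol=0, atol=1e-12
    ):
        raise GridMismatchError("trajectory and sensitivity field use different time grids")
    x = traj.states  # (T, n)
    floor = NORMALIZATION_FLOOR * np.maximum(np.max(np.abs(x), axis=0), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = field.raw * (field.nominal[None, None, :] / x[:, :, None])
    undefined = np.broadcast_to(
        np.abs(x)[:, :, None] < floor[None, :, None], scaled.shape
    )
    scaled = np.where(undefined, np.nan, scaled)
    # zero parameters give exactly zero relative sensitivity where defined
    zero_p = field.nominal == 0
    scaled[:, :, zero_p] = np.where(undefined[:, :, zero_p], np.nan, 0.0)
    return replace(field, normalized=scaled)


def consolidate(
    field: SensitivityField,
    metric: str,
    state: int | str,
    t_star: float | None = None,
) -> RankingTable:
    """Collapse a normalized field into one score per augmented parameter.

    inf: max_t |S̄|; fim: sqrt(sum_t S̄²) (diagonal of S̄ᵀS̄); int: trapezoidal
    integral of |S̄|; at_time: |S̄(t_star)| with linear interpolation.
    Undefined (NaN) samples are skipped; an all-undefined column scores 0 and
    is flagged with a warning.
    """
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    if field.normalized is None:
        raise ValidationError("consolidate requires a normalized field (call normalize first)")
    if isinstance(state, str):
        try:
            i_state = field.state_names.index(state)
        except ValueError:
            raise ValidationError(f"unknown state {state!r}") from None
    else:
        i_state = int(state)
    if metric == "at_time":
        if t_star is None:
            raise ValidationError("metric 'at_time' requires t_star")
        if not (field.times[0] - 1e-12 <= t_star <= field.times[-1] + 1e-12):
            raise ValidationError(f"t_star={t_star:g} outside the field's time range")

    A = field.normalized[:, i_state, :]  # (T, P)
    t = field.times
    P = field.n_params
    values = np.zeros(P)
    flags: list[str] = []
    for j in range(P):
        col = A[:, j]
        ok = np.isfinite(col)
        if not ok.any():
            flags.append(field.param_labels[j])
            continue
        if metric == "inf":
            values[j] = np.max(np.abs(col[ok]))
        elif metric == "fim":
            values[j] = np.sqrt(np.sum(col[ok] ** 2))
        elif metric == "int":
            if ok.sum() >= 2:
                values[j] = np.trapezoid(np.abs(col[ok]), t[ok])
        else:  # at_time
            values[j] = abs(np.interp(t_star, t[ok], col[ok]))
    if flags:
        warnings.warn(
            f"all-undefined sensitivity column(s) scored 0: {', '.join(flags)}",
            RuntimeWarning,
            stacklevel=2,
        )
    # descending score, ties broken by declaration order (stable sort on -value)
    order = np.argsort(-values, kind="stable")
    return RankingTable(
        metric_name=metric,
        state_index=i_state,
        state_name=field.state_names[i_state],
        param_labels=list(field.param_labels),
        values=values,
        order=order,
        flags=flags,
    )
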