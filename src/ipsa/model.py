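"""ODE models of biochemical networks: construction, simulation, knock-outs.

A model is declared as a set of states, named kinetic parameters, and
reactions (rate expression + stoichiometry).  The right-hand side is the
stoichiometry-weighted sum of reaction rates; Jacobians with respect to
states and kinetic parameters are derived symbolically with sympy where
possible, with a central-difference fallback otherwise.

Kinetic parameters and initial conditions are treated on the same footing
through the *augmented parameter vector* ``p = [kinetic params, initial
conditions]`` (length ``m + n``), in declaration order.  That ordering fixes
the column order of every sensitivity matrix produced downstream.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicHermiteSpline
from sympy.core.function import AppliedUndef

from .errors import (
    ConfigError,
    NoSwitchError,
    SimulationError,
    UnknownReactionError,
    ValidationError,
)

__all__ = [
    "Reaction",
    "OdeModel",
    "Trajectory",
    "SimulationSettings",
    "build_model",
    "simulate",
    "knockout",
    "switching_time",
]

_TIME = sp.Symbol("t", real=True)
# Michaelis-Menten primitive: mm(vmax, km, substrate) = vmax*s/(km + s)
_MM = sp.Function("mm")


@dataclass(frozen=True)
class SimulationSettings:
    """Default integration window and tolerances for a model."""

    t_start: float = 0.0
    t_end: float = 10.0
    n_points: int = 201
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"

    def grid(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)


@dataclass(frozen=True)
class Reaction:
    """One reaction: a rate law and the stoichiometric change it drives."""

    id: str
    rate: sp.Expr
    stoichiometry: dict[str, float]
    source: str = ""


def _parse_rate(text: str, symbols: Mapping[str, sp.Symbol], param_values: Mapping[str, float],
                reaction_id: str) -> sp.Expr:
    """Parse a rate expression, expanding the mm() primitive and validating symbols."""
    local = dict(symbols)
    local["mm"] = _MM
    local["t"] = _TIME
    try:
        expr = sp.sympify(text, locals=local)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ConfigError(f"reaction {reaction_id!r}: cannot parse rate {text!r}: {exc}") from exc

    for fn in expr.atoms(AppliedUndef):
        if fn.func is not _MM:
            raise ConfigError(
                f"reaction {reaction_id!r}: unknown function {fn.func.__name__!r} in rate"
            )
        if len(fn.args) != 3:
            raise ConfigError(
                f"reaction {reaction_id!r}: mm() takes (vmax, km, substrate), got {len(fn.args)} args"
            )
        km = fn.args[1]
        km_val = km.subs({symbols[k]: v for k, v in param_values.items()})
        if km_val.is_number and float(km_val) < 0:
            raise ValidationError(
                f"reaction {reaction_id!r}: negative Michaelis constant {km} = {float(km_val):g}"
            )

    known = set(symbols.values()) | {_TIME}
    unknown = [s for s in expr.free_symbols if s not in known]
    if unknown:
        names = ", ".join(sorted(str(s) for s in unknown))
        raise ConfigError(f"reaction {reaction_id!r}: unknown symbol(s) {names} in rate {text!r}")

    # expand the MM primitive into plain algebra for differentiation
    expr = expr.replace(_MM, lambda v, k, s: v * s / (k + s))
    return expr


class OdeModel:
    """An ODE model dx/dt = f(x, k, t) built from reactions.

    Parameters
    ----------
    name : model identifier.
    state_names : the ``n`` state identifiers, order fixed.
    param_names, param_values : the ``m`` kinetic parameters, declaration order.
    initial_conditions : length-``n`` vector aligned with ``state_names``.
    reactions : the reaction list; the rhs is ``sum_r stoich_r * rate_r``.
    simulation : default integration settings.
    """

    def __init__(
        self,
        name: str,
        state_names: Sequence[str],
        param_names: Sequence[str],
        param_values: Sequence[float],
        initial_conditions: Sequence[float],
        reactions: Sequence[Reaction],
        simulation: SimulationSettings | None = None,
    ):
        self.name = name
        self.state_names = list(state_names)
        self.param_names = list(param_names)
        self.param_values = np.asarray(param_values, dtype=float)
        self.initial_conditions = np.asarray(initial_conditions, dtype=float)
        self.reactions = list(reactions)
        self.simulation = simulation or SimulationSettings()
        if len(self.param_values) != len(self.param_names):
            raise ConfigError("parameter names/values length mismatch")
        if len(self.initial_conditions) != len(self.state_names):
            raise ConfigError("initial conditions must cover every state")

        self._x_syms = [sp.Symbol(s, real=True) for s in self.state_names]
        self._p_syms = [sp.Symbol(p, real=True) for p in self.param_names]
        self._compile()

    # ------------------------------------------------------------------ build
    def _compile(self) -> None:
        n = self.n
        rhs_exprs = [sp.Integer(0)] * n
        index = {s: i for i, s in enumerate(self.state_names)}
        for rx in self.reactions:
            for state, coeff in rx.stoichiometry.items():
                if state not in index:
                    raise ConfigError(
                        f"reaction {rx.id!r}: stoichiometry names unknown state {state!r}"
                    )
                rhs_exprs[index[state]] = rhs_exprs[index[state]] + coeff * rx.rate
        self._rhs_exprs = sp.Matrix(rhs_exprs)

        args = (self._x_syms, self._p_syms, _TIME)
        self._rhs_fn = sp.lambdify(args, self._rhs_exprs, modules="numpy")
        self.jacobian_mode = "symbolic"
        try:
            jx = self._rhs_exprs.jacobian(self._x_syms) if n else sp.Matrix(0, 0, [])
            jp = (
                self._rhs_exprs.jacobian(self._p_syms)
                if self.m
                else sp.zeros(n, 0)
            )
            self._jacx_fn = sp.lambdify(args, jx, modules="numpy")
            self._jacp_fn = sp.lambdify(args, jp, modules="numpy")
        except Exception:  # non-differentiable rate law: fall back to numerics
            self.jacobian_mode = "numeric"
            self._jacx_fn = None
            self._jacp_fn = None

    # ------------------------------------------------------------- dimensions
    @property
    def n(self) -> int:
        return len(self.state_names)

    @property
    def m(self) -> int:
        return len(self.param_names)

    @property
    def augmented_dim(self) -> int:
        """m kinetic parameters followed by n initial conditions."""
        return self.m + self.n

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def augmented_labels(self) -> list[str]:
        """Column labels of sensitivity matrices: kinetic params, then x0's."""
        return self.param_names + [f"{s}_0" for s in self.state_names]

    def augmented_values(self) -> np.ndarray:
        return np.concatenate([self.param_values, self.initial_conditions])

    def state_index(self, state: int | str) -> int:
        if isinstance(state, str):
            try:
                return self.state_names.index(state)
            except ValueError:
                raise ValidationError(f"unknown state {state!r}") from None
        if not 0 <= state < self.n:
            raise ValidationError(f"state index {state} out of range for n={self.n}")
        return int(state)

    # ------------------------------------------------------------- evaluation
    def rhs(self, x: np.ndarray, params: np.ndarray | None = None, t: float = 0.0) -> np.ndarray:
        k = self.param_values if params is None else np.asarray(params, dtype=float)
        out = np.asarray(self._rhs_fn(x, k, t), dtype=float).reshape(self.n)
        return out

    def _fd_step(self, v: float) -> float:
        return max(1e-7, 1e-7 * abs(v))

    def jac_x(self, x: np.ndarray, params: np.ndarray | None = None, t: float = 0.0) -> np.ndarray:
        k = self.param_values if params is None else np.asarray(params, dtype=float)
        if self._jacx_fn is not None:
            return np.asarray(self._jacx_fn(x, k, t), dtype=float).reshape(self.n, self.n)
        x = np.asarray(x, dtype=float)
        J = np.empty((self.n, self.n))
        for j in range(self.n):
            h = self._fd_step(x[j])
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (self.rhs(xp, k, t) - self.rhs(xm, k, t)) / (2 * h)
        return J

    def jac_p(self, x: np.ndarray, params: np.ndarray | None = None, t: float = 0.0) -> np.ndarray:
        """n x m Jacobian with respect to the kinetic parameters only."""
        k = self.param_values if params is None else np.asarray(params, dtype=float)
        if self._jacp_fn is not None:
            return np.asarray(self._jacp_fn(x, k, t), dtype=float).reshape(self.n, self.m)
        J = np.empty((self.n, self.m))
        for j in range(self.m):
            h = self._fd_step(k[j])
            kp, km = k.copy(), k.copy()
            kp[j] += h
            km[j] -= h
            J[:, j] = (self.rhs(x, kp, t) - self.rhs(x, km, t)) / (2 * h)
        return J

    # ------------------------------------------------------------ derivations
    def knockout(self, reaction_ids: Sequence[str]) -> "OdeModel":
        """Return a copy with the named reactions' rates identically zero."""
        known = set(self.reaction_ids)
        for rid in reaction_ids:
            if rid not in known:
                raise UnknownReactionError(rid)
        removed = set(reaction_ids)
        new_reactions = [
            Reaction(r.id, sp.Integer(0) if r.id in removed else r.rate, dict(r.stoichiometry), r.source)
            for r in self.reactions
        ]
        return OdeModel(
            name=f"{self.name}-ko-{'+'.join(reaction_ids)}",
            state_names=self.state_names,
            param_names=self.param_names,
            param_values=self.param_values,
            initial_conditions=self.initial_conditions,
            reactions=new_reactions,
            simulation=self.simulation,
        )

    def with_augmented(self, augmented: np.ndarray) -> "OdeModel":
        """Copy with kinetic parameters and initial conditions replaced."""
        augmented = np.asarray(augmented, dtype=float)
        if augmented.shape != (self.augmented_dim,):
            raise ValidationError(
                f"augmented vector must have length {self.augmented_dim}, got {augmented.shape}"
            )
        out = copy.copy(self)
        out.param_values = augmented[: self.m].copy()
        out.initial_conditions = augmented[self.m :].copy()
        return out

    def __repr__(self) -> str:
        return (
            f"OdeModel({self.name!r}, n={self.n}, m={self.m}, "
            f"reactions={self.reaction_ids})"
        )


@dataclass
class Trajectory:
    """A forward simulation: time grid, state matrix, and provenance."""

    times: np.ndarray
    states: np.ndarray  # (len(times), n)
    model: OdeModel
    params: np.ndarray  # augmented vector actually used

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)

    def state(self, state: int | str) -> np.ndarray:
        return self.states[:, self.model.state_index(state)]

    def interpolant(self) -> CubicHermiteSpline:
        """Cubic Hermite interpolant using rhs-derived slopes at the knots."""
        k = self.params[: self.model.m]
        dydx = np.stack(
            [self.model.rhs(x, k, t) for t, x in zip(self.times, self.states)]
        )
        return CubicHermiteSpline(self.times, self.states, dydx, axis=0)

    def to_frame(self):
        """Tidy (time, state, value) table."""
        import pandas as pd

        n = self.model.n
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "state": np.tile(self.model.state_names, len(self.times)),
                "value": self.states.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# configuration documents
# ---------------------------------------------------------------------------

def build_model(config: Mapping | str | Path) -> OdeModel:
    """Build an :class:`OdeModel` from a declarative config (dict, YAML or JSON path).

    The document declares ``states``, ``parameters`` (name -> value),
    ``reactions`` (id, rate expression, stoichiometry), ``initial_conditions``
    and optionally ``simulation`` (t_start, t_end, n_points, rtol, atol,
    method).  Rates may use the ``mm(vmax, km, s)`` Michaelis-Menten
    primitive, mass action products, and general arithmetic in the declared
    symbols.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    if not isinstance(config, Mapping):
        raise ConfigError("model config must be a mapping")

    for key in ("states", "parameters", "reactions"):
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")

    state_names = list(config["states"])
    if len(set(state_names)) != len(state_names):
        raise ConfigError("duplicate state names")
    raw_params = dict(config["parameters"] or {})
    param_names = list(raw_params)
    clash = set(param_names) & set(state_names)
    if clash:
        raise ConfigError(f"names used as both state and parameter: {sorted(clash)}")
    none_params = [k for k, v in raw_params.items() if v is None]
    if none_params:
        raise ConfigError(
            "parameters without values (fill from a parameter table): "
            + ", ".join(none_params)
        )
    param_values = [float(raw_params[k]) for k in param_names]

    symbols = {s: sp.Symbol(s, real=True) for s in state_names}
    symbols.update({p: sp.Symbol(p, real=True) for p in param_names})

    reactions = []
    seen_ids: set[str] = set()
    for entry in config["reactions"]:
        rid = str(entry.get("id", f"r{len(reactions) + 1}"))
        if rid in seen_ids:
            raise ConfigError(f"duplicate reaction id {rid!r}")
        seen_ids.add(rid)
        rate_text = str(entry["rate"])
        expr = _parse_rate(rate_text, symbols, raw_params if not none_params else {}, rid)
        stoich = {str(k): float(v) for k, v in dict(entry["stoichiometry"]).items()}
        for state in stoich:
            if state not in state_names:
                raise ConfigError(
                    f"reaction {rid!r}: stoichiometry names unknown state {state!r}"
                )
        reactions.append(Reaction(rid, expr, stoich, source=rate_text))

    ic_map = dict(config.get("initial_conditions") or {})
    for state in ic_map:
        if state not in state_names:
            raise ConfigError(f"initial condition for unknown state {state!r}")
    x0 = [float(ic_map.get(s, 0.0)) for s in state_names]

    sim_cfg = dict(config.get("simulation") or {})
    sim = SimulationSettings(
        t_start=float(sim_cfg.get("t_start", 0.0)),
        t_end=float(sim_cfg.get("t_end", 10.0)),
        n_points=int(sim_cfg.get("n_points", 201)),
        rtol=float(sim_cfg.get("rtol", 1e-8)),
        atol=float(sim_cfg.get("atol", 1e-10)),
        method=str(sim_cfg.get("method", "LSODA")),
    )
    return OdeModel(
        name=str(config.get("name", "model")),
        state_names=state_names,
        param_names=param_names,
        param_values=param_values,
        initial_conditions=x0,
        reactions=reactions,
        simulation=sim,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    model: OdeModel,
    t_grid: np.ndarray | None = None,
    params: np.ndarray | None = None,
    rtol: float | None = None,
    atol: float | None = None,
    method: str | None = None,
) -> Trajectory:
    """Integrate the model on ``t_grid`` (defaults to the config's grid).

    ``params``, if given, is a full augmented vector ``[kinetic, x0]`` of
    length ``m + n``; its initial-condition block replaces the model's.
    """
    if t_grid is None:
        t_grid = model.simulation.grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValidationError("t_grid must be a strictly increasing 1-d vector")

    if params is None:
        k = model.param_values
        x0 = model.initial_conditions
        aug = model.augmented_values()
    else:
        aug = np.asarray(params, dtype=float)
        if aug.shape != (model.augmented_dim,):
            raise ValidationError(
                f"params must be the augmented vector of length {model.augmented_dim}"
            )
        k = aug[: model.m]
        x0 = aug[model.m :]

    sol = solve_ivp(
        lambda t, x: model.rhs(x, k, t),
        (t_grid[0], t_grid[-1]),
        x0,
        method=method or model.simulation.method,
        t_eval=t_grid,
        rtol=model.simulation.rtol if rtol is None else rtol,
        atol=model.simulation.atol if atol is None else atol,
        jac=(lambda t, x: model.jac_x(x, k, t)),
        dense_output=False,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else float(t_grid[0])
        raise SimulationError(f"integration failed: {sol.message}", time=t_fail)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = np.argwhere(~np.isfinite(states))[0]
        raise SimulationError("non-finite state encountered", time=float(t_grid[bad[0]]))
    traj = Trajectory(times=t_grid, states=states, model=model, params=aug)
    # anchor the first sample exactly at the initial conditions
    traj.states[0] = x0
    return traj


def knockout(model: OdeModel, reaction_ids: Sequence[str]) -> OdeModel:
    """Functional alias for :meth:`OdeModel.knockout`."""
    return model.knockout(reaction_ids)


def switching_time(traj: Trajectory, state: int | str) -> float:
    """Time at which a switch-like state rises fastest (argmax of dx/dt).

    The derivative is estimated by central differences on the trajectory
    grid and the argmax refined by a local quadratic fit; ties break to the
    earliest time.  A trajectory whose derivative is ~0 everywhere raises
    :class:`NoSwitchError`.
    """
    if len(traj.times) < 3:
        raise ValidationError("switching_time needs at least 3 trajectory points")
    i_state = traj.model.state_index(state)
    x = traj.states[:, i_state]
    t = traj.times
    d = np.gradient(x, t)
    scale = max(1.0, float(np.max(np.abs(x))))
    if np.max(np.abs(d)) <= 1e-9 * scale:
        raise NoSwitchError(f"state {traj.model.state_names[i_state]!r} never switches")
    i = int(np.argmax(d))  # first occurrence = earliest tie
    if i == 0 or i == len(t) - 1:
        return float(t[i])
    # quadratic through the three bracketing samples; vertex clamped to them
    t3, d3 = t[i - 1 : i + 2], d[i - 1 : i + 2]
    a, b, _ = np.polyfit(t3 - t3[1], d3, 2)
    if a >= 0:
        return float(t[i])
    t_star = float(t3[1] - b / (2 * a))
    return float(np.clip(t_star, t3[0], t3[2]))
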