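"""Built-in models: closed-form oracles, the 6-state switch network, random
Michaelis-Menten networks, and the apoptosis model schema/loader.

Closed-form entries ship analytic sensitivity callables so the direct-method,
Green's-function and impulse computations can all be checked against exact
expressions.  The switch-network parameters are documented stand-ins chosen
to give a switch-like x6 activation whose switching is carried by the
indirect pathway; they are not measured values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError, GenerationError, SimulationError, ValidationError
from .model import OdeModel, build_model, simulate

__all__ = [
    "FixtureEntry",
    "CATALOG",
    "list_fixtures",
    "get_fixture",
    "load_fixture_config",
    "make_linear_model",
    "make_simple_network",
    "make_random_mm",
    "load_apoptosis_model",
]


def load_fixture_config(name: str) -> dict:
    """Load a shipped fixture config document by file stem."""
    ref = resources.files("ipsa") / "fixtures_data" / f"{name}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ValidationError(f"no fixture config named {name!r}") from None
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# closed-form linear models
# ---------------------------------------------------------------------------

def make_linear_model(
    a: Sequence[float], x0: Sequence[float]
) -> tuple[OdeModel, dict[str, Callable]]:
    """Decoupled linear model dx_i/dt = a_i x_i with exact sensitivities.

    ``a`` entries should be negative for stability.  Returns the model and a
    dict of analytic callables (vectorized in t):

    - ``x(t)``: states, shape (n,)
    - ``psa(t, tau)``: classical S(t, tau) w.r.t. the augmented vector,
      shape (n, m+n) — step perturbation applied at tau
    - ``gfm(t, tau)``: S^x(t, tau), shape (n, n)
    - ``ipsa(t, tau)``: impulse sensitivities w.r.t. kinetic parameters,
      shape (n, m)
    """
    a = np.asarray(a, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n = len(a)
    if len(x0) != n:
        raise ValidationError("a and x0 must have equal length")
    states = [f"x{i + 1}" for i in range(n)]
    params = {f"a{i + 1}": float(a[i]) for i in range(n)}
    reactions = [
        {"id": f"g{i + 1}", "rate": f"a{i + 1}*x{i + 1}", "stoichiometry": {f"x{i + 1}": 1}}
        for i in range(n)
    ]
    model = build_model(
        {
            "name": f"linear_{n}state",
            "states": states,
            "parameters": params,
            "reactions": reactions,
            "initial_conditions": {s: float(v) for s, v in zip(states, x0)},
            "simulation": {"t_start": 0.0, "t_end": 5.0, "n_points": 101},
        }
    )

    def x_of(t):
        return x0 * np.exp(a * t)

    def gfm_of(t, tau):
        return np.diag(np.exp(a * (t - tau)))

    def psa_of(t, tau):
        # persistent perturbation from tau: d/da_i -> (t-tau) x_i(t);
        # state jump at tau for the x0 block -> e^{a_i (t-tau)}
        S = np.zeros((n, 2 * n))
        if t >= tau:
            S[np.arange(n), np.arange(n)] = (t - tau) * x_of(t)
            S[np.arange(n), n + np.arange(n)] = np.exp(a * (t - tau))
        return S

    def ipsa_of(t, tau):
        # impulse kick df/da_i = x_i(tau), propagated by e^{a_i (t-tau)}
        iS = np.zeros((n, n))
        if t >= tau:
            iS[np.arange(n), np.arange(n)] = np.exp(a * (t - tau)) * x_of(tau)
        return iS

    return model, {"x": x_of, "psa": psa_of, "gfm": gfm_of, "ipsa": ipsa_of}


# ---------------------------------------------------------------------------
# the 6-state switch network
# ---------------------------------------------------------------------------

#: reaction ids of the two x6-activating routes
DIRECT_PATHWAY = ["r2"]
INDIRECT_PATHWAY = ["r3", "r4"]


def make_simple_network(params: Mapping[str, float] | None = None) -> OdeModel:
    """The 6-state, 4-reaction switch network.

    r1 converts the stimulus x1 into the enzyme x2 (mass action, kf1);
    the direct route r2 has x2 catalysing activation of x6 from the pool x4;
    the indirect route first builds the second enzyme x5 from x3 (r3,
    catalysed by x2) which then drives the same x4 -> x6 activation (r4).
    All catalytic steps are irreversible Michaelis-Menten.

    ``params``, if given, replaces the default rate constants; missing
    constants raise.  The defaults are stand-ins tuned for the qualitative
    behaviour (switch-like x6, indirect pathway dominant at the switch,
    direct pathway driving early activation), not measured values.
    """
    config = load_fixture_config("simple_switch")
    if params is not None:
        declared = set(config["parameters"])
        missing = declared - set(params)
        if missing:
            raise ConfigError(
                "parameter table missing declared constant(s): " + ", ".join(sorted(missing))
            )
        config["parameters"] = {k: float(params[k]) for k in config["parameters"]}
    return build_model(config)


# ---------------------------------------------------------------------------
# random Michaelis-Menten / mass-action networks
# ---------------------------------------------------------------------------

def _random_mm_config(seed: int, n_states: int, scale: float) -> dict:
    rng = np.random.default_rng(seed)
    states = [f"x{i + 1}" for i in range(n_states)]
    n_reactions = n_states
    params: dict[str, float] = {}
    reactions = []
    for r in range(n_reactions):
        src, dst = rng.choice(n_states, size=2, replace=False)
        kind = rng.choice(["mass_action", "mm", "mm_enzyme"])
        rid = f"r{r + 1}"
        if kind == "mass_action":
            params[f"k{r + 1}"] = round(float(rng.uniform(0.1, 10)) * scale, 12)
            rate = f"k{r + 1}*{states[src]}"
        else:
            params[f"v{r + 1}"] = round(float(rng.uniform(0.1, 10)) * scale, 12)
            params[f"km{r + 1}"] = round(float(rng.uniform(0.1, 10)), 12)
            if kind == "mm_enzyme":
                enz = states[int(rng.integers(n_states))]
                rate = f"mm(v{r + 1}*{enz}, km{r + 1}, {states[src]})"
            else:
                rate = f"mm(v{r + 1}, km{r + 1}, {states[src]})"
        reactions.append(
            {"id": rid, "rate": rate, "stoichiometry": {states[src]: -1, states[dst]: 1}}
        )
    x0 = {s: round(float(rng.uniform(0.1, 10)), 12) for s in states}
    return {
        "name": f"random_mm_seed{seed}_n{n_states}",
        "states": states,
        "parameters": params,
        "reactions": reactions,
        "initial_conditions": x0,
        "simulation": {"t_start": 0.0, "t_end": 10.0, "n_points": 101},
    }


def make_random_mm(seed: int, n_states: int = 4) -> OdeModel:
    """Random sparse conversion network with MM/mass-action kinetics.

    Reactions only interconvert species (total mass is conserved), so
    trajectories on [0, 10] are bounded; if the integrator still struggles
    the rate constants are halved, up to 10 times.  The same seed always
    yields an identical model (config hash stored on ``model.config_hash``).
    """
    if not (2 <= n_states <= 20):
        raise ValidationError("n_states must be in [2, 20]")
    scale = 1.0
    for _attempt in range(10):
        config = _random_mm_config(seed, n_states, scale)
        model = build_model(config)
        try:
            simulate(model)
        except SimulationError:
            scale *= 0.5
            continue
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()
        model.config_hash = digest
        return model
    raise GenerationError(
        f"could not stabilise random network seed={seed}, n_states={n_states}"
    )


# ---------------------------------------------------------------------------
# apoptosis model schema + loader
# ---------------------------------------------------------------------------

#: reactions any usable parameterisation must provide constants for
APOPTOSIS_KEY_REACTIONS = ("r1", "r5", "r9", "r14")


def load_apoptosis_model(
    params_table: Mapping[str, float],
    initial_conditions: Mapping[str, float] | None = None,
) -> OdeModel:
    """Build the Fas-induced apoptosis model from a rate-constant table.

    The shipped skeleton declares the reaction structure of the Jurkat
    T-cell cell-death network — receptor module (r1-r4), the direct type-I
    caspase-8 -> caspase-3 cleavage (r5), Bid/mitochondria module (r6-r13)
    and the mitochondria-dependent type-II activation of caspase-3 (r14) —
    but no rate constants: those must be transcribed from a published
    parameter table and passed in here.  Missing constants raise a
    :class:`ConfigError` listing every gap.  FasL enters as a stimulus
    through its initial condition (part of the augmented parameter vector).
    """
    config = load_fixture_config("apoptosis_skeleton")
    declared = list(config["parameters"])
    table = dict(params_table or {})
    unknown = sorted(set(table) - set(declared))
    if unknown:
        raise ConfigError("parameter table has unknown constant(s): " + ", ".join(unknown))
    merged = {k: table.get(k, config["parameters"][k]) for k in declared}
    gaps = sorted(k for k, v in merged.items() if v is None)
    if gaps:
        raise ConfigError(
            f"apoptosis model is missing {len(gaps)} rate constant(s): " + ", ".join(gaps)
        )
    config["parameters"] = merged
    if initial_conditions:
        ic = dict(config.get("initial_conditions") or {})
        bad = sorted(set(initial_conditions) - set(config["states"]))
        if bad:
            raise ConfigError("initial condition for unknown state(s): " + ", ".join(bad))
        ic.update({k: float(v) for k, v in initial_conditions.items()})
        config["initial_conditions"] = ic
    model = build_model(config)
    missing_rx = [r for r in APOPTOSIS_KEY_REACTIONS if r not in model.reaction_ids]
    if missing_rx:  # guards against a truncated skeleton edit
        raise ConfigError("skeleton lost key reaction(s): " + ", ".join(missing_rx))
    return model


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureEntry:
    name: str
    provenance: str  # closed_form | published_structure | supplement_required | synthetic
    builder: Callable
    description: str


CATALOG: dict[str, FixtureEntry] = {
    "linear_decay": FixtureEntry(
        "linear_decay",
        "closed_form",
        lambda: make_linear_model([-1.0], [1.0]),
        "dx/dt = -x with exact sensitivity formulas",
    ),
    "linear_2state": FixtureEntry(
        "linear_2state",
        "closed_form",
        lambda: make_linear_model([-1.0, -2.0], [1.0, 0.5]),
        "diag(-1,-2) linear system with exact sensitivity formulas",
    ),
    "random_mm": FixtureEntry(
        "random_mm",
        "synthetic",
        make_random_mm,
        "seeded random MM/mass-action conversion network",
    ),
    "simple_switch_network": FixtureEntry(
        "simple_switch_network",
        "published_structure",
        make_simple_network,
        "6-state switch: direct (r2) vs indirect (r3,r4) activation of x6; stand-in constants",
    ),
    "apoptosis_skeleton": FixtureEntry(
        "apoptosis_skeleton",
        "supplement_required",
        load_apoptosis_model,
        "Fas-induced apoptosis reaction schema; rate constants must be supplied",
    ),
}


def list_fixtures() -> list[tuple[str, str]]:
    """(name, provenance) pairs for every catalog entry."""
    return [(e.name, e.provenance) for e in CATALOG.values()]


def get_fixture(name: str, **kwargs):
    try:
        entry = CATALOG[name]
    except KeyError:
        raise ValidationError(f"unknown fixture {name!r}") from None
    return entry.builder(**kwargs)
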