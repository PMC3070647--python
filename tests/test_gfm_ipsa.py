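"""Green's function matrix, impulse sensitivities, pulse oracle, superposition."""

import numpy as np
import pandas as pd
import pytest

import ipsa as ip
from ipsa.errors import ValidationError


def test_gfm_identity_at_equal_times(linear2):
    model, _ = linear2
    traj = ip.simulate(model, np.linspace(0, 3, 31))
    taus = np.linspace(0, 2, 5)
    gfm = ip.greens_function(model, traj, taus, np.linspace(0, 3, 31))
    for tau in taus:
        assert np.array_equal(gfm.at(tau, tau), np.eye(model.n))


def test_gfm_matrix_exponential_closed_form(linear2):
    """diag(-1,-2): S^x(t,tau) = diag(e^{-(t-tau)}, e^{-2(t-tau)})."""
    model, analytic = linear2
    t = np.linspace(0, 3, 31)
    traj = ip.simulate(model, t)
    taus = np.array([0.0, 0.5, 1.3])
    gfm = ip.greens_function(model, traj, taus, t)
    for tau in taus:
        for tv in (1.5, 2.4, 3.0):
            got = gfm.at(tv, tau)
            assert got == pytest.approx(analytic["gfm"](tv, tau), abs=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gfm_semigroup_random_network(seed):
    """S^x(t,tau1) = S^x(t,tau2) S^x(tau2,tau1) for tau1 <= tau2 <= t."""
    model = ip.make_random_mm(seed=seed, n_states=3)
    t = np.linspace(0, 10, 21)
    traj = ip.simulate(model, t)
    tau1, tau2, tv = 1.0, 4.0, 8.5
    gfm = ip.greens_function(model, traj, np.array([tau1, tau2]), np.array([tau2, tv]))
    lhs = gfm.at(tv, tau1)
    rhs = gfm.at(tv, tau2) @ gfm.at(tau2, tau1)
    scale = max(np.max(np.abs(lhs)), 1.0)
    assert np.max(np.abs(lhs - rhs)) / scale < 1e-4


def test_gfm_tau_outside_trajectory_rejected(linear2):
    model, _ = linear2
    traj = ip.simulate(model, np.linspace(0, 3, 7))
    with pytest.raises(ValidationError):
        ip.greens_function(model, traj, np.array([-1.0]), np.array([2.0]))
    with pytest.raises(ValidationError):
        ip.greens_function(model, traj, np.array([0.0]), np.array([5.0]))


# --------------------------------------------------------------------- ipsa

def test_ipsa_equals_jac_p_at_perturbation_time(switch_model, switch_traj):
    taus = np.array([0.0, 3.0, 7.0])
    gfm = ip.greens_function(switch_model, switch_traj, taus, taus)
    field = ip.ipsa(switch_model, switch_traj, gfm)
    x_of = switch_traj.interpolant()
    for ik, tau in enumerate(taus):
        it = ik  # same grid
        got = field.raw[it, ik, :, : switch_model.m]
        expected = switch_model.jac_p(x_of(tau))
        assert got == pytest.approx(expected, abs=1e-8)


def test_ipsa_decay_closed_form(decay_model):
    """dx/dt = -kx: iS(t,tau) = e^{-(t-tau)}(-x(tau)) = -e^{-t}, any tau."""
    t = np.linspace(0, 2, 21)
    traj = ip.simulate(decay_model, t)
    taus = np.array([0.0, 0.5, 1.0])
    gfm = ip.greens_function(decay_model, traj, taus, t)
    field = ip.ipsa(decay_model, traj, gfm)
    it = 10  # t = 1
    for ik in range(3):
        assert field.raw[it, ik, 0, 0] == pytest.approx(-np.exp(-1), abs=1e-5)


def test_ipsa_linear2_matches_analytic(linear2):
    model, analytic = linear2
    t = np.linspace(0, 3, 31)
    traj = ip.simulate(model, t)
    taus = np.array([0.0, 0.8, 1.7])
    gfm = ip.greens_function(model, traj, taus, t)
    field = ip.ipsa(model, traj, gfm)
    for ik, tau in enumerate(taus):
        for it, tv in enumerate(t):
            if tv < tau:
                assert np.all(np.isnan(field.raw[it, ik]))
                continue
            assert field.raw[it, ik, :, : model.m] == pytest.approx(
                analytic["ipsa"](tv, tau), abs=1e-5
            )


def test_ipsa_initial_condition_columns_only_at_t0(linear2):
    model, analytic = linear2
    t = np.linspace(0, 3, 7)
    traj = ip.simulate(model, t)
    taus = np.array([0.0, 1.0])
    gfm = ip.greens_function(model, traj, taus, t)
    field = ip.ipsa(model, traj, gfm)
    m = model.m
    # at tau = t0 the x0 columns equal the GFM columns
    assert field.raw[-1, 0, :, m:] == pytest.approx(analytic["gfm"](3.0, 0.0), abs=1e-6)
    # at later tau they are undefined
    assert np.all(np.isnan(field.raw[-1, 1, :, m:]))


# -------------------------------------------------------------- pulse oracle

def test_pulse_oracle_decay_closed_form(decay_model):
    t = np.linspace(0, 2, 21)
    oracle = ip.ipsa_pulse_oracle(decay_model, tau=0.5, delta_tau=1e-3,
                                  delta_p_rel=1e-4, t_grid=t)
    sel = t >= 0.5 + 1e-3
    assert oracle.raw[sel, 0, 0, 0] == pytest.approx(-np.exp(-t[sel]), abs=1e-3)


def test_pulse_oracle_zero_height_is_zero(decay_model):
    t = np.linspace(0, 2, 11)
    oracle = ip.ipsa_pulse_oracle(decay_model, tau=0.5, delta_tau=1e-2,
                                  delta_p_rel=0.0, t_grid=t)
    sel = t >= 0.5
    assert np.array_equal(
        oracle.raw[sel, 0, :, : decay_model.m],
        np.zeros((sel.sum(), 1, 1)),
    )


def test_pulse_oracle_first_order_convergence(switch_model, switch_traj):
    """Halving delta_tau roughly halves the discrepancy vs the impulse limit.

    Needs a model whose impulse response varies with the perturbation time
    (for decoupled linear decay iS is tau-independent and the pulse-width
    error vanishes identically).
    """
    tau = 4.0
    t = switch_traj.times
    gfm = ip.greens_function(switch_model, switch_traj, np.array([tau]), t)
    exact = ip.ipsa(switch_model, switch_traj, gfm).raw[-1, 0, :, : switch_model.m]
    widths = (4e-1, 2e-1, 1e-1)
    errs = []
    for dtau in widths:
        oracle = ip.ipsa_pulse_oracle(switch_model, tau=tau, delta_tau=dtau,
                                      delta_p_rel=1e-4, t_grid=t)
        errs.append(np.max(np.abs(oracle.raw[-1, 0, :, : switch_model.m] - exact)))
    order = np.polyfit(np.log(widths), np.log(errs), 1)[0]
    assert 0.7 < order < 1.5


def test_pulse_oracle_matches_ipsa_switch_network(switch_model, switch_traj):
    tau = 4.0
    t = switch_traj.times
    gfm = ip.greens_function(switch_model, switch_traj, np.array([tau]), t)
    field = ip.ipsa(switch_model, switch_traj, gfm)
    oracle = ip.ipsa_pulse_oracle(switch_model, tau=tau, delta_tau=1e-3,
                                  delta_p_rel=1e-4, t_grid=t)
    sel = t >= tau + 1e-3
    a = field.raw[sel, 0, :, : switch_model.m]
    b = oracle.raw[sel, 0, :, : switch_model.m]
    scale = np.max(np.abs(a))
    assert np.max(np.abs(a - b)) / scale < 1e-2


def test_pulse_oracle_validates_inputs(decay_model):
    t = np.linspace(0, 2, 11)
    with pytest.raises(ValidationError):
        ip.ipsa_pulse_oracle(decay_model, tau=0.5, delta_tau=1e-3, delta_p_rel=0.5, t_grid=t)
    with pytest.raises(ValidationError):
        ip.ipsa_pulse_oracle(decay_model, tau=1.9999, delta_tau=1e-2, delta_p_rel=1e-4, t_grid=t)


# ---------------------------------------------------------------- normalize

def test_normalize_ipsa_decay_is_minus_one(decay_model):
    """(k/x(t)) iS = (1/e^{-t})(-e^{-t}) = -1 for every t >= tau."""
    t = np.linspace(0, 2, 21)
    traj = ip.simulate(decay_model, t)
    taus = np.array([0.0, 0.7])
    gfm = ip.greens_function(decay_model, traj, taus, t)
    field = ip.normalize_ipsa(ip.ipsa(decay_model, traj, gfm), traj)
    for ik, tau in enumerate(taus):
        sel = t >= tau
        assert field.normalized[sel, ik, 0, 0] == pytest.approx(-1.0, abs=1e-5)


def test_normalize_ipsa_indirect_dominates_at_switch(switch_model, switch_traj, switch_time):
    """Observed at t = 15, impulses near the switch matter most through r4."""
    taus = np.linspace(0, 15, 61)
    gfm = ip.greens_function(switch_model, switch_traj, taus, np.array([15.0]))
    field = ip.normalize_ipsa(ip.ipsa(switch_model, switch_traj, gfm), switch_traj)
    i6 = switch_model.state_index("x6")
    j2 = switch_model.param_names.index("kv2")
    j4 = switch_model.param_names.index("kv4")
    ik = int(np.argmin(np.abs(taus - switch_time)))
    vals = np.abs(field.normalized[0, ik, i6, : switch_model.m])
    assert vals[j4] > vals[j2]


# ------------------------------------------------------------- superposition

def test_superposition_decay_exact(decay_model):
    """∫_0^t (-e^{-t}) dsigma = -t e^{-t} = S(t,0): quadrature error only."""
    traj = ip.simulate(decay_model, np.linspace(0, 2, 21))
    residual = ip.psa_ipsa_consistency(decay_model, traj, tau=0.0, n_sigma=101)
    assert residual < 1e-6


def test_superposition_switch_network(switch_model, switch_traj):
    residual = ip.psa_ipsa_consistency(switch_model, switch_traj, tau=0.0, n_sigma=201)
    assert residual < 1e-2


def test_superposition_residual_shrinks_with_refinement(switch_model, switch_traj):
    coarse = ip.psa_ipsa_consistency(switch_model, switch_traj, tau=0.0, n_sigma=26)
    fine = ip.psa_ipsa_consistency(switch_model, switch_traj, tau=0.0, n_sigma=101)
    assert fine < coarse


# ------------------------------------------------------------------ heatmap

def test_heatmap_lower_triangle_and_roundtrip(decay_model, tmp_path):
    t = np.linspace(0, 2, 3)
    traj = ip.simulate(decay_model, t)
    gfm = ip.greens_function(decay_model, traj, t, t)
    field = ip.ipsa(decay_model, traj, gfm)
    out = tmp_path / "hm.csv"
    frame = ip.export_heatmap(field, 0, "k", out)
    # upper triangle (t < tau) is NA, diagonal+lower defined
    M = frame.to_numpy()
    assert np.all(np.isnan(M[np.triu_indices(3, 1)]))
    assert np.all(np.isfinite(M[np.tril_indices(3)]))
    # rows follow -e^{-t}, independent of tau
    for it, tv in enumerate(t):
        for ik in range(it + 1):
            assert M[it, ik] == pytest.approx(-np.exp(-tv), abs=1e-5)
    back = pd.read_csv(out, index_col=0, float_precision="round_trip")
    assert np.array_equal(back.to_numpy(), M, equal_nan=True)  # bit-exact round trip


def test_heatmap_unknown_parameter(decay_model):
    t = np.linspace(0, 2, 3)
    traj = ip.simulate(decay_model, t)
    gfm = ip.greens_function(decay_model, traj, t, t)
    field = ip.ipsa(decay_model, traj, gfm)
    with pytest.raises(ValidationError, match="zz"):
        ip.export_heatmap(field, 0, "zz", "unused.csv")
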