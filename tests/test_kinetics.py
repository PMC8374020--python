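"""Antibody model, linear models, and generated-daughter transport."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from actidose.fixtures import default_ab_params
from actidose.kinetics import (
    KineticsError,
    LinearModel,
    binding_rate,
    default_grid,
    distribute_generated,
    simulate_ab,
    simulate_daughter_on_antibody,
    simulate_linear,
)

LN2 = np.log(2.0)
LAM_AC225 = LN2 / 238.08
GRID = default_grid(3000.0, 300)


# ---------------------------------------------------------------- binding


def test_binding_rate_arithmetic():
    # 14.95 nmol in 3.8 L = 3.934 nM; times 0.5 /(nM h) = 1.967 /h
    assert binding_rate(14.95, 0.5, 3.8) == pytest.approx(0.5 * 14.95 / 3.8, rel=1e-12)
    assert binding_rate(0.0, 0.5, 3.8) == 0.0
    assert binding_rate(2 * 14.95, 0.5, 3.8) == pytest.approx(
        2 * binding_rate(14.95, 0.5, 3.8)
    )
    with pytest.raises(KineticsError):
        binding_rate(1.0, 0.5, 0.0)


# ---------------------------------------------------------------- antibody


def test_ab_initial_condition():
    ab = simulate_ab(default_ab_params(LAM_AC225), GRID)
    assert ab.curves["vascular"][0] == pytest.approx(1.0, abs=1e-12)
    assert ab.curves["bound"][0] == 0.0
    assert ab.curves["internalized"][0] == 0.0


def test_ab_no_binding_single_exponential():
    """With k_on = 0 the vascular curve is exp(-(ln2/Tc + lambda) t)."""
    p = default_ab_params(LAM_AC225).replace(k_on=0.0)
    ab = simulate_ab(p, GRID)
    expected = np.exp(-(LN2 / 40.0 + LAM_AC225) * GRID)
    mask = expected > 1e-8
    assert np.max(np.abs(ab.curves["vascular"][mask] / expected[mask] - 1)) < 1e-6
    # value quoted for t = 40 h
    i = np.argmin(np.abs(GRID - 40.0))
    assert ab.curves["vascular"][i] == pytest.approx(
        np.exp(-(LN2 / 40.0 + LAM_AC225) * GRID[i]), rel=1e-8
    )


def test_ab_label_conservation():
    ab = simulate_ab(default_ab_params(LAM_AC225), GRID)
    total = ab.curves.total(
        ["vascular", "bound", "internalized", "excreted", "decayed"]
    )
    assert np.max(np.abs(total - 1.0)) < 1e-6


def test_ab_antigen_conservation():
    p = default_ab_params(LAM_AC225)
    ab = simulate_ab(p, GRID)
    # biological amounts: undo the label decay factor
    damp = np.exp(-p.lambda_phys * GRID)
    occupied = (ab.curves["bound"] + ab.curves["internalized"]) * p.ab0 / damp
    assert np.all(occupied <= p.ag0 * (1 + 1e-9))
    assert np.all(ab.ag_free(GRID) >= -1e-9)


def test_ab_matches_brute_force_ode():
    """Independent oracle: the three-compartment equations written out
    explicitly and integrated with a different solver."""
    p = default_ab_params(LAM_AC225)
    kc, ki, kk = LN2 / p.t_clear, LN2 / p.t_int, LN2 / p.t_cat

    def rhs(_t, y):
        b1, b2, b3 = y
        k21 = p.k_on * max(p.ag0 - b2 - b3, 0.0) / p.vd
        return [
            -k21 * b1 + p.k_off * b2 - kc * b1,
            k21 * b1 - (p.k_off + ki) * b2,
            ki * b2 - kk * b3,
        ]

    sol = solve_ivp(rhs, (0, GRID[-1]), [p.ab0, 0, 0], t_eval=GRID,
                    method="Radau", rtol=1e-10, atol=1e-13)
    ab = simulate_ab(p, GRID)
    damp = np.exp(-p.lambda_phys * GRID)
    for i, name in enumerate(("vascular", "bound", "internalized")):
        ref = sol.y[i] / p.ab0 * damp
        mask = ref > 1e-8 * np.max(ref)
        assert np.max(np.abs(ab.curves[name][mask] / ref[mask] - 1)) < 1e-6, name


def test_ab_solver_convergence():
    """Tightening tolerances by 100x does not move the curves (>1e-6)."""
    p = default_ab_params(LAM_AC225)
    a = simulate_ab(p, GRID, rtol=1e-8, atol=1e-12)
    b = simulate_ab(p, GRID, rtol=1e-10, atol=1e-14)
    for name in ("vascular", "bound", "internalized"):
        scale = np.max(np.abs(b.curves[name]))
        assert np.max(np.abs(a.curves[name] - b.curves[name])) < 1e-6 * scale


def test_ab_rejects_bad_inputs():
    with pytest.raises(KineticsError):
        default_ab_params().replace(ab0=-1.0)
    with pytest.raises(KineticsError):
        simulate_ab(default_ab_params(), np.array([1.0, 2.0]))


# ---------------------------------------------------------------- linear


def one_compartment(rate=0.05):
    return LinearModel(
        model_id="one",
        compartments=["c"],
        transfer=[("c", "out", rate)],
        source_compartment="c",
        region_map={"c": [("Liver", 1.0)]},
    )


def test_linear_bolus_closed_form():
    m = one_compartment(0.05)
    lam = 0.01
    grid = np.linspace(0.0, 100.0, 200)
    pk = simulate_linear(m, ("bolus", 1.0), grid, lambda_phys=lam)
    expected = np.exp(-(0.05 + lam) * grid)
    assert np.max(np.abs(pk["c"] - expected)) < 1e-8


def test_linear_zero_input():
    m = one_compartment()
    grid = np.linspace(0.0, 10.0, 20)
    pk = simulate_linear(m, ("production", np.zeros_like(grid)), grid)
    assert np.all(pk["c"] == 0.0)


def test_linear_two_compartment_vs_brute_force():
    m = LinearModel(
        model_id="catenary",
        compartments=["a", "b"],
        transfer=[("a", "b", 0.3), ("b", "out", 0.07), ("b", "a", 0.02)],
        source_compartment="a",
        region_map={},
    )
    lam = 0.005
    grid = np.linspace(0.0, 80.0, 120)

    def rhs(_t, y):
        a, b = y
        return [-0.3 * a + 0.02 * b - lam * a, 0.3 * a - (0.07 + 0.02) * b - lam * b]

    sol = solve_ivp(rhs, (0, grid[-1]), [1.0, 0.0], t_eval=grid, method="DOP853",
                    rtol=1e-12, atol=1e-15)
    pk = simulate_linear(m, ("bolus", 1.0), grid, lambda_phys=lam)
    for i, name in enumerate(("a", "b")):
        ref = sol.y[i]
        mask = ref > 1e-10
        assert np.max(np.abs(pk[name][mask] / ref[mask] - 1)) < 1e-6


def test_linear_conservation():
    m = LinearModel(
        model_id="m",
        compartments=["a", "b"],
        transfer=[("a", "b", 0.2), ("a", "urine", 0.05), ("b", "faeces", 0.01)],
        source_compartment="a",
        region_map={},
    )
    grid = np.linspace(0.0, 200.0, 100)
    pk = simulate_linear(m, ("bolus", 1.0), grid, lambda_phys=0.004)
    total = pk.total(["a", "b", "urine", "faeces", "decayed"])
    assert np.max(np.abs(total - 1.0)) < 1e-6


def test_linear_rejects_negative_coefficient():
    with pytest.raises(KineticsError):
        LinearModel(
            model_id="bad",
            compartments=["a"],
            transfer=[("a", "out", -0.1)],
            source_compartment="a",
        )


# ------------------------------------------------------- generated atoms


def test_distribute_generated_constant_production_closed_form():
    """Constant production P into one compartment with total removal r:
    content(T) = (P/r)(1 - exp(-rT))."""
    m = one_compartment(0.05)
    lam = 0.02
    r = 0.05 + lam
    grid = np.linspace(0.0, 60.0, 400)
    production = np.full_like(grid, 0.3)
    pk = distribute_generated(production, m, grid, lambda_phys=lam)
    expected = (0.3 / r) * (1.0 - np.exp(-r * grid))
    mask = expected > 1e-12
    assert np.max(np.abs(pk["c"][mask] / expected[mask] - 1)) < 1e-6


def test_distribute_generated_impulse_matches_bolus():
    """A production spike concentrated at t=0 reproduces the bolus response."""
    m = one_compartment(0.05)
    width = 1e-3
    grid = np.unique(np.concatenate([[0.0, width], np.geomspace(width, 50.0, 200)]))
    production = np.where(grid <= width, 1.0 / width, 0.0)
    production = production / np.trapezoid(production, grid)  # unit integral
    pk = distribute_generated(production, m, grid, lambda_phys=0.0)
    bolus = simulate_linear(m, ("bolus", 1.0), grid, lambda_phys=0.0)
    late = grid > 1.0
    assert np.max(np.abs(pk["c"][late] / bolus["c"][late] - 1)) < 2e-3


def test_distribute_generated_linearity(rng):
    m = one_compartment(0.1)
    grid = np.linspace(0.0, 30.0, 80)
    pa = rng.uniform(0.0, 1.0, grid.shape)
    pb = rng.uniform(0.0, 1.0, grid.shape)
    kw = dict(rtol=1e-12, atol=1e-16)
    ca = distribute_generated(pa, m, grid, **kw)["c"]
    cb = distribute_generated(pb, m, grid, **kw)["c"]
    cab = distribute_generated(pa + pb, m, grid, **kw)["c"]
    scale = np.max(np.abs(cab))
    assert np.max(np.abs(cab - (ca + cb))) < 1e-9 * scale


def test_distribute_generated_rejects_mismatched_grid():
    m = one_compartment()
    with pytest.raises(KineticsError):
        distribute_generated(np.zeros(5), m, np.linspace(0, 1, 6))


# ------------------------------------------------- bound daughter transport


def test_bound_daughter_vs_brute_force_coupled_ode():
    """Oracle: the full parent+daughter coupled label system integrated
    directly (parent label atoms and daughter atoms in one ODE)."""
    p = default_ab_params(LN2 / 238.08)  # parent label decay
    lam_p = p.lambda_phys
    lam_d = LN2 / (18.68 * 24.0)
    frac = 0.99 * 0.7
    kc, ki, kk = LN2 / p.t_clear, LN2 / p.t_int, LN2 / p.t_cat
    grid = default_grid(3000.0, 250)

    def rhs(_t, y):
        b1, b2, b3, n1, n2, n3, m1, m2, m3 = y
        k21 = p.k_on * max(p.ag0 - b2 - b3, 0.0) / p.vd
        flows = lambda x1, x2, x3: (
            -k21 * x1 + p.k_off * x2 - kc * x1,
            k21 * x1 - (p.k_off + ki) * x2,
            ki * x2 - kk * x3,
        )
        db = flows(b1, b2, b3)
        dn = flows(n1, n2, n3)
        dm = flows(m1, m2, m3)
        return [
            *db,
            dn[0] - lam_p * n1,
            dn[1] - lam_p * n2,
            dn[2] - lam_p * n3,
            dm[0] - lam_d * m1 + frac * lam_p * n1,
            dm[1] - lam_d * m2 + frac * lam_p * n2,
            dm[2] - lam_d * m3 + frac * lam_p * n3,
        ]

    y0 = [p.ab0, 0, 0, 1.0 / lam_p, 0, 0, 0, 0, 0]  # parent: 1 MBq at t=0
    sol = solve_ivp(rhs, (0, grid[-1]), y0, t_eval=grid, method="LSODA",
                    rtol=1e-11, atol=1e-14)
    ab = simulate_ab(p, grid)
    dk = simulate_daughter_on_antibody(ab, frac, lam_d, grid)
    peak = {}
    for i, name in enumerate(("vascular", "bound", "internalized")):
        ref = lam_d * sol.y[6 + i]
        peak[name] = np.max(ref)
        assert np.max(np.abs(dk[name] - ref)) < 1e-6 * peak[name], name


def test_bound_daughter_conservation_and_linearity():
    p = default_ab_params(LN2 / 238.08)
    lam_d = LN2 / 448.32
    grid = default_grid(2000.0, 150)
    ab = simulate_ab(p, grid)
    a = simulate_daughter_on_antibody(ab, 0.3, lam_d, grid)
    b = simulate_daughter_on_antibody(ab, 0.6, lam_d, grid)
    atoms = a.total(["vascular", "bound", "internalized"]) / lam_d
    balance = atoms + a["atoms_excreted"] + a["atoms_decayed"] - a["atoms_produced"]
    assert np.max(np.abs(balance)) < 1e-9 * max(a["atoms_produced"][-1], 1.0)
    for name in ("vascular", "bound", "internalized"):
        assert np.allclose(b[name], 2.0 * a[name], rtol=1e-7, atol=1e-16)
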