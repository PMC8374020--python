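"""Compartmental pharmacokinetic simulators.

Three simulators cover the kinetic machinery of the pipeline:

:func:`simulate_ab`
    the nonlinear antibody-antigen model: free antibody in a distribution
    volume binds antigen-positive cells by saturable mass-action binding,
    dissociates, internalizes, and is cleared by vascular clearance and
    intracellular catabolism.  The biology (antibody amounts in nmol) is
    independent of the radiolabel; label activity curves are the biological
    solution damped by the physical decay of the labeling nuclide.

:func:`simulate_linear` / :func:`distribute_generated`
    generic linear first-order biokinetic models (e.g. the free-thorium and
    free-radium systemic models), driven either by a bolus or by a
    production-rate time course (atoms generated inside the body are
    distributed as they are created; models are not coupled to each other).

:func:`simulate_daughter_on_antibody`
    generation-aware transport of a radioactive daughter that remains
    attached to the antibody: a linear, time-varying label system driven by
    the parent label's decay, following the antibody model's instantaneous
    flow rates.

All rates are per hour, amounts in nmol (biology) or MBq-equivalents
(label), activities as fraction of injected activity (FIA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

LN2 = float(np.log(2.0))

#: smooth floor width for the free-antigen clip, nmol
_AG_EPS = 1e-9

_SOLVER = dict(method="LSODA", rtol=1e-10, atol=1e-14)


class KineticsError(ValueError):
    pass


def default_grid(t_max: float = 5000.0, n: int = 400) -> np.ndarray:
    """Output grid 0..t_max hours, logarithmically dense at early times."""
    return np.concatenate([[0.0], np.geomspace(1e-2, t_max, n - 1)])


# ---------------------------------------------------------------------------
# antibody-antigen model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbModelParams:
    """Parameters of the antibody-antigen model.

    ``k_on`` is the association rate in 1/(nM h); ``t_clear``, ``t_int`` and
    ``t_cat`` are the half-times (h) of vascular clearance, internalization
    and intracellular catabolism.  ``lambda_phys`` is the physical decay
    constant (1/h) of the labeling nuclide.
    """

    ag0: float  # antigen amount, nmol
    ab0: float  # administered antibody, nmol
    vd: float  # distribution volume, L
    k_on: float  # association rate, 1/(nM h)
    k_off: float  # dissociation rate, 1/h
    t_clear: float  # vascular clearance half-time, h
    t_int: float  # internalization half-time, h
    t_cat: float  # catabolism half-time, h
    f_l1: float  # liver ECF share of the vascular compartment
    f_s1: float  # spleen ECF share of the vascular compartment
    f_l2: float  # liver share of antigen-positive cells
    f_s2: float  # spleen share of antigen-positive cells
    v_rmecf: float  # red-marrow ECF volume, L
    lambda_phys: float = 0.0  # physical decay constant, 1/h

    def __post_init__(self) -> None:
        for name in ("ag0", "ab0", "vd", "t_clear", "t_int", "t_cat", "v_rmecf"):
            if getattr(self, name) <= 0:
                raise KineticsError(f"{name} must be positive")
        for name in ("k_on", "k_off", "lambda_phys"):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be nonnegative")
        for name in ("f_l1", "f_s1", "f_l2", "f_s2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise KineticsError(f"{name} must be in [0, 1]")
        if self.f_l1 + self.f_s1 > 1.0 or self.f_l2 + self.f_s2 > 1.0:
            raise KineticsError("fraction pairs must sum to <= 1")
        if self.v_rmecf > self.vd:
            raise KineticsError("v_rmecf cannot exceed the distribution volume")

    def replace(self, **kw) -> "AbModelParams":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class PKCurves:
    """Per-compartment time courses on a common grid.

    ``curves`` values are fractions of injected (or generated) activity for
    activity curves; bookkeeping entries (``excreted_*``, ``decayed``) carry
    the cumulative label fraction routed to each sink.
    """

    times: np.ndarray
    curves: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.curves[key]

    def total(self, keys: Sequence[str] | None = None) -> np.ndarray:
        keys = list(self.curves) if keys is None else list(keys)
        return np.sum([self.curves[k] for k in keys], axis=0)


def binding_rate(free_antigen_nmol: float, k_on: float, vd: float):
    """Instantaneous association rate k(2,1) = k_on * [free antigen], 1/h."""
    if vd <= 0:
        raise KineticsError("distribution volume must be positive")
    return k_on * (np.asarray(free_antigen_nmol) / vd)


def _smooth_floor(x, eps: float = _AG_EPS):
    """Smooth max(x, 0); exact to ~eps near the origin."""
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


@dataclass
class AbSolution:
    """Antibody simulation result: label curves plus the biological solution
    needed to transport daughter labels along the same flows."""

    params: AbModelParams
    curves: PKCurves
    _bio_dense: Callable  # dense biology solution t -> (b1, b2, b3)

    def ag_free(self, t):
        b = self._bio_dense(np.atleast_1d(t))
        return _smooth_floor(self.params.ag0 - b[1] - b[2])

    def k21(self, t):
        return binding_rate(self.ag_free(t), self.params.k_on, self.params.vd)

    def label_activity(self, compartment: str) -> np.ndarray:
        return self.curves[compartment]


_AB_COMPARTMENTS = ("vascular", "bound", "internalized")


def simulate_ab(
    params: AbModelParams,
    grid: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> AbSolution:
    """Solve the antibody-antigen model and return label FIA curves.

    States: compartment 1 (free antibody in the distribution volume),
    compartment 2 (antigen-bound), compartment 3 (internalized), plus
    cumulative sinks.  The label activity in compartment i is the
    biological content scaled by exp(-lambda_phys t); sink partitioning of
    the label is integrated alongside so that

        sum(compartments) + excreted + decayed = 1

    holds to solver tolerance at every grid point.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise KineticsError("grid must start at t = 0")
    p = params
    kc = LN2 / p.t_clear
    ki = LN2 / p.t_int
    kk = LN2 / p.t_cat
    lam = p.lambda_phys

    def rhs(t, y):
        b1, b2, b3 = y[:3]
        ag = _smooth_floor(p.ag0 - b2 - b3)
        k21 = p.k_on * ag / p.vd
        db1 = -k21 * b1 + p.k_off * b2 - kc * b1
        db2 = k21 * b1 - (p.k_off + ki) * b2
        db3 = ki * b2 - kk * b3
        damp = np.exp(-lam * t) / p.ab0
        d_exc = (kc * b1 + kk * b3) * damp
        d_dec = lam * (b1 + b2 + b3) * damp
        return (db1, db2, db3, d_exc, d_dec)

    y0 = (p.ab0, 0.0, 0.0, 0.0, 0.0)
    sol = solve_ivp(
        rhs,
        (0.0, grid[-1]),
        y0,
        t_eval=grid,
        dense_output=True,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - solver diagnostics
        raise KineticsError(f"antibody model solver failed: {sol.message}")
    damp = np.exp(-lam * grid)
    curves = {
        name: sol.y[i] / p.ab0 * damp for i, name in enumerate(_AB_COMPARTMENTS)
    }
    curves["excreted"] = sol.y[3]
    curves["decayed"] = sol.y[4]
    pk = PKCurves(times=grid, curves=curves, meta={"lambda_phys": lam})
    return AbSolution(params=p, curves=pk, _bio_dense=lambda t: sol.sol(t))


# ---------------------------------------------------------------------------
# linear first-order models
# ---------------------------------------------------------------------------


@dataclass
class LinearModel:
    """A linear biokinetic model: named compartments, first-order transfer
    coefficients (1/h) and a region map used for TIAC apportionment.

    Transfer destinations that are not listed compartments become absorbing
    sinks (excreta).  ``region_map`` maps each compartment to one or more
    ``(source region, weight)`` pairs; the special regions ``@blood`` and
    ``@soft_tissue_mass`` are resolved against the phantom at apportionment
    time.
    """

    model_id: str
    compartments: list[str]
    transfer: list[tuple[str, str, float]]
    source_compartment: str
    region_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_compartment not in self.compartments:
            raise KineticsError("source compartment not among compartments")
        for src, dst, rate in self.transfer:
            if src not in self.compartments:
                raise KineticsError(f"transfer source {src!r} not a compartment")
            if rate < 0:
                raise KineticsError(
                    f"negative transfer coefficient {src}->{dst}: {rate}"
                )

    @property
    def sinks(self) -> list[str]:
        return sorted({dst for _, dst, _ in self.transfer if dst not in self.compartments})

    def matrix(self) -> np.ndarray:
        """Generator over compartments + sinks; columns sum to zero."""
        names = self.compartments + self.sinks
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        T = np.zeros((n, n))
        for src, dst, rate in self.transfer:
            i, j = idx[src], idx[dst]
            T[j, i] += rate
            T[i, i] -= rate
        return T


def simulate_linear(
    model: LinearModel,
    input_spec: tuple[str, object],
    grid: np.ndarray,
    lambda_phys: float = 0.0,
    rtol: float = 1e-10,
    atol: float = 1e-14,
) -> PKCurves:
    """Solve dx/dt = T x - lambda x + u(t) for a linear model.

    ``input_spec`` is ``("bolus", amount)`` (amount enters the source
    compartment at t=0) or ``("production", rate_on_grid)`` (a nonnegative
    production-rate time course, linearly interpolated between grid points).
    Returned curves are compartment contents normalized to the total input,
    plus cumulative sink and ``decayed`` bookkeeping curves.
    """
    grid = np.asarray(grid, dtype=float)
    kind, value = input_spec
    names = model.compartments + model.sinks
    T = model.matrix()
    n = len(names)
    src = model.compartments.index(model.source_compartment)
    ncomp = len(model.compartments)

    if kind == "bolus":
        amount = float(value)
        if amount < 0:
            raise KineticsError("bolus must be nonnegative")
        u = None
        total_in = amount
    elif kind == "production":
        rate = np.asarray(value, dtype=float)
        if rate.shape != grid.shape:
            raise KineticsError("production-rate grid mismatch")
        if np.any(rate < 0):
            raise KineticsError("production rate must be nonnegative")
        u = lambda t: np.interp(t, grid, rate)
        total_in = float(np.trapezoid(rate, grid))
        amount = 0.0
    else:
        raise KineticsError(f"unknown input kind {kind!r}")

    lam_vec = np.zeros(n)
    lam_vec[:ncomp] = lambda_phys  # sinks keep what they received

    def rhs(t, y):
        x = y[:n]
        dx = T @ x - lam_vec * x
        if u is not None:
            dx[src] += u(t)
        d_dec = lambda_phys * x[:ncomp].sum()
        return np.concatenate([dx, [d_dec]])

    y0 = np.zeros(n + 1)
    y0[src] = amount
    sol = solve_ivp(
        rhs, (0.0, grid[-1]), y0, t_eval=grid, method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success:  # pragma: no cover
        raise KineticsError(f"linear model solver failed: {sol.message}")
    norm = total_in if total_in > 0 else 1.0
    curves = {name: sol.y[i] / norm for i, name in enumerate(names)}
    curves["decayed"] = sol.y[n] / norm
    return PKCurves(
        times=grid,
        curves=curves,
        meta={
            "model_id": model.model_id,
            "lambda_phys": lambda_phys,
            "total_input": total_in,
            "compartments": list(model.compartments),
            "sinks": model.sinks,
        },
    )


def distribute_generated(
    production_rate: np.ndarray,
    model: LinearModel,
    grid: np.ndarray,
    lambda_phys: float = 0.0,
    **kw,
) -> PKCurves:
    """Distribute internally generated atoms through a linear model.

    ``production_rate`` is the atom generation rate on the grid in
    MBq-equivalents (the decay rate of the parent species feeding this
    nuclide).  Equivalent to the convolution of the rate with the model's
    bolus impulse response.  Curves are *not* normalized: compartment
    entries are atom contents in MBq*h equivalents; multiply by the decay
    constant for activities (see :func:`activity_curves`).
    """
    grid = np.asarray(grid, dtype=float)
    production_rate = np.asarray(production_rate, dtype=float)
    if production_rate.shape != grid.shape:
        raise KineticsError("production-rate grid mismatch")
    pk = simulate_linear(
        model, ("production", production_rate), grid, lambda_phys=lambda_phys, **kw
    )
    total_in = pk.meta["total_input"]
    # undo input normalization: keep absolute atom contents
    for k in pk.curves:
        pk.curves[k] = pk.curves[k] * (total_in if total_in > 0 else 1.0)
    pk.meta["normalized"] = False
    return pk


def activity_curves(pk: PKCurves, lambda_phys: float) -> dict[str, np.ndarray]:
    """Activities (MBq) of the modeled nuclide in each true compartment."""
    comps = pk.meta.get("compartments", list(pk.curves))
    return {c: lambda_phys * pk.curves[c] for c in comps}


# ---------------------------------------------------------------------------
# antibody-bound daughter transport
# ---------------------------------------------------------------------------


def simulate_daughter_on_antibody(
    ab: AbSolution,
    production_fraction: float,
    lambda_daughter: float,
    grid: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-14,
) -> PKCurves:
    """Kinetics of a daughter nuclide generated on, and retained by, the
    circulating antibody.

    Daughter atoms appear in each antibody compartment at a rate
    ``production_fraction`` times the parent label's decay rate there (per
    MBq of parent administered) and subsequently follow the antibody
    model's instantaneous flows (time-varying because antigen binding is
    saturable).  Returns daughter *activity* curves per compartment plus
    atom bookkeeping sinks; everything scales linearly with
    ``production_fraction``.
    """
    if grid is None:
        grid = ab.curves.times
    grid = np.asarray(grid, dtype=float)
    p = ab.params
    kc = LN2 / p.t_clear
    ki = LN2 / p.t_int
    kk = LN2 / p.t_cat
    lam_p = p.lambda_phys
    lam_d = lambda_daughter
    bio = ab._bio_dense
    ab0 = p.ab0

    def rhs(t, y):
        m1, m2, m3 = y[:3]
        b = bio(np.atleast_1d(t))
        b1, b2, b3 = float(b[0, 0]), float(b[1, 0]), float(b[2, 0])
        ag = float(_smooth_floor(p.ag0 - b2 - b3))
        k21 = p.k_on * ag / p.vd
        damp = np.exp(-lam_p * t)
        # parent label activities (FIA per MBq parent administered)
        a1, a2, a3 = (b1 * damp / ab0, b2 * damp / ab0, b3 * damp / ab0)
        pr = production_fraction
        dm1 = -(k21 + kc + lam_d) * m1 + p.k_off * m2 + pr * a1
        dm2 = k21 * m1 - (p.k_off + ki + lam_d) * m2 + pr * a2
        dm3 = ki * m2 - (kk + lam_d) * m3 + pr * a3
        d_exc = kc * m1 + kk * m3
        d_dec = lam_d * (m1 + m2 + m3)
        d_prod = pr * (a1 + a2 + a3)
        return (dm1, dm2, dm3, d_exc, d_dec, d_prod)

    sol = solve_ivp(
        rhs,
        (0.0, grid[-1]),
        np.zeros(6),
        t_eval=grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover
        raise KineticsError(f"bound-daughter solver failed: {sol.message}")
    curves = {
        name: lam_d * sol.y[i] for i, name in enumerate(_AB_COMPARTMENTS)
    }
    curves["atoms_excreted"] = sol.y[3]
    curves["atoms_decayed"] = sol.y[4]
    curves["atoms_produced"] = sol.y[5]
    return PKCurves(
        times=grid,
        curves=curves,
        meta={
            "lambda_phys": lam_d,
            "production_fraction": production_fraction,
            "compartments": list(_AB_COMPARTMENTS),
        },
    )
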