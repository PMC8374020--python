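"""Radionuclides, branched decay chains and chain kinetics.

A :class:`DecayChain` bundles the nuclides of a decay series (half-lives,
yield-weighted mean emission energies per decay) with its branching ratios
and a *fate policy* per nuclide.  The fate policy encodes what the dosimetry
pipeline assumes about atoms of that nuclide generated inside the body:

``AT_PARENT_SITE``
    the nuclide decays where its kinetic anchor (the nearest ancestor that
    has kinetics of its own) decayed; its time-integrated activity is the
    anchor's scaled by the net yield.
``FREE_MODEL``
    the nuclide has its own registered biokinetic model (or fixed
    distribution table).
``SPLIT``
    a fraction stays bound to the carrier (antibody) and the remainder is
    handed to a free-species model as it is generated.
``DISCARD``
    the nuclide and its descendants along this path are excluded from
    dosimetry (used for minor branches deemed negligible).

Chain kinetics (:func:`bateman_activities`) are solved exactly via the
matrix exponential of the branched-decay generator; this serves as an
oracle for the compartmental simulators rather than as pipeline plumbing.

All times are hours internally; half-lives are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.linalg import expm

LN2 = float(np.log(2.0))

#: hours per unit; year is the Julian year (365.25 d)
TIME_UNITS_H = {
    "us": 1.0 / 3.6e9,
    "ms": 1.0 / 3.6e6,
    "s": 1.0 / 3600.0,
    "min": 1.0 / 60.0,
    "h": 1.0,
    "d": 24.0,
    "y": 8766.0,
}

EMISSION_KINDS = ("alpha", "beta", "electron", "photon")

#: generated atoms with a net yield below this are dropped at chain load
MIN_NET_YIELD = 1e-6


class ChainError(ValueError):
    """Raised for malformed chain specifications."""


@dataclass(frozen=True)
class Emission:
    """Yield-weighted mean energy emitted per decay for one emission kind."""

    kind: str
    mev_per_decay: float

    def __post_init__(self) -> None:
        if self.kind not in EMISSION_KINDS:
            raise ChainError(f"unknown emission kind {self.kind!r}")
        if self.mev_per_decay < 0:
            raise ChainError("mean energy per decay must be >= 0")


@dataclass(frozen=True)
class Nuclide:
    """A chain member with half-life (hours) and per-decay mean energies."""

    name: str
    half_life_h: float  # np.inf marks a stable end state
    emissions: tuple[Emission, ...] = ()

    @property
    def stable(self) -> bool:
        return not np.isfinite(self.half_life_h)

    @property
    def decay_constant(self) -> float:
        """lambda = ln 2 / T1/2 in 1/h (0 for stable members)."""
        return 0.0 if self.stable else LN2 / self.half_life_h

    def energy(self, kind: str) -> float:
        if kind not in EMISSION_KINDS:
            raise ChainError(f"unknown emission kind {kind!r}")
        return sum(e.mev_per_decay for e in self.emissions if e.kind == kind)

    @property
    def total_energy(self) -> float:
        return sum(e.mev_per_decay for e in self.emissions)


@dataclass(frozen=True)
class Branch:
    parent: str
    daughter: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ChainError(
                f"branch fraction {self.parent}->{self.daughter} = "
                f"{self.fraction} outside [0, 1]"
            )


@dataclass(frozen=True)
class FatePolicy:
    mode: str  # AT_PARENT_SITE | FREE_MODEL | SPLIT | DISCARD
    model_id: str | None = None
    bound_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("AT_PARENT_SITE", "FREE_MODEL", "SPLIT", "DISCARD"):
            raise ChainError(f"unknown fate mode {self.mode!r}")
        if self.mode == "FREE_MODEL" and not self.model_id:
            raise ChainError("FREE_MODEL fate requires a model id")
        if self.mode == "SPLIT":
            if self.bound_fraction is None or not 0.0 <= self.bound_fraction <= 1.0:
                raise ChainError("SPLIT fate requires bound_fraction in [0, 1]")
            if not self.model_id:
                raise ChainError("SPLIT fate requires a free-model id")


@dataclass
class DecayChain:
    """An acyclic branched decay series with per-nuclide fate policies."""

    name: str
    nuclides: dict[str, Nuclide]
    branches: list[Branch]
    fates: dict[str, FatePolicy] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        names = list(self.nuclides)
        if len(set(names)) != len(names):
            raise ChainError("duplicate nuclide names")
        for b in self.branches:
            for end in (b.parent, b.daughter):
                if end not in self.nuclides:
                    raise ChainError(f"branch endpoint {end!r} is not a listed nuclide")
        for parent in names:
            tot = sum(b.fraction for b in self.branches if b.parent == parent)
            if tot > 1.0 + 1e-12:
                raise ChainError(
                    f"branch fractions of {parent} sum to {tot:.6f} > 1"
                )
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        order: list[str] = []
        marks: dict[str, int] = {}

        def visit(n: str) -> None:
            state = marks.get(n, 0)
            if state == 1:
                raise ChainError("branch graph contains a cycle")
            if state == 2:
                return
            marks[n] = 1
            for b in self.branches:
                if b.parent == n:
                    visit(b.daughter)
            marks[n] = 2
            order.append(n)

        for n in self.nuclides:
            visit(n)
        return list(reversed(order))

    def parents(self, name: str) -> list[Branch]:
        return [b for b in self.branches if b.daughter == name]

    def daughters(self, name: str) -> list[Branch]:
        return [b for b in self.branches if b.parent == name]

    def fate(self, name: str) -> FatePolicy:
        if name not in self.nuclides:
            raise ChainError(f"{name!r} not in chain {self.name!r}")
        try:
            return self.fates[name]
        except KeyError:
            raise ChainError(f"no fate policy for {name!r}") from None

    def anchor(self, name: str) -> str:
        """Nearest ancestor with kinetics of its own (non-AT_PARENT_SITE).

        Atoms of an ``AT_PARENT_SITE`` nuclide decay where this anchor
        decayed.  Raises if different parent paths lead to different anchors.
        """
        if self.fate(name).mode != "AT_PARENT_SITE":
            return name
        anchors = set()
        for b in self.parents(name):
            if self.fates.get(b.parent) and self.fate(b.parent).mode == "DISCARD":
                continue
            anchors.add(self.anchor(b.parent))
        if len(anchors) != 1:
            raise ChainError(
                f"ambiguous or missing decay-site anchor for {name!r}: {anchors}"
            )
        return anchors.pop()

    # -- yields ------------------------------------------------------------

    def net_yield(self, ancestor: str, descendant: str) -> float:
        """Sum over all directed ancestor->descendant paths of the product
        of branch fractions (1.0 for ancestor == descendant)."""
        for n in (ancestor, descendant):
            if n not in self.nuclides:
                raise ChainError(f"{n!r} not in chain {self.name!r}")
        order = self.topological_order()
        reach = {n: 0.0 for n in order}
        reach[ancestor] = 1.0
        for n in order:
            y = reach[n]
            if y == 0.0:
                continue
            for b in self.daughters(n):
                reach[b.daughter] += y * b.fraction
        return reach[descendant]


# ---------------------------------------------------------------------------


def _parse_emissions(raw) -> tuple[Emission, ...]:
    if raw is None:
        return ()
    if isinstance(raw, Mapping):
        return tuple(Emission(kind=k, mev_per_decay=float(v)) for k, v in raw.items())
    return tuple(
        Emission(kind=e["kind"], mev_per_decay=float(e["mev_per_decay"])) for e in raw
    )


def _parse_fate(raw) -> FatePolicy:
    if isinstance(raw, str):
        return FatePolicy(mode=raw)
    return FatePolicy(
        mode=raw["mode"],
        model_id=raw.get("model"),
        bound_fraction=raw.get("bound_fraction"),
    )


def load_chain(spec: Mapping | str | Path) -> DecayChain:
    """Build a validated :class:`DecayChain` from a dict or a YAML file.

    Half-lives are given with an explicit unit (``us/ms/s/min/h/d/y``) and
    converted to hours.  Nuclides whose net yield from the chain head falls
    below :data:`MIN_NET_YIELD` are dropped together with their branches.
    """
    if isinstance(spec, (str, Path)):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    nuclides: dict[str, Nuclide] = {}
    for raw in spec["nuclides"]:
        unit = raw.get("unit", "h")
        if raw.get("stable"):
            hl = np.inf
        else:
            if unit not in TIME_UNITS_H:
                raise ChainError(f"unknown time unit {unit!r}")
            hl = float(raw["half_life"]) * TIME_UNITS_H[unit]
            if hl <= 0:
                raise ChainError(f"half-life of {raw['name']} must be positive")
        nuclides[raw["name"]] = Nuclide(
            name=raw["name"],
            half_life_h=hl,
            emissions=_parse_emissions(raw.get("emissions")),
        )
    branches = [
        Branch(b["parent"], b["daughter"], float(b["fraction"]))
        for b in spec.get("branches", [])
    ]
    fates = {name: _parse_fate(raw) for name, raw in (spec.get("fates") or {}).items()}
    chain = DecayChain(
        name=spec.get("name", "chain"),
        nuclides=nuclides,
        branches=branches,
        fates=fates,
    )
    head = next(iter(nuclides))
    keep = {n for n in chain.nuclides if chain.net_yield(head, n) >= MIN_NET_YIELD}
    if keep != set(chain.nuclides):
        chain = DecayChain(
            name=chain.name,
            nuclides={n: v for n, v in chain.nuclides.items() if n in keep},
            branches=[
                b for b in chain.branches if b.parent in keep and b.daughter in keep
            ],
            fates={n: f for n, f in chain.fates.items() if n in keep},
        )
    return chain


# ---------------------------------------------------------------------------


@dataclass
class BatemanResult:
    times: np.ndarray
    activities: dict[str, np.ndarray]  # MBq per nuclide
    atoms: dict[str, np.ndarray]  # MBq*h atom-equivalents, incl. sink states

    def total_atoms(self) -> np.ndarray:
        return sum(self.atoms.values())


def bateman_activities(
    chain: DecayChain,
    initial_activity: Mapping[str, float],
    times: Iterable[float],
) -> BatemanResult:
    """Exact activities of every chain member on a time grid.

    Solves dN/dt = A N for the branched decay generator A (matrix
    exponential, exact for arbitrary and repeated half-lives).  Atoms are
    carried in MBq*h equivalents (activity / decay constant) so that
    activities come out in MBq.  Two absorbing bookkeeping states,
    ``<name>:lost`` for each parent whose branch fractions sum below 1, and
    the stable chain members themselves, make total atom count conserved.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size and (np.any(times < 0) or np.any(np.diff(times) < 0)):
        raise ValueError("times must be nonnegative and non-decreasing")
    for name, a0 in initial_activity.items():
        if name not in chain.nuclides:
            raise ChainError(f"{name!r} not in chain {chain.name!r}")
        if a0 < 0:
            raise ValueError("initial activity must be nonnegative")

    names = chain.topological_order()
    index = {n: i for i, n in enumerate(names)}
    lost_states: dict[str, int] = {}
    n_main = len(names)
    # absorbing 'lost' state per parent with missing branch fraction
    for n in names:
        nuc = chain.nuclides[n]
        if nuc.stable:
            continue
        tot = sum(b.fraction for b in chain.daughters(n))
        if tot < 1.0 - 1e-12:
            lost_states[n] = n_main + len(lost_states)
    dim = n_main + len(lost_states)
    A = np.zeros((dim, dim))
    for n in names:
        nuc = chain.nuclides[n]
        lam = nuc.decay_constant
        i = index[n]
        A[i, i] = -lam
        tot = 0.0
        for b in chain.daughters(n):
            A[index[b.daughter], i] += b.fraction * lam
            tot += b.fraction
        if n in lost_states:
            A[lost_states[n], i] = (1.0 - tot) * lam

    n0 = np.zeros(dim)
    for name, a0 in initial_activity.items():
        nuc = chain.nuclides[name]
        if nuc.stable:
            if a0 > 0:
                raise ValueError(f"stable nuclide {name!r} cannot carry activity")
            continue
        n0[index[name]] = a0 / nuc.decay_constant

    atoms = np.empty((times.size, dim))
    prev_t = 0.0
    state = n0.copy()
    for k, t in enumerate(times):
        dt = t - prev_t
        if dt > 0:
            state = expm(A * dt) @ state
            prev_t = t
        atoms[k] = state if t > 0 else n0
    activities = {
        n: chain.nuclides[n].decay_constant * atoms[:, index[n]] for n in names
    }
    atom_curves: dict[str, np.ndarray] = {n: atoms[:, index[n]] for n in names}
    for parent, j in lost_states.items():
        atom_curves[f"{parent}:lost"] = atoms[:, j]
    return BatemanResult(times=times, activities=activities, atoms=atom_curves)
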