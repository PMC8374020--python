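"""Time-integrated activity coefficients (TIACs) and their apportionment.

The TIAC of a source region is the integral of its activity time course per
MBq administered (MBq h/MBq, formerly "residence time").  Curves are
integrated with the trapezoidal rule on the simulation grid; beyond the
simulated horizon an analytic single-exponential tail, fitted to the final
stretch of the curve, bounds the truncation error.

Apportionment follows the antibody model's anatomy: the vascular
compartment splits into liver/spleen/red-marrow extracellular fluid and a
blood remainder that is shared among all tissues in proportion to their
blood volume; the antigen-bound and internalized compartments split across
the antigen-positive cell sites (liver, spleen, red marrow).  Daughters
flagged ``AT_PARENT_SITE`` inherit the TIAC of their kinetic anchor scaled
by the net yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .decay import DecayChain
from .kinetics import AbModelParams, AbSolution, PKCurves

BLOOD_REGION = "@blood"
SOFT_TISSUE_REGION = "@soft_tissue_mass"


class TIACError(ValueError):
    pass


# ---------------------------------------------------------------------------


@dataclass
class Phantom:
    """Tissue masses and blood-volume fractions of the reference body.

    ``tissues`` has one row per source/target region with columns
    ``mass_kg`` and ``blood_volume_fraction`` (share of the circulating
    blood pool residing in the region; fractions sum to <= 1).  ``targets``
    lists the regions for which absorbed dose is reported (radiosensitive
    tissues; excludes excreta content and mineral-bone source regions).
    """

    tissues: pd.DataFrame  # index: region name
    targets: list[str]
    name: str = "phantom"

    def __post_init__(self) -> None:
        t = self.tissues
        if (t["mass_kg"] <= 0).any():
            raise TIACError("tissue masses must be positive")
        bv = t["blood_volume_fraction"]
        if (bv < 0).any() or bv.sum() > 1.0 + 1e-9:
            raise TIACError("blood-volume fractions must be >= 0 and sum to <= 1")
        missing = [x for x in self.targets if x not in t.index]
        if missing:
            raise TIACError(f"target regions missing from phantom: {missing}")

    def mass(self, region: str) -> float:
        try:
            return float(self.tissues.at[region, "mass_kg"])
        except KeyError:
            raise TIACError(f"no mass for region {region!r}") from None

    def blood_fraction(self, region: str) -> float:
        return float(self.tissues.at[region, "blood_volume_fraction"])

    @property
    def regions(self) -> list[str]:
        return list(self.tissues.index)

    def soft_tissue_weights(self) -> dict[str, float]:
        """Mass weights over parenchymal soft tissue, used to spread the
        'other soft tissue' compartment of the systemic models.  Excludes
        excreta contents, bone surfaces, mineral bone, marrow, and the
        organs those models treat explicitly (liver, kidneys)."""
        skip = {"Red marrow", "Endosteal bone surface", "Liver", "Kidneys",
                "Cortical bone", "Trabecular bone"}
        rows = [
            r
            for r in self.regions
            if r not in skip and "content" not in r and "surface" not in r
        ]
        total = sum(self.mass(r) for r in rows)
        return {r: self.mass(r) / total for r in rows}


# ---------------------------------------------------------------------------


@dataclass
class TIACTable:
    """(source region, nuclide group) -> TIAC in MBq h per MBq administered."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, region: str, group: str, value: float) -> None:
        if value < 0:
            if value > -1e-12:  # numerical noise from the integrator
                value = 0.0
            else:
                raise TIACError(f"negative TIAC for ({region}, {group}): {value}")
        key = (region, group)
        self.entries[key] = self.entries.get(key, 0.0) + value

    def get(self, region: str, group: str) -> float:
        return self.entries.get((region, group), 0.0)

    def groups(self) -> list[str]:
        return sorted({g for _, g in self.entries})

    def regions(self, group: str | None = None) -> list[str]:
        return sorted({r for r, g in self.entries if group is None or g == group})

    def total(self, group: str) -> float:
        return sum(v for (_, g), v in self.entries.items() if g == group)

    def scaled(self, factor: float, group_suffix: str = "") -> "TIACTable":
        return TIACTable(
            entries={
                (r, g + group_suffix): v * factor for (r, g), v in self.entries.items()
            },
            meta=dict(self.meta),
        )

    def merged_with(self, other: "TIACTable") -> "TIACTable":
        out = TIACTable(entries=dict(self.entries), meta=dict(self.meta))
        for (r, g), v in other.entries.items():
            out.add(r, g, v)
        return out

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"source_region": r, "nuclide_group": g, "tiac_mbqh_per_mbq": v}
            for (r, g), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["source_region", "nuclide_group", "tiac_mbqh_per_mbq"])

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TIACTable":
        df = pd.read_csv(path, float_precision="round_trip")
        table = cls()
        for row in df.itertuples(index=False):
            table.entries[(row.source_region, row.nuclide_group)] = float(
                row.tiac_mbqh_per_mbq
            )
        return table


# ---------------------------------------------------------------------------
# curve integration
# ---------------------------------------------------------------------------


def integrate_curve(
    times: np.ndarray,
    values: np.ndarray,
    tail: str = "exponential",
) -> float:
    """Trapezoidal integral of a nonnegative activity curve, plus an
    analytic exponential tail beyond the final grid point.

    The tail rate is fitted by log-linear regression over the last stretch
    of the curve (points in the last factor-of-two of the time axis); if
    the curve has already decayed to zero or is not decreasing there, the
    tail contribution is zero.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise TIACError("need at least two grid points to integrate")
    if np.any(np.diff(times) <= 0):
        raise TIACError("time grid must be strictly increasing")
    if np.any(values < -1e-12):
        raise TIACError("activity curve must be nonnegative")
    values = np.clip(values, 0.0, None)
    area = float(np.trapezoid(values, times))
    if tail == "none":
        return area
    if tail != "exponential":
        raise TIACError(f"unknown tail policy {tail!r}")
    y_end = values[-1]
    if y_end <= 0.0:
        return area
    sel = times >= times[-1] / 2.0
    if sel.sum() < 3 or np.any(values[sel] <= 0.0):
        return area
    t_fit, y_fit = times[sel], np.log(values[sel])
    slope = np.polyfit(t_fit, y_fit, 1)[0]
    if slope >= 0:
        # curve still in uptake at the horizon: no defensible exponential
        # tail; return the (under-estimating) truncated integral
        return area
    return area + float(y_end / (-slope))


def integrate_pk(
    pk: PKCurves, compartments: Iterable[str], tail: str = "exponential"
) -> dict[str, float]:
    return {c: integrate_curve(pk.times, pk[c], tail=tail) for c in compartments}


# ---------------------------------------------------------------------------
# apportionment
# ---------------------------------------------------------------------------


def apportion_blood(blood_tiac: float, phantom: Phantom) -> dict[str, float]:
    """Share a blood TIAC among tissues by their blood-volume fraction."""
    if blood_tiac < 0:
        raise TIACError("blood TIAC must be nonnegative")
    bv = phantom.tissues["blood_volume_fraction"]
    return {r: blood_tiac * f for r, f in bv.items() if f > 0}


def apportion_ab_model(
    ab: AbSolution | PKCurves,
    params: AbModelParams,
    phantom: Phantom,
    tail: str = "exponential",
) -> TIACTable:
    """Apportion antibody-model compartment TIACs to source regions.

    The vascular compartment splits into liver ECF (f_L1), spleen ECF
    (f_S1), red-marrow ECF (V_RMECF/Vd) and a blood remainder apportioned
    by blood volume; the antigen-bound + internalized compartments split
    across antigen-positive cell sites (f_L2 liver, f_S2 spleen, remainder
    red marrow).
    """
    pk = ab.curves if isinstance(ab, AbSolution) else ab
    f_rm1 = params.v_rmecf / params.vd
    f_blood = 1.0 - params.f_l1 - params.f_s1 - f_rm1
    if f_blood < -1e-12:
        raise TIACError("vascular fractions (f_L1 + f_S1 + V_RMECF/Vd) exceed 1")
    c = integrate_pk(pk, ("vascular", "bound", "internalized"), tail=tail)
    c1, c23 = c["vascular"], c["bound"] + c["internalized"]
    table = TIACTable(meta={"tail": tail, "blood_tiac": f_blood * c1})
    group = pk.meta.get("group", "Ab")
    table.add("Liver", group, params.f_l1 * c1 + params.f_l2 * c23)
    table.add("Spleen", group, params.f_s1 * c1 + params.f_s2 * c23)
    table.add(
        "Red marrow",
        group,
        f_rm1 * c1 + (1.0 - params.f_l2 - params.f_s2) * c23,
    )
    for region, share in apportion_blood(f_blood * c1, phantom).items():
        table.add(region, group, share)
    return table


def apportion_linear_model(
    compartment_tiacs: Mapping[str, float],
    region_map: Mapping[str, list[tuple[str, float]]],
    phantom: Phantom,
) -> dict[str, float]:
    """Resolve a linear model's region map into per-region TIACs.

    Handles the special regions ``@blood`` (blood-volume apportionment)
    and ``@soft_tissue_mass`` (mass-weighted spread over parenchymal
    targets).
    """
    out: dict[str, float] = {}

    def _add(region: str, value: float) -> None:
        out[region] = out.get(region, 0.0) + value

    for comp, tiac in compartment_tiacs.items():
        if comp not in region_map:
            raise TIACError(f"no region mapping for compartment {comp!r}")
        for region, weight in region_map[comp]:
            share = tiac * weight
            if region == BLOOD_REGION:
                for r, v in apportion_blood(share, phantom).items():
                    _add(r, v)
            elif region == SOFT_TISSUE_REGION:
                for r, w in phantom.soft_tissue_weights().items():
                    _add(r, share * w)
            else:
                if region not in phantom.tissues.index:
                    raise TIACError(f"region {region!r} not in phantom")
                _add(region, share)
    return out


# ---------------------------------------------------------------------------
# daughters
# ---------------------------------------------------------------------------


def assign_daughters(
    parent_tiacs: TIACTable,
    chain: DecayChain,
    strict: bool = True,
) -> TIACTable:
    """Extend a TIAC table with ``AT_PARENT_SITE`` daughters.

    Each such nuclide inherits the regional TIAC of its kinetic anchor (the
    nearest ancestor with kinetics of its own) scaled by the net yield
    between the two; ``DISCARD`` nuclides are skipped.  Nuclides with their
    own kinetics (``FREE_MODEL``/``SPLIT``) must already be present when
    ``strict`` is set.
    """
    out = TIACTable(entries=dict(parent_tiacs.entries), meta=dict(parent_tiacs.meta))
    present = set(out.groups())
    for name in chain.topological_order():
        if chain.nuclides[name].stable:
            continue
        fate = chain.fate(name)
        if fate.mode == "DISCARD":
            continue
        if fate.mode != "AT_PARENT_SITE":
            if strict and name not in present and chain.daughters(name):
                # heads and free-model nuclides supply their own TIACs
                pass
            continue
        if name in present:
            continue
        anchor = chain.anchor(name)
        if anchor not in present:
            if strict:
                raise TIACError(
                    f"anchor {anchor!r} of {name!r} has no TIAC entries"
                )
            continue
        y = chain.net_yield(anchor, name)
        for region in parent_tiacs.regions(anchor):
            out.add(region, name, parent_tiacs.get(region, anchor) * y)
        present.add(name)
    return out
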