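"""Secondary chemical shifts, structural propensity calls, and H-bond flags.

A secondary shift is the observed shift minus a random-coil reference
(optionally minus a deuterium-isotope correction).  Positive Ca/CO values
indicate helix, negative values extended (beta) structure, values near
zero random coil.  The H-bond analysis compares |h3J_NC'| trans-hydrogen-
bond couplings at structurally equivalent positions across a set of
domains and flags groups where the less stable domains have weaker (or
stronger) H-bonds than every stable domain.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Atom",
    "Propensity",
    "ShiftRecord",
    "RandomCoilTable",
    "HBondRecord",
    "secondary_shift",
    "propensity_call",
    "flag_weakened_hbonds",
]


class Atom(str, enum.Enum):
    CA = "CA"
    CB = "CB"
    CO = "CO"
    N = "N"
    HA = "HA"


class Propensity(str, enum.Enum):
    helix = "helix"
    extended = "extended"
    coil = "coil"


@dataclass(frozen=True)
class ShiftRecord:
    residue: int
    residue_type: str
    atom: Atom
    delta_obs: float  # ppm

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_obs):
            raise ValueError("observed shift must be finite")


@dataclass
class RandomCoilTable:
    """Random-coil reference shifts: (residue type, atom) -> ppm.

    ``deuterium_corrections`` maps (residue type, atom) -> ppm correction
    to subtract for perdeuterated samples; empty for protonated work.
    """

    shifts: dict[tuple[str, str], float]
    deuterium_corrections: dict[tuple[str, str], float] | None = None

    def lookup(self, residue_type: str, atom: Atom | str) -> float:
        key = (residue_type.upper(), Atom(atom).value)
        if key not in self.shifts:
            raise KeyError(f"no random-coil reference for {key}")
        return self.shifts[key]

    def correction(self, residue_type: str, atom: Atom | str) -> float:
        if not self.deuterium_corrections:
            return 0.0
        return self.deuterium_corrections.get(
            (residue_type.upper(), Atom(atom).value), 0.0
        )


def secondary_shift(
    obs: ShiftRecord,
    random_coil_ppm: float,
    deuterium_correction: float = 0.0,
) -> float:
    """Secondary shift = observed - random coil - deuterium correction (ppm)."""
    if not np.isfinite(random_coil_ppm):
        raise ValueError("random-coil reference must be finite")
    return obs.delta_obs - random_coil_ppm - deuterium_correction


def propensity_call(
    dd_ca: dict[int, float],
    dd_co: dict[int, float],
    window: int = 3,
    t_ca: float = 0.7,
    t_co: float = 0.5,
) -> dict[int, Propensity]:
    """Per-residue secondary-structure propensity from Ca and CO secondary shifts.

    A centred sliding-window mean is taken over each series; a residue is
    called helix when both averaged series exceed +t, extended when both
    fall below -t, otherwise coil.  Thresholds default to 0.7 ppm (Ca) and
    0.5 ppm (CO), conventional cutoffs for backbone-shift propensities.
    """
    residues = sorted(set(dd_ca) & set(dd_co))
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > len(residues):
        raise ValueError("window larger than the aligned series")

    half = window // 2
    calls: dict[int, Propensity] = {}
    for r in residues:
        neigh = [q for q in range(r - half, r + half + 1) if q in dd_ca and q in dd_co]
        ca = float(np.mean([dd_ca[q] for q in neigh]))
        co = float(np.mean([dd_co[q] for q in neigh]))
        if ca > t_ca and co > t_co:
            calls[r] = Propensity.helix
        elif ca < -t_ca and co < -t_co:
            calls[r] = Propensity.extended
        else:
            calls[r] = Propensity.coil
    return calls


@dataclass(frozen=True)
class HBondRecord:
    """One domain's |h3J_NC'| measurement for one equivalence group."""

    group: int          # equivalence group number aligning positions across domains
    sheet: str          # e.g. "b1-b2"
    domain: str
    donor: int | None = None
    acceptor: int | None = None
    abs_J: float | None = None   # Hz; None when not measurable
    sigma_J: float | None = None
    missing_reason: str | None = None

    def __post_init__(self) -> None:
        if self.abs_J is not None and self.abs_J < 0:
            raise ValueError("|h3J_NC'| must be non-negative")


def flag_weakened_hbonds(
    records: Iterable[HBondRecord],
    stable_domains: set[str],
    reduced_domains: set[str],
    k_min: int = 2,
) -> dict[int, dict]:
    """Flag H-bond groups weakened (or strengthened) in the less stable domains.

    Within each group, a domain with reduced thermodynamic stability
    counts as "weaker" when its |h3J_NC'| is below the minimum over the
    stable domains with data in that group (strictest order-invariant
    reading), and "stronger" when above the stable maximum.  A group is
    flagged when at least ``k_min`` reduced-stability domains agree.
    Missing values are excluded from comparisons and listed per group.
    """
    by_group: dict[int, list[HBondRecord]] = defaultdict(list)
    for rec in records:
        by_group[rec.group].append(rec)

    out: dict[int, dict] = {}
    for group in sorted(by_group):
        recs = by_group[group]
        # deduplicate identical records so duplication cannot change counts
        seen, uniq = set(), []
        for r in recs:
            key = (r.domain, r.donor, r.acceptor, r.abs_J)
            if key not in seen:
                seen.add(key)
                uniq.append(r)
        stable_vals = [
            r.abs_J for r in uniq if r.domain in stable_domains and r.abs_J is not None
        ]
        reduced_vals = [
            r.abs_J for r in uniq if r.domain in reduced_domains and r.abs_J is not None
        ]
        missing = sorted(
            r.domain for r in uniq if r.abs_J is None and (r.domain in stable_domains or r.domain in reduced_domains)
        )
        info: dict = {
            "flag": "none",
            "n_stable": len(stable_vals),
            "n_reduced": len(reduced_vals),
            "missing": missing,
            "warnings": [],
        }
        if not stable_vals:
            info["warnings"].append("no stable-domain data in this group")
            out[group] = info
            continue
        s_min, s_max = min(stable_vals), max(stable_vals)
        n_weaker = sum(1 for v in reduced_vals if v < s_min)
        n_stronger = sum(1 for v in reduced_vals if v > s_max)
        if n_weaker >= k_min:
            info["flag"] = "weaker"
        elif n_stronger >= k_min:
            info["flag"] = "stronger"
        info["n_weaker"] = n_weaker
        info["n_stronger"] = n_stronger
        out[group] = info
    return out
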