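"""Electron and hydrogen-atom donation map for antioxidants (eH-DAMA).

Each relevant acid-base species is placed at (IP, minimum BDE): the
ionization potential gauges single-electron-transfer (SET) donation and the
minimum X-H bond dissociation energy over the declared donor sites (phenol
O-H, amine N-H, thiol S-H, ester methyl C-H) gauges hydrogen-atom-transfer
(HAT) donation.  Lower is better on both axes.  Species are classified
against a reference panel (Trolox, alpha-tocopherol, ascorbate) and against
the oxidant target H2O2/hydroperoxyl: a species whose minimum BDE lies below
the H-OOH homolysis energy, or whose IP lies below the hydroperoxyl
electron-acceptance entry, is predicted to scavenge the radical by that
mechanism.  Ties within 0.1 kcal/mol are "similar" rather than better/worse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ReactivityRecord",
    "ReferencePanel",
    "SpeciesClassification",
    "SYNTHETIC_REFERENCE_PANEL",
    "build_map",
    "classify_species",
    "rank_antioxidants",
]

#: Comparison tolerance for "similar" calls, in kcal/mol.
SIMILARITY_TOL_KCAL = 0.1

KCAL_PER_KJ = 1.0 / 4.184

#: Donor-site inventory recognised in reactivity tables.
H_DONOR_SITES = ("phenol_OH", "amine_NH", "thiol_SH", "ester_CH3")


@dataclass(frozen=True)
class ReactivityRecord:
    """Per-species ionization potential and bond dissociation energies."""

    id: str
    species: str
    ip: float
    bde_by_site: Mapping[str, float]
    unit: str = "kcal/mol"  # or "kJ/mol"

    @property
    def bde_min(self) -> Optional[float]:
        return min(self.bde_by_site.values()) if self.bde_by_site else None


@dataclass(frozen=True)
class ReferencePanel:
    """Reference antioxidants plus the oxidant target, shared unit."""

    trolox: ReactivityRecord
    alpha_tocopherol: ReactivityRecord
    ascorbate: ReactivityRecord
    ooh_target: ReactivityRecord
    unit: str = "kcal/mol"

    @property
    def antioxidants(self) -> Dict[str, ReactivityRecord]:
        return {
            "trolox": self.trolox,
            "alpha_tocopherol": self.alpha_tocopherol,
            "ascorbate": self.ascorbate,
        }

    def as_records(self) -> List[ReactivityRecord]:
        return [self.trolox, self.alpha_tocopherol, self.ascorbate, self.ooh_target]


#: Synthetic stand-in panel (kcal/mol).  The BDE ordering (ascorbate <
#: alpha-tocopherol < Trolox << H-OOH) and IP ordering (ascorbate lowest)
#: follow the known relative behaviour of these antioxidants; the numbers
#: themselves are plausible synthetic values, not measured or computed ones.
SYNTHETIC_REFERENCE_PANEL = ReferencePanel(
    trolox=ReactivityRecord("trolox", "trolox", ip=103.7,
                            bde_by_site={"phenol_OH": 78.9}),
    alpha_tocopherol=ReactivityRecord("alpha_tocopherol", "alpha_tocopherol",
                                      ip=99.0, bde_by_site={"phenol_OH": 77.1}),
    ascorbate=ReactivityRecord("ascorbate", "ascorbate", ip=82.0,
                               bde_by_site={"enol_OH": 74.3}),
    ooh_target=ReactivityRecord("H2O2/OOH", "H2O2/OOH", ip=105.0,
                                bde_by_site={"OO-H": 87.8}),
)


def _tol_for(unit: str) -> float:
    if unit == "kcal/mol":
        return SIMILARITY_TOL_KCAL
    if unit == "kJ/mol":
        return SIMILARITY_TOL_KCAL * 4.184
    raise ValueError(f"unknown energy unit {unit!r}")


def _check_units(records: Sequence[ReactivityRecord], refs: ReferencePanel) -> None:
    units = {r.unit for r in records} | {refs.unit}
    if len(units) > 1:
        raise ValueError(f"mixed energy units: {sorted(units)}")


def build_map(
    records: Sequence[ReactivityRecord], refs: ReferencePanel
) -> pd.DataFrame:
    """Tabulate (IP, min BDE) coordinates for species and references.

    One row per species plus the four reference rows, ready for export or
    scatter plotting.
    """
    for name, rec in {**refs.antioxidants, "ooh_target": refs.ooh_target}.items():
        if rec is None:
            raise ValueError(f"reference panel is missing {name}")
    _check_units(records, refs)
    rows = []
    for rec in list(records) + refs.as_records():
        is_ref = rec in refs.as_records()
        rows.append({
            "id": rec.id,
            "species": rec.species,
            "ip": rec.ip,
            "bde_min": rec.bde_min,
            "role": "reference" if is_ref else "candidate",
        })
    return pd.DataFrame(rows, columns=["id", "species", "ip", "bde_min", "role"])


def _compare(value: float, ref_value: float, tol: float) -> str:
    if abs(value - ref_value) <= tol:
        return "similar"
    return "better" if value < ref_value else "worse"


@dataclass(frozen=True)
class SpeciesClassification:
    """SET/HAT comparison of one species against the panel."""

    id: str
    species: str
    set_class: Mapping[str, str]   # reference name -> better/similar/worse
    hat_class: Mapping[str, str]
    scavenges_ooh_hat: bool
    scavenges_ooh_set: bool

    def dominates(self, reference: str) -> bool:
        """Better than ``reference`` via both mechanisms."""
        return (
            self.set_class[reference] == "better"
            and self.hat_class[reference] == "better"
        )

    @property
    def n_dominated(self) -> int:
        return sum(1 for name in self.set_class if self.dominates(name))


def classify_species(
    rec: ReactivityRecord, refs: ReferencePanel
) -> SpeciesClassification:
    """Classify one species against each reference antioxidant and the
    hydroperoxyl target."""
    _check_units([rec], refs)
    if rec.bde_min is None:
        raise ValueError(f"species {rec.species!r} has no H-donor site")
    tol = _tol_for(refs.unit)
    set_class, hat_class = {}, {}
    for name, ref in refs.antioxidants.items():
        set_class[name] = _compare(rec.ip, ref.ip, tol)
        hat_class[name] = _compare(rec.bde_min, ref.bde_min, tol)
    return SpeciesClassification(
        id=rec.id,
        species=rec.species,
        set_class=set_class,
        hat_class=hat_class,
        scavenges_ooh_hat=rec.bde_min < refs.ooh_target.bde_min,
        scavenges_ooh_set=rec.ip < refs.ooh_target.ip,
    )


def rank_antioxidants(
    records: Sequence[ReactivityRecord], refs: ReferencePanel
) -> List[SpeciesClassification]:
    """Order species by antioxidant strength.

    Sort key: number of references dominated via both mechanisms
    (descending), then ascending minimum BDE, then ascending IP, then id.
    """
    classified = [(rec, classify_species(rec, refs)) for rec in records]
    classified.sort(
        key=lambda rc: (-rc[1].n_dominated, rc[0].bde_min, rc[0].ip, rc[0].id)
    )
    return [c for _, c in classified]


def best_species_classification(
    classifications: Sequence[SpeciesClassification],
) -> Optional[SpeciesClassification]:
    """Compound-level summary: the strongest class among relevant species."""
    if not classifications:
        return None
    return max(classifications, key=lambda c: (c.n_dominated, c.scavenges_ooh_hat))
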