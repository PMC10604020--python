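"""Physicochemical descriptors, drug-likeness rule filters and the first
(missing-toxicity) screen.

Descriptors come from RDKit; hydrogen-bond donors/acceptors follow Lipinski's
original count definitions (HBD = OH + NH, HBA = N + O) so that they can be
verified by hand.  Synthetic accessibility (0-100, higher = easier) and the
four toxicity endpoints — rodent oral LD50 (mg/kg), Ames mutagenicity and
developmental toxicity (probabilities) and the log10 bioaccumulation factor —
are produced by external predictors and are ingested as table columns; any
compound missing a toxicity endpoint is removed in the first screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

__all__ = [
    "PropertyVector",
    "RuleReport",
    "TOXICITY_ENDPOINTS",
    "ADME2_FIELDS",
    "ADME8_FIELDS",
    "PROPERTY_COLUMNS",
    "compute_descriptors",
    "apply_rules",
    "first_screen",
    "rescale_ertl_sa",
]

#: Endpoints whose absence triggers elimination in the first screen.
TOXICITY_ENDPOINTS = ("ld50", "mutagenicity", "dev_tox", "bf")

#: The two-descriptor and eight-descriptor ADME panels used by the scores.
ADME2_FIELDS = ("mw", "logp")
ADME8_FIELDS = ("mw", "logp", "hbd", "hba", "tpsa", "rotb", "mr", "heavy_atoms")

#: Canonical column order of the property table (CSV interface).
PROPERTY_COLUMNS = [
    "id", "mw", "logp", "hbd", "hba", "tpsa", "rotb", "mr",
    "heavy_atoms", "carbons", "heteroatoms", "rings",
    "sa", "ld50", "mutagenicity", "dev_tox", "bf",
]


@dataclass
class PropertyVector:
    """ADME descriptors plus SA and toxicity endpoints for one compound."""

    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    rotb: int
    mr: float
    heavy_atoms: int
    carbons: int
    heteroatoms: int
    rings: int
    sa: Optional[float] = None
    ld50: Optional[float] = None
    mutagenicity: Optional[float] = None
    dev_tox: Optional[float] = None
    bf: Optional[float] = None

    @property
    def missing(self) -> Set[str]:
        """Names of SA/toxicity endpoints with no value."""
        out = set()
        for name in ("sa",) + TOXICITY_ENDPOINTS:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                out.add(name)
        return out


def compute_descriptors(smiles: str, compound_id: str = "") -> PropertyVector:
    """Compute the descriptor block of a :class:`PropertyVector` from SMILES.

    SA and toxicity fields are left unset (missing); they come from external
    predictors or the synthetic generator.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" for {compound_id!r}" if compound_id else ""
        raise ValueError(f"unparseable SMILES{label}: {smiles!r}")
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        tpsa=Descriptors.TPSA(mol),
        rotb=Lipinski.NumRotatableBonds(mol),
        mr=Crippen.MolMR(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        carbons=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        heteroatoms=sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6)
        ),
        rings=rdMolDescriptors.CalcNumRings(mol),
    )


@dataclass(frozen=True)
class RuleReport:
    """Violation counts and pass flags for the five drug-likeness rule sets."""

    violations: Dict[str, int]
    passed: Dict[str, bool]

    @property
    def total_rules_violated(self) -> int:
        return sum(1 for ok in self.passed.values() if not ok)

    @property
    def n_rules_passed(self) -> int:
        return sum(1 for ok in self.passed.values() if ok)

    @property
    def bioavailability_concern(self) -> bool:
        """More than one rule set violated (informational flag)."""
        return self.total_rules_violated > 1


_REQUIRED_DESCRIPTORS = (
    "mw", "logp", "hbd", "hba", "tpsa", "rotb", "mr",
    "heavy_atoms", "carbons", "heteroatoms", "rings",
)


def apply_rules(p: PropertyVector) -> RuleReport:
    """Evaluate Lipinski, Ghose, Veber, Egan and Muegge (inclusive bounds).

    Lipinski tolerates one violated condition; the other rule sets none.
    """
    missing = [
        f for f in _REQUIRED_DESCRIPTORS
        if getattr(p, f) is None
        or (isinstance(getattr(p, f), float) and math.isnan(getattr(p, f)))
    ]
    if missing:
        raise ValueError(f"missing descriptor fields: {missing}")

    lipinski = sum([p.mw > 500, p.logp > 5, p.hbd > 5, p.hba > 10])
    ghose = sum([
        not (160 <= p.mw <= 480),
        not (-0.4 <= p.logp <= 5.6),
        not (40 <= p.mr <= 130),
        not (20 <= p.heavy_atoms <= 70),
    ])
    veber = sum([p.rotb > 10, p.tpsa > 140])
    egan = sum([p.logp > 5.88, p.tpsa > 131.6])
    muegge = sum([
        not (200 <= p.mw <= 600),
        not (-2 <= p.logp <= 5),
        p.tpsa > 150,
        p.rings > 7,
        not (p.carbons > 4),
        not (p.heteroatoms > 1),
        p.rotb > 15,
        p.hbd > 5,
        p.hba > 10,
    ])
    violations = {
        "lipinski": lipinski, "ghose": ghose, "veber": veber,
        "egan": egan, "muegge": muegge,
    }
    passed = {
        "lipinski": lipinski <= 1, "ghose": ghose == 0, "veber": veber == 0,
        "egan": egan == 0, "muegge": muegge == 0,
    }
    return RuleReport(violations=violations, passed=passed)


def first_screen(table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a property table into (kept, dropped) by missing toxicity.

    A compound is dropped when any of the four toxicity endpoints is absent
    (NaN/empty).  The partition is order-independent and exhaustive.
    """
    if table.empty:
        return table.copy(), table.copy()
    missing_any = table[list(TOXICITY_ENDPOINTS)].isna().any(axis=1)
    kept = table.loc[~missing_any].copy()
    dropped = table.loc[missing_any].copy()
    return kept, dropped


def rescale_ertl_sa(ertl_score: float) -> float:
    """Map an Ertl-style 1-10 difficulty score onto the 0-100 ease scale."""
    return 100.0 * (10.0 - ertl_score) / 9.0
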