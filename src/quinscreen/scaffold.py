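"""Combinatorial enumeration of substituted derivatives of a labeled scaffold.

A scaffold is a SMILES string in which the substitutable positions carry
atom-map numbers; each map number is bound to a site label (``R1``..``R7``
for quinoline).  Monovalent substituents are given as fragment SMILES with a
single dummy atom (``*``) marking the attachment point.  Enumeration walks
every site subset of size 1..max_k and every assignment of groups to those
sites, attaches the fragments, and emits canonical SMILES, so the count for
order *k* is C(s, k) * g**k for *s* sites and *g* groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Scaffold",
    "SubstituentLibrary",
    "DerivativeRecord",
    "ScaffoldError",
    "QUINOLINE",
    "DEFAULT_LIBRARY",
    "canonicalize",
    "enumerate_derivatives",
]


class ScaffoldError(ValueError):
    """Raised for unparseable structures or inconsistent site definitions."""


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of ``smiles``.

    Idempotent: two spellings of the same molecule map to the same string.
    Raises :class:`ScaffoldError` if the input does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ScaffoldError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Scaffold:
    """A core structure with labeled substitution sites.

    Parameters
    ----------
    core:
        SMILES with atom-map numbers on the substitutable atoms.
    sites:
        Mapping of site label -> atom-map number in ``core``.  Labels are
        enumerated in sorted order, which fixes the derivative numbering.
    """

    core: str
    sites: Mapping[str, int]

    def __post_init__(self) -> None:
        labels = list(self.sites)
        if len(set(labels)) != len(labels):
            raise ScaffoldError("duplicate site labels")
        mapnums = list(self.sites.values())
        if len(set(mapnums)) != len(mapnums):
            raise ScaffoldError("two site labels bound to the same atom")
        mol = Chem.MolFromSmiles(self.core)
        if mol is None:
            raise ScaffoldError(f"unparseable scaffold core: {self.core!r}")
        present = {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()}
        missing = [lab for lab, num in self.sites.items() if num not in present]
        if missing:
            raise ScaffoldError(f"site labels with no matching atom map: {missing}")

    @property
    def site_labels(self) -> List[str]:
        return sorted(self.sites)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.core)


@dataclass(frozen=True)
class SubstituentLibrary:
    """Named monovalent fragments, each with exactly one ``*`` attachment."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, frag in self.entries.items():
            mol = Chem.MolFromSmiles(frag)
            if mol is None:
                raise ScaffoldError(f"unparseable fragment {name!r}: {frag!r}")
            dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
            if len(dummies) != 1:
                raise ScaffoldError(
                    f"fragment {name!r} must have exactly one attachment point, "
                    f"found {len(dummies)}"
                )

    @property
    def group_names(self) -> List[str]:
        # listed order is the enumeration order, not alphabetical
        return list(self.entries)


@dataclass(frozen=True)
class DerivativeRecord:
    """One enumerated structure."""

    id: str
    pattern: Mapping[str, str]  # site label -> group name
    order_k: int
    smiles: str


#: Quinoline with its seven CH positions mapped R1..R7 (ring-fusion carbons
#: and the ring nitrogen are not substituted).
QUINOLINE = Scaffold(
    core="[cH:1]1[cH:2][cH:3]c2[cH:4][cH:5][cH:6][cH:7]c2n1",
    sites={f"R{i}": i for i in range(1, 8)},
)

#: The six functional groups used to decorate the quinoline core.
DEFAULT_LIBRARY = SubstituentLibrary(
    entries={
        "OH": "*O",
        "NH2": "*N",
        "SH": "*S",
        "COH": "*C=O",
        "COCH3": "*C(C)=O",
        "COOCH3": "*C(=O)OC",
    }
)


def _attach(core: Chem.Mol, assignments: Mapping[int, str]) -> str:
    """Attach fragment SMILES to the mapped atoms of ``core``; return SMILES.

    ``assignments`` maps atom-map number -> fragment SMILES.
    """
    mol = Chem.RWMol(core)
    for mapnum, frag_smiles in assignments.items():
        frag = Chem.MolFromSmiles(frag_smiles)
        offset = mol.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        site_idx = next(
            a.GetIdx()
            for a in combined.GetAtoms()
            if a.GetAtomMapNum() == mapnum and a.GetIdx() < offset
        )
        dummy_idx = next(
            a.GetIdx()
            for a in combined.GetAtoms()
            if a.GetIdx() >= offset and a.GetAtomicNum() == 0
        )
        anchor_idx = next(
            n.GetIdx() for n in combined.GetAtomWithIdx(dummy_idx).GetNeighbors()
        )
        combined.AddBond(site_idx, anchor_idx, Chem.BondType.SINGLE)
        site_atom = combined.GetAtomWithIdx(site_idx)
        site_atom.SetNumExplicitHs(0)  # the substituent replaces the ring H
        site_atom.SetNoImplicit(False)
        combined.RemoveAtom(dummy_idx)
        mol = combined
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _iter_patterns(
    labels: List[str], groups: List[str], max_k: int
) -> Iterator[Dict[str, str]]:
    """Yield substitution patterns in deterministic lexicographic order."""
    yield {}
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(labels, k):
            for assignment in itertools.product(groups, repeat=k):
                yield dict(zip(subset, assignment))


def enumerate_derivatives(
    scaffold: Scaffold,
    library: SubstituentLibrary,
    max_k: int,
    id_prefix: str = "dQ",
) -> List[DerivativeRecord]:
    """Enumerate the parent plus all derivatives with 1..max_k substituents.

    Records are ordered lexicographically by (substitution order, site
    subset, group assignment); the parent (order 0) comes first and is
    ``dQ1``, so identifiers are a pure function of the pattern given the
    scaffold and library definitions.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    labels = scaffold.site_labels
    if max_k > len(labels):
        raise ValueError(f"max_k={max_k} exceeds the {len(labels)} sites")
    core = scaffold.mol()
    label_to_map = dict(scaffold.sites)
    records: List[DerivativeRecord] = []
    for index, pattern in enumerate(
        _iter_patterns(labels, library.group_names, max_k), start=1
    ):
        assignments = {
            label_to_map[lab]: library.entries[grp] for lab, grp in pattern.items()
        }
        smiles = _attach(core, assignments)
        records.append(
            DerivativeRecord(
                id=f"{id_prefix}{index}",
                pattern=dict(pattern),
                order_k=len(pattern),
                smiles=smiles,
            )
        )
    return records


def write_smiles(records: List[DerivativeRecord], path: str) -> None:
    """Write one ``smiles<TAB>id`` line per record."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")
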