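"""Multiprotic acid-base speciation along a single (macro-pKa) ladder.

For a ladder of n stepwise pKa values (ascending), the species are ordered
from most protonated to most deprotonated.  Each deprotonation step obeys
[A_j]/[A_{j-1}] = 10**(pH - pKa_j), so the unnormalized weight of the
species with j protons removed is

    log10 w_j = sum_{i<=j} (pH - pKa_i),   w_0 = 1,

and the molar fractions are the normalized weights.  Weights are evaluated
in log10 space with max-subtraction so extreme pH cannot overflow.

Charges are assigned from the charge of the fully protonated species
(``n_basic``, the number of protonations on basic sites such as the
quinolinium nitrogen): species j carries charge n_basic - j.  Species with
molar fraction >= 1% (inclusive) at the working pH are "relevant" and are
the ones carried into the reactivity and docking stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

__all__ = [
    "AcidBaseProfile",
    "species_fractions",
    "relevant_species",
    "species_label",
]

DEFAULT_PH = 7.4
DEFAULT_RELEVANCE_THRESHOLD = 0.01


def species_label(compound_id: str, charge: int) -> str:
    """Microspecies label in the HdQ+/dQ/H-1dQ- convention.

    ``charge`` is relative protonation: +1 is one extra proton on the
    neutral form, -1 one proton removed.
    """
    if charge == 0:
        return compound_id
    count = abs(charge)
    h = f"H{charge}" if charge < 0 else ("H" if count == 1 else f"H{count}")
    sign = ("+" if count == 1 else f"+{count}") if charge > 0 else (
        "-" if count == 1 else f"-{count}"
    )
    return f"{h}{compound_id}{sign}"


@dataclass(frozen=True)
class AcidBaseProfile:
    """Molar fractions of the ladder microspecies at one pH."""

    id: str
    pkas: Sequence[float]
    species: Sequence[str]          # most protonated first
    charges: Sequence[int]
    fractions: Dict[str, float]
    ph: float

    def fraction_of(self, label: str) -> float:
        return self.fractions[label]


def species_fractions(
    pkas: Sequence[float],
    ph: float = DEFAULT_PH,
    compound_id: str = "dQ",
    n_basic: int = 0,
) -> AcidBaseProfile:
    """Closed-form microspecies fractions at ``ph`` for a pKa ladder.

    ``pkas`` must be strictly ascending (stepwise macro-constants); an empty
    ladder yields a single species with fraction 1.  ``n_basic`` is the
    charge of the fully protonated species.
    """
    pkas = [float(x) for x in pkas]
    if any(b <= a for a, b in zip(pkas, pkas[1:])):
        raise ValueError(f"pKa values must be strictly ascending: {pkas}")
    if not all(np.isfinite(pkas)) or not np.isfinite(ph):
        raise ValueError("pKa and pH values must be finite")
    n = len(pkas)
    logw = np.concatenate([[0.0], np.cumsum(ph - np.asarray(pkas))]) if n else np.zeros(1)
    logw -= logw.max()  # guard against overflow at extreme pH
    w = np.power(10.0, logw)
    fracs = w / w.sum()
    charges = [n_basic - j for j in range(n + 1)]
    labels = [species_label(compound_id, c) for c in charges]
    return AcidBaseProfile(
        id=compound_id,
        pkas=tuple(pkas),
        species=tuple(labels),
        charges=tuple(charges),
        fractions={lab: float(f) for lab, f in zip(labels, fracs)},
        ph=float(ph),
    )


def relevant_species(
    profile: AcidBaseProfile,
    threshold: float = DEFAULT_RELEVANCE_THRESHOLD,
) -> List[str]:
    """Species with molar fraction >= threshold, in protonation order.

    The boundary is inclusive: a species sitting exactly at 1% counts as
    present.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("relevance threshold must lie in (0, 1)")
    return [s for s in profile.species if profile.fractions[s] >= threshold]
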