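"""Species-weighted docking aggregation and the polygenic neuroprotection score.

Per enzyme, the best-pose binding score dG_B (kcal/mol, negative =
favorable) of each relevant acid-base microspecies is averaged with weights
equal to the species' molar fractions at pH 7.4, renormalized over the
relevant subset, giving the weighted score dG_B^W.  The per-enzyme affinity
term is log10(dG_B^W / dG_B,sub) against the enzyme's natural substrate
(dopamine for COMT, phenylethylamine for MAO-B, acetylcholine for AChE):
positive means the derivative binds more strongly than the substrate, zero
means equal affinity.  The polygenic score S_P is the sum of the three
enzyme terms; S_P > 0 flags a broadly stronger binder than the substrates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ENZYMES",
    "SubstrateBaseline",
    "AffinityRecord",
    "SYNTHETIC_SUBSTRATE_BASELINES",
    "weighted_score",
    "enzyme_term",
    "polygenic_score",
    "score_compound",
    "psp_table",
]

ENZYMES = ("COMT", "MAOB", "AChE")


@dataclass(frozen=True)
class SubstrateBaseline:
    """Natural-substrate docking scores per enzyme (all strictly negative)."""

    scores: Mapping[str, float]
    substrates: Mapping[str, str] = None

    def __post_init__(self) -> None:
        missing = [e for e in ENZYMES if e not in self.scores]
        if missing:
            raise ValueError(f"baseline missing enzymes: {missing}")
        bad = {e: v for e, v in self.scores.items() if not v < 0}
        if bad:
            raise ValueError(f"substrate scores must be negative: {bad}")


#: Synthetic stand-in baselines (kcal/mol); plausible magnitudes for small
#: natural substrates, not actual docking outputs.
SYNTHETIC_SUBSTRATE_BASELINES = SubstrateBaseline(
    scores={"COMT": -6.8, "MAOB": -6.2, "AChE": -5.9},
    substrates={"COMT": "dopamine", "MAOB": "phenylethylamine",
                "AChE": "acetylcholine"},
)


def weighted_score(
    species_scores: Mapping[str, float], fractions: Mapping[str, float]
) -> float:
    """Fraction-weighted binding score over the relevant species.

    Fractions are renormalized over the scored subset, so the result always
    lies between the per-species extremes and is invariant to a common
    rescaling of the fractions.
    """
    if not species_scores:
        raise ValueError("no species scores given")
    missing = [s for s in species_scores if s not in fractions]
    if missing:
        raise ValueError(f"species without fractions: {missing}")
    total = sum(fractions[s] for s in species_scores)
    if total <= 0:
        raise ValueError("species fractions sum to zero")
    return sum(species_scores[s] * (fractions[s] / total) for s in species_scores)


def enzyme_term(dgw: float, baseline: float, log_base: float = 10.0) -> float:
    """Log-ratio affinity term log_b(dG_B^W / dG_B,sub).

    Both scores must be strictly negative; the ratio of two favorable
    binding energies is positive, and the term is 0 exactly when the
    derivative matches the substrate.
    """
    if not (dgw < 0 and baseline < 0):
        raise ValueError(
            f"binding scores must be strictly negative, got {dgw} / {baseline}"
        )
    return math.log(dgw / baseline, log_base)


def polygenic_score(terms: Mapping[str, float]) -> float:
    """Sum of the per-enzyme log-ratio terms (S_P)."""
    missing = [e for e in ENZYMES if e not in terms]
    if missing:
        raise ValueError(f"missing enzyme terms: {missing}")
    return float(sum(terms[e] for e in ENZYMES))


@dataclass(frozen=True)
class AffinityRecord:
    """Aggregated docking result for one compound."""

    id: str
    weighted: Mapping[str, float]      # enzyme -> dG_B^W
    baselines: Mapping[str, float]     # enzyme -> dG_B,sub
    terms: Mapping[str, float]         # enzyme -> log-ratio
    s_poly: float


def score_compound(
    compound_id: str,
    docking: Mapping[str, Mapping[str, float]],
    fractions: Mapping[str, float],
    baselines: SubstrateBaseline,
    log_base: float = 10.0,
) -> AffinityRecord:
    """Chain weighting, log-ratio terms and the polygenic score.

    ``docking`` maps enzyme -> {species -> dG_B}; ``fractions`` holds the
    relevant-species molar fractions (renormalized internally).
    """
    weighted, terms = {}, {}
    for enzyme in ENZYMES:
        if enzyme not in docking:
            raise ValueError(f"{compound_id}: no docking scores for {enzyme}")
        dgw = weighted_score(docking[enzyme], fractions)
        weighted[enzyme] = dgw
        terms[enzyme] = enzyme_term(dgw, baselines.scores[enzyme], log_base)
    return AffinityRecord(
        id=compound_id,
        weighted=weighted,
        baselines=dict(baselines.scores),
        terms=terms,
        s_poly=polygenic_score(terms),
    )


def psp_table(records: Sequence[AffinityRecord]) -> pd.DataFrame:
    """Long-form polygenic-score-plot table: one signed segment per enzyme.

    Negative segments mark enzymes where the derivative binds more weakly
    than the natural substrate.  Per-compound segment sums equal S_P.
    """
    rows = []
    for rec in records:
        for enzyme in ENZYMES:
            rows.append({
                "id": rec.id,
                "enzyme": enzyme,
                "term": rec.terms[enzyme],
                "s_poly": rec.s_poly,
            })
    return pd.DataFrame(rows, columns=["id", "enzyme", "term", "s_poly"])
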