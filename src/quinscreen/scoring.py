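"""Selection and elimination scores against a reference compound set.

The selection score S_sel rewards bioavailability, safety and ease of
synthesis.  It is the mean of three blocks, each on a 0-4 scale:

* ADME block — number of satisfied drug-likeness rule sets (0-5) rescaled;
* toxicity block — per endpoint, 4 * Phi(z_benefit) where z_benefit is the
  standardized deviation from the reference mean signed so that
  safer-than-reference is positive (higher LD50 is safer; lower mutagenicity,
  developmental toxicity and bioaccumulation are safer); the block is the
  mean over the four endpoints;
* SA block — synthetic accessibility 0-100 rescaled.

The elimination score S_elim is direction-agnostic: per scored property,
e_i = |x_i - mu_ref,i| / sigma_ref,i, and S_elim is the sum.  The nested
sub-scores aggregate these coefficients over growing panels: S_ADME2 (MW,
logP), S_ADME8 (+ HBD, HBA, TPSA, rotatable bonds, molar refractivity, heavy
atoms), S_ADMET (+ the four toxicity endpoints) and S_ADMETSA (+ SA).
Candidates pass the selection filter when S_sel beats both the parent
molecule and the reference-set average; survivors are ordered by ascending
S_elim (most reference-like first).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .admet import ADME2_FIELDS, ADME8_FIELDS, TOXICITY_ENDPOINTS, PropertyVector, apply_rules

__all__ = [
    "ReferenceStats",
    "ScoreRecord",
    "TOX_BENEFIT_SIGN",
    "selection_score",
    "elimination_score",
    "score_table",
    "rank_and_select",
]

#: Sign applied to (x - mu)/sigma so that positive means safer than reference.
TOX_BENEFIT_SIGN = {"ld50": +1.0, "mutagenicity": -1.0, "dev_tox": -1.0, "bf": -1.0}

#: Properties entering the elimination score, in panel order.
SCORED_PROPERTIES = ADME8_FIELDS + TOXICITY_ENDPOINTS + ("sa",)


@dataclass(frozen=True)
class ReferenceStats:
    """Per-property mean and standard deviation over the reference set."""

    means: Mapping[str, float]
    stds: Mapping[str, float]
    n_refs: int

    def __post_init__(self) -> None:
        if self.n_refs < 2:
            raise ValueError("reference set needs at least 2 compounds")
        bad = [k for k in self.stds if not self.stds[k] > 0]
        if bad:
            raise ValueError(f"degenerate (zero-spread) reference properties: {bad}")

    @classmethod
    def from_table(cls, refs: pd.DataFrame,
                   properties: Iterable[str] = SCORED_PROPERTIES) -> "ReferenceStats":
        """Build stats from a reference property table (sample std, ddof=1)."""
        props = list(properties)
        sub = refs[props].astype(float)
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"reference table has missing values in {bad}")
        means = sub.mean().to_dict()
        stds = sub.std(ddof=1).to_dict()
        degenerate = [k for k, s in stds.items() if not s > 0]
        for k in degenerate:
            del means[k], stds[k]
        return cls(means=means, stds=stds, n_refs=len(refs))


@dataclass(frozen=True)
class ScoreRecord:
    id: str
    s_sel: float
    s_elim: float
    components: Mapping[str, float]


def _require_present(p: PropertyVector, fields: Iterable[str]) -> None:
    missing = [
        f for f in fields
        if getattr(p, f) is None
        or (isinstance(getattr(p, f), float) and np.isnan(getattr(p, f)))
    ]
    if missing:
        raise ValueError(
            f"cannot score with missing properties {missing}; "
            "run the first screen upstream"
        )


def selection_score(p: PropertyVector, ref: ReferenceStats) -> float:
    """Composite desirability S_sel in [0, 4]; higher is better."""
    _require_present(p, TOXICITY_ENDPOINTS + ("sa",))
    adme_block = 4.0 * apply_rules(p).n_rules_passed / 5.0
    tox_scores = []
    for name in TOXICITY_ENDPOINTS:
        z = (getattr(p, name) - ref.means[name]) / ref.stds[name]
        tox_scores.append(4.0 * norm.cdf(TOX_BENEFIT_SIGN[name] * z))
    tox_block = float(np.mean(tox_scores))
    sa_block = 4.0 * p.sa / 100.0
    return float(np.mean([adme_block, tox_block, sa_block]))


def elimination_score(
    p: PropertyVector, ref: ReferenceStats
) -> Tuple[float, Dict[str, float]]:
    """Sum of absolute standardized deviations, with nested sub-scores.

    Returns ``(s_elim, components)``; components hold the per-property
    coefficients ``e_<prop>`` and the aggregates S_ADME2, S_ADME8, S_ADMET
    and S_ADMETSA.  S_elim equals S_ADMETSA exactly as constructed.
    """
    _require_present(p, SCORED_PROPERTIES)
    coeffs = {}
    for name in SCORED_PROPERTIES:
        if name not in ref.means:
            raise ValueError(f"reference statistics missing property {name!r}")
        coeffs[name] = abs(getattr(p, name) - ref.means[name]) / ref.stds[name]
    s_adme2 = sum(coeffs[f] for f in ADME2_FIELDS)
    s_adme8 = sum(coeffs[f] for f in ADME8_FIELDS)
    s_admet = s_adme8 + sum(coeffs[f] for f in TOXICITY_ENDPOINTS)
    s_admetsa = s_admet + coeffs["sa"]
    components = {f"e_{k}": v for k, v in coeffs.items()}
    components.update(
        S_ADME2=s_adme2, S_ADME8=s_adme8, S_ADMET=s_admet, S_ADMETSA=s_admetsa
    )
    return s_admetsa, components


def _vector_from_row(row: pd.Series) -> PropertyVector:
    fields = (
        "mw", "logp", "hbd", "hba", "tpsa", "rotb", "mr", "heavy_atoms",
        "carbons", "heteroatoms", "rings", "sa",
    ) + TOXICITY_ENDPOINTS
    kwargs = {}
    for f in fields:
        v = row.get(f, np.nan)
        kwargs[f] = None if pd.isna(v) else float(v)
    for count_field in ("hbd", "hba", "rotb", "heavy_atoms", "carbons",
                        "heteroatoms", "rings"):
        if kwargs[count_field] is not None:
            kwargs[count_field] = int(round(kwargs[count_field]))
    return PropertyVector(**kwargs)


def score_table(table: pd.DataFrame, ref: ReferenceStats) -> pd.DataFrame:
    """Score every row of a property table; returns the scores frame."""
    rows = []
    for _, row in table.iterrows():
        p = _vector_from_row(row)
        s_sel = selection_score(p, ref)
        s_elim, comps = elimination_score(p, ref)
        rows.append({
            "id": row["id"], "s_sel": s_sel, "s_elim": s_elim,
            "S_ADME2": comps["S_ADME2"], "S_ADME8": comps["S_ADME8"],
            "S_ADMET": comps["S_ADMET"], "S_ADMETSA": comps["S_ADMETSA"],
            **{k: v for k, v in comps.items() if k.startswith("e_")},
        })
    return pd.DataFrame(rows)


def rank_and_select(
    scores: pd.DataFrame,
    top_n: int,
    parent_score: float,
    reference_average: float,
) -> pd.DataFrame:
    """Filter by the two S_sel thresholds, rank by S_elim, truncate to top_n.

    A compound passes when its S_sel strictly beats both the parent
    molecule's score and the reference-set average.  Survivors are ordered
    by ascending S_elim, then descending S_sel, then id (stable ties).
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if scores.empty:
        raise ValueError("empty score table")
    passed = scores[
        (scores["s_sel"] > parent_score) & (scores["s_sel"] > reference_average)
    ].copy()
    passed["_neg_sel"] = -passed["s_sel"]
    passed = passed.sort_values(
        ["s_elim", "_neg_sel", "id"], kind="mergesort"
    ).drop(columns="_neg_sel")
    return passed.head(top_n).reset_index(drop=True)
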