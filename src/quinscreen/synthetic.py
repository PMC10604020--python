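"""Synthetic input bundles emulating the external property predictors.

The enumeration, scoring, speciation, reactivity-mapping and docking stages
consume tables that, on real projects, come from QSAR toxicity predictors,
synthetic-accessibility estimators, pKa predictors, electronic-structure
calculations and docking engines.  This module draws statistically plausible
stand-ins for all of them so the full pipeline is testable end to end:

* reference set — a dozen large neuroprotector-like molecules; the
  derivative cohort is drawn deliberately smaller (lower MW, fewer heavy
  atoms, lower refractivity), which is what makes the elimination scores
  sizable for every real derivative;
* toxicity — log-normal LD50, Beta-distributed mutagenicity/developmental
  toxicity probabilities, normal log10 bioaccumulation factor; derivatives
  are drawn slightly safer on LD50 and developmental toxicity than the
  reference set, with a wide bioaccumulation spread;
* a configurable per-compound missing-toxicity rate feeds the first screen;
* 0-3 stepwise pKa values per compound in 2-12 (values below 7 are treated
  as basic-site protonations when assigning species charges);
* per-species ionization potentials and bond dissociation energies drawn
  from ranges bracketing the synthetic reference panel;
* negative per-species, per-enzyme docking scores.

``plant_known_winners`` additionally rewrites *k* compounds so that, by
construction, they beat both selection-score thresholds, dominate Trolox in
both antioxidant mechanisms and carry a positive polygenic score; their ids
form the answer key for end-to-end recovery tests.  Planting margins are
applied in standardized (z) or energy space and clipped to physically
plausible ranges, so scaling them up saturates instead of producing
impossible values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .admet import PROPERTY_COLUMNS, TOXICITY_ENDPOINTS, compute_descriptors
from .affinity import ENZYMES, SYNTHETIC_SUBSTRATE_BASELINES, SubstrateBaseline
from .ehdama import H_DONOR_SITES, SYNTHETIC_REFERENCE_PANEL, ReferencePanel
from .scaffold import canonicalize
from .speciation import species_label

__all__ = ["SimulationConfig", "CohortBundle", "simulate_cohort", "plant_known_winners"]

QUINOLINE_SMILES = "c1ccc2ncccc2c1"
#: Experimental quinolinium pKa is close to 4.9; used for the parent ladder.
PARENT_PKA = 4.85

#: (mean, sd) of the reference-set property distributions: large, polar,
#: synthetically demanding neuroprotector-like molecules.
REFERENCE_DISTRIBUTIONS: Dict[str, Tuple[float, float]] = {
    "mw": (320.0, 45.0), "logp": (3.0, 1.2), "hbd": (2.0, 1.0),
    "hba": (5.0, 1.5), "tpsa": (75.0, 20.0), "rotb": (6.0, 2.0),
    "mr": (95.0, 12.0), "heavy_atoms": (23.0, 4.0), "carbons": (18.0, 3.0),
    "heteroatoms": (5.0, 1.5), "rings": (3.0, 1.0), "sa": (40.0, 12.0),
}

#: (mean, sd) of the derivative-cohort descriptor draws: small decorated
#: bicyclics, systematically below the reference set in size.
DERIVATIVE_DISTRIBUTIONS: Dict[str, Tuple[float, float]] = {
    "mw": (210.0, 35.0), "logp": (1.8, 0.9), "hbd": (1.2, 0.9),
    "hba": (2.8, 1.0), "tpsa": (45.0, 15.0), "rotb": (2.0, 1.2),
    "mr": (60.0, 10.0), "heavy_atoms": (16.0, 3.0), "carbons": (11.0, 2.0),
    "heteroatoms": (3.0, 1.0), "rings": (2.0, 0.0), "sa": (70.0, 12.0),
}

_COUNT_FIELDS = ("hbd", "hba", "rotb", "heavy_atoms", "carbons",
                 "heteroatoms", "rings")

# Hard caps on planting margins (z units / kcal/mol / ratio), so that scaled
# margins stay inside physically plausible ranges.
_TOX_MARGIN_CAP_Z = 1.5
_SA_MARGIN_CAP_Z = 2.5
_REACTIVITY_MARGIN_CAP = 12.0
_DOCKING_MARGIN_CAP = 0.8


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_compounds: int = 8358
    n_refs: int = 12
    missing_tox_rate: float = 0.24
    ph: float = 7.4
    relevance_threshold: float = 0.01
    # endpoint draw parameters
    ld50_ref_logmean: float = float(np.log(700.0))
    ld50_ref_logsd: float = 0.6
    ld50_drv_logmean: float = float(np.log(800.0))
    ld50_drv_logsd: float = 0.5
    pka_count_probs: Tuple[float, ...] = (0.15, 0.35, 0.35, 0.15)
    pka_range: Tuple[float, float] = (2.0, 12.0)
    ip_range: Tuple[float, float] = (75.0, 115.0)
    bde_range: Tuple[float, float] = (70.0, 95.0)
    dg_range: Tuple[float, float] = (-11.0, -4.0)
    # planting margins (scaled by margin_scale, then clipped)
    tox_margin_z: float = 0.5
    sa_margin_z: float = 2.0
    reactivity_margin: float = 2.0   # kcal/mol below Trolox
    docking_margin: float = 0.15     # fractional strengthening vs substrate
    margin_scale: float = 1.0

    def validate(self) -> None:
        problems = []
        if self.n_compounds < 1:
            problems.append("n_compounds must be >= 1")
        if self.n_refs < 2:
            problems.append("n_refs must be >= 2")
        if not 0.0 <= self.missing_tox_rate <= 1.0:
            problems.append("missing_tox_rate must lie in [0, 1]")
        if abs(sum(self.pka_count_probs) - 1.0) > 1e-9:
            problems.append("pka_count_probs must sum to 1")
        for name in ("pka_range", "ip_range", "bde_range", "dg_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                problems.append(f"{name} must be ordered (lo < hi)")
        if self.dg_range[1] >= 0:
            problems.append("docking scores must be negative")
        if self.margin_scale <= 0:
            problems.append("margin_scale must be positive")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class CohortBundle:
    """All synthetic inputs of one pipeline run."""

    properties: pd.DataFrame   # property-table schema, parent row included
    reference: pd.DataFrame    # same schema, no missing values
    pkas: pd.DataFrame         # id, pka1..pka3 (blank = absent), n_basic
    reactivity: pd.DataFrame   # id, species, ip, site, bde (long form)
    docking: pd.DataFrame      # id, species, enzyme, dg_kcal_mol
    panel: ReferencePanel
    baselines: SubstrateBaseline
    config: SimulationConfig
    parent_id: str = "dQ1"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.properties.to_csv(outdir / "properties.csv", index=False)
        self.reference.to_csv(outdir / "reference.csv", index=False)
        self.pkas.to_csv(outdir / "pkas.csv", index=False)
        self.reactivity.to_csv(outdir / "reactivity.csv", index=False)
        self.docking.to_csv(outdir / "docking.csv", index=False)
        refs = {
            name: {"ip": rec.ip, "bde_by_site": dict(rec.bde_by_site)}
            for name, rec in {
                "trolox": self.panel.trolox,
                "alpha_tocopherol": self.panel.alpha_tocopherol,
                "ascorbate": self.panel.ascorbate,
                "ooh_target": self.panel.ooh_target,
            }.items()
        }
        meta = {
            "parent_id": self.parent_id,
            "ph": self.config.ph,
            "relevance_threshold": self.config.relevance_threshold,
            "reference_panel": refs,
            "substrate_baselines": dict(self.baselines.scores),
        }
        (outdir / "bundle.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def _draw_properties(
    rng: np.random.Generator,
    ids: Sequence[str],
    dists: Mapping[str, Tuple[float, float]],
    ld50_logmean: float,
    ld50_logsd: float,
    mut_beta: Tuple[float, float],
    dev_beta: Tuple[float, float],
    bf_params: Tuple[float, float],
) -> pd.DataFrame:
    n = len(ids)
    cols: Dict[str, np.ndarray] = {"id": np.asarray(ids, dtype=object)}
    for name, (mean, sd) in dists.items():
        if name == "sa":
            continue
        vals = rng.normal(mean, sd, n) if sd > 0 else np.full(n, mean)
        if name in _COUNT_FIELDS:
            vals = np.clip(np.rint(vals), 0, None)
        elif name in ("mw", "tpsa", "mr"):
            vals = np.clip(vals, 1.0, None)
        cols[name] = vals
    cols["sa"] = np.clip(rng.normal(*dists["sa"], n), 1.0, 99.0)
    cols["ld50"] = np.exp(rng.normal(ld50_logmean, ld50_logsd, n))
    cols["mutagenicity"] = rng.beta(*mut_beta, n)
    cols["dev_tox"] = rng.beta(*dev_beta, n)
    cols["bf"] = rng.normal(*bf_params, n)
    return pd.DataFrame(cols)[PROPERTY_COLUMNS]


def _draw_pka_ladder(rng: np.random.Generator, count: int,
                     lo: float, hi: float) -> List[float]:
    """Strictly ascending pKa values with at least 0.5 units of separation."""
    for _ in range(50):
        vals = np.sort(rng.uniform(lo, hi, count))
        if count < 2 or np.all(np.diff(vals) >= 0.5):
            return [round(float(v), 2) for v in vals]
    vals = np.sort(rng.uniform(lo, hi, count))
    vals = vals + np.arange(count) * 0.5  # force separation; may exceed hi
    return [round(float(v), 2) for v in vals]


def _species_of(compound_id: str, pkas: Sequence[float], n_basic: int) -> List[str]:
    return [species_label(compound_id, n_basic - j) for j in range(len(pkas) + 1)]


def simulate_cohort(cfg: SimulationConfig) -> CohortBundle:
    """Draw a complete, reproducible synthetic input bundle."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    ref_ids = [f"ref{i + 1}" for i in range(cfg.n_refs)]
    reference = _draw_properties(
        rng, ref_ids, REFERENCE_DISTRIBUTIONS,
        cfg.ld50_ref_logmean, cfg.ld50_ref_logsd,
        mut_beta=(2.0, 3.0), dev_beta=(2.0, 3.0), bf_params=(1.0, 0.8),
    )

    ids = [f"dQ{i + 2}" for i in range(cfg.n_compounds)]
    props = _draw_properties(
        rng, ids, DERIVATIVE_DISTRIBUTIONS,
        cfg.ld50_drv_logmean, cfg.ld50_drv_logsd,
        mut_beta=(2.0, 2.5), dev_beta=(1.5, 4.0), bf_params=(0.6, 0.9),
    )

    # Parent: real quinoline descriptors, easy synthesis, modestly less safe
    # than the reference set (it is the most atypical molecule of the cohort).
    parent_vec = compute_descriptors(canonicalize(QUINOLINE_SMILES))
    ref_mu = reference.set_index("id").mean()
    ref_sd = reference.set_index("id").std(ddof=1)
    parent_row = {
        "id": "dQ1",
        **{f: getattr(parent_vec, f) for f in (
            "mw", "logp", "hbd", "hba", "tpsa", "rotb", "mr",
            "heavy_atoms", "carbons", "heteroatoms", "rings")},
        "sa": 85.0,
        "ld50": float(ref_mu["ld50"] - 0.5 * ref_sd["ld50"]),
        "mutagenicity": float(np.clip(ref_mu["mutagenicity"]
                                      + 0.5 * ref_sd["mutagenicity"], 0.001, 0.999)),
        "dev_tox": float(np.clip(ref_mu["dev_tox"]
                                 + 0.5 * ref_sd["dev_tox"], 0.001, 0.999)),
        "bf": float(ref_mu["bf"] + 0.5 * ref_sd["bf"]),
    }
    properties = pd.concat(
        [pd.DataFrame([parent_row])[PROPERTY_COLUMNS], props], ignore_index=True
    )

    # Missingness: a compound is hit with probability missing_tox_rate, and
    # then loses a uniformly chosen non-empty subset of the four endpoints.
    hit = rng.random(cfg.n_compounds) < cfg.missing_tox_rate
    subset_codes = rng.integers(1, 16, cfg.n_compounds)  # bitmask over 4 endpoints
    for row_offset, (is_hit, code) in enumerate(zip(hit, subset_codes)):
        if not is_hit:
            continue
        for bit, endpoint in enumerate(TOXICITY_ENDPOINTS):
            if code >> bit & 1:
                properties.iloc[row_offset + 1,
                                properties.columns.get_loc(endpoint)] = np.nan

    # pKa ladders; the parent keeps the quinolinium protonation.
    pka_counts = rng.choice(len(cfg.pka_count_probs), cfg.n_compounds,
                            p=cfg.pka_count_probs)
    pka_rows = [{"id": "dQ1", "pka1": PARENT_PKA, "pka2": np.nan,
                 "pka3": np.nan, "n_basic": 1}]
    ladders: Dict[str, Tuple[List[float], int]] = {"dQ1": ([PARENT_PKA], 1)}
    for cid, count in zip(ids, pka_counts):
        vals = _draw_pka_ladder(rng, int(count), *cfg.pka_range)
        n_basic = sum(1 for v in vals if v < 7.0)
        row = {"id": cid, "pka1": np.nan, "pka2": np.nan, "pka3": np.nan,
               "n_basic": n_basic}
        for i, v in enumerate(vals):
            row[f"pka{i + 1}"] = v
        pka_rows.append(row)
        ladders[cid] = (vals, n_basic)
    pkas = pd.DataFrame(pka_rows, columns=["id", "pka1", "pka2", "pka3", "n_basic"])

    # Per-species reactivity (the parent has no sp3 H-donor site and is
    # deliberately absent) and docking scores for every species.
    react_rows, dock_rows = [], []
    for cid in ["dQ1"] + ids:
        vals, n_basic = ladders[cid]
        for label in _species_of(cid, vals, n_basic):
            if cid != "dQ1":
                n_sites = int(rng.integers(1, 3))
                sites = rng.choice(len(H_DONOR_SITES), n_sites, replace=False)
                ip = float(rng.uniform(*cfg.ip_range))
                for s in sorted(sites):
                    react_rows.append({
                        "id": cid, "species": label, "ip": ip,
                        "site": H_DONOR_SITES[s],
                        "bde": float(rng.uniform(*cfg.bde_range)),
                    })
            for enzyme in ENZYMES:
                dock_rows.append({
                    "id": cid, "species": label, "enzyme": enzyme,
                    "dg_kcal_mol": float(rng.uniform(*cfg.dg_range)),
                })
    reactivity = pd.DataFrame(react_rows,
                              columns=["id", "species", "ip", "site", "bde"])
    docking = pd.DataFrame(dock_rows,
                           columns=["id", "species", "enzyme", "dg_kcal_mol"])

    return CohortBundle(
        properties=properties, reference=reference, pkas=pkas,
        reactivity=reactivity, docking=docking,
        panel=SYNTHETIC_REFERENCE_PANEL,
        baselines=SYNTHETIC_SUBSTRATE_BASELINES,
        config=cfg,
    )


def plant_known_winners(
    cfg: SimulationConfig, k: int
) -> Tuple[CohortBundle, List[str]]:
    """Simulate a cohort and rewrite ``k`` compounds into known winners.

    The planted compounds sit exactly at the reference descriptor centroid
    (zero ADME deviation, all rule sets satisfied), carry a clipped
    toxicity-safety and synthetic-accessibility margin, dominate Trolox in
    both antioxidant mechanisms, and bind every enzyme more strongly than
    its natural substrate.  Returns the bundle and the planted ids.
    """
    cfg.validate()
    if not 0 <= k < cfg.n_compounds:
        raise ValueError(f"k must lie in [0, n_compounds); got {k}")
    bundle = simulate_cohort(cfg)
    if k == 0:
        return bundle, []

    rng = np.random.default_rng([cfg.seed, 1])
    candidates = [i for i in bundle.properties["id"] if i != bundle.parent_id]
    planted = sorted(rng.choice(candidates, k, replace=False).tolist())

    tox_z = min(cfg.tox_margin_z * cfg.margin_scale, _TOX_MARGIN_CAP_Z)
    sa_z = min(cfg.sa_margin_z * cfg.margin_scale, _SA_MARGIN_CAP_Z)
    react_margin = min(cfg.reactivity_margin * cfg.margin_scale,
                       _REACTIVITY_MARGIN_CAP)
    dock_margin = min(cfg.docking_margin * cfg.margin_scale, _DOCKING_MARGIN_CAP)

    ref = bundle.reference.drop(columns="id")
    mu, sd = ref.mean(), ref.std(ddof=1)
    props = bundle.properties.set_index("id")
    descriptor_fields = [c for c in PROPERTY_COLUMNS
                         if c not in ("id", "sa") + TOXICITY_ENDPOINTS]
    for cid in planted:
        for f in descriptor_fields:
            props.loc[cid, f] = mu[f]
        props.loc[cid, "sa"] = float(np.clip(mu["sa"] + sa_z * sd["sa"], 1.0, 99.0))
        props.loc[cid, "ld50"] = float(mu["ld50"] + tox_z * sd["ld50"])
        props.loc[cid, "mutagenicity"] = float(
            np.clip(mu["mutagenicity"] - tox_z * sd["mutagenicity"], 0.001, 0.999))
        props.loc[cid, "dev_tox"] = float(
            np.clip(mu["dev_tox"] - tox_z * sd["dev_tox"], 0.001, 0.999))
        props.loc[cid, "bf"] = float(mu["bf"] - tox_z * sd["bf"])
    bundle.properties = props.reset_index()[PROPERTY_COLUMNS]

    # single neutral species, Trolox-dominating reactivity, uniformly
    # stronger-than-substrate docking
    trolox = bundle.panel.trolox
    keep = ~bundle.pkas["id"].isin(planted)
    planted_pka = pd.DataFrame(
        [{"id": cid, "pka1": np.nan, "pka2": np.nan, "pka3": np.nan,
          "n_basic": 0} for cid in planted]
    )
    bundle.pkas = pd.concat([bundle.pkas[keep], planted_pka], ignore_index=True)

    bundle.reactivity = bundle.reactivity[~bundle.reactivity["id"].isin(planted)]
    react_rows = [{
        "id": cid, "species": cid, "ip": trolox.ip - react_margin,
        "site": "phenol_OH", "bde": trolox.bde_min - react_margin,
    } for cid in planted]
    bundle.reactivity = pd.concat(
        [bundle.reactivity, pd.DataFrame(react_rows)], ignore_index=True)

    bundle.docking = bundle.docking[~bundle.docking["id"].isin(planted)]
    dock_rows = [{
        "id": cid, "species": cid, "enzyme": enzyme,
        "dg_kcal_mol": bundle.baselines.scores[enzyme] * (1.0 + dock_margin),
    } for cid in planted for enzyme in ENZYMES]
    bundle.docking = pd.concat(
        [bundle.docking, pd.DataFrame(dock_rows)], ignore_index=True)

    return bundle, planted
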