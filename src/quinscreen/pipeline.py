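"""End-to-end orchestration: screen -> score -> select -> speciate ->
antioxidant map -> docking aggregation -> proposals.

The stages communicate through the tabular bundle (:class:`CohortBundle`),
so each one can also be re-run individually from CSV files.  A run report
carries per-stage counts, the selected candidates, the final proposal list
(selected compounds that dominate Trolox via both antioxidant mechanisms and
out-bind all three natural substrates) and a manifest of input hashes and
parameters for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .admet import first_screen
from .affinity import (ENZYMES, AffinityRecord, SubstrateBaseline,
                       psp_table, score_compound)
from .ehdama import (ReactivityRecord, ReferencePanel, SpeciesClassification,
                     best_species_classification, build_map, classify_species)
from .scoring import ReferenceStats, rank_and_select, score_table
from .speciation import relevant_species, species_fractions
from .synthetic import CohortBundle, SimulationConfig

logger = logging.getLogger("quinscreen")

__all__ = ["RunReport", "run_pipeline", "read_bundle"]


@dataclass
class RunReport:
    """Outcome of one pipeline run."""

    status: str
    counts: Dict[str, int]
    scores: Optional[pd.DataFrame] = None
    selected: Optional[pd.DataFrame] = None
    speciation: Optional[pd.DataFrame] = None
    ehdama_map: Optional[pd.DataFrame] = None
    affinity: Optional[pd.DataFrame] = None
    psp: Optional[pd.DataFrame] = None
    proposals: List[str] = field(default_factory=list)
    thresholds: Dict[str, float] = field(default_factory=dict)
    manifest: Dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("scores", "selected", "speciation", "ehdama_map",
                     "affinity", "psp"):
            frame = getattr(self, name)
            if frame is not None:
                frame.to_csv(outdir / f"{name}.csv", index=False)
        payload = {
            "status": self.status,
            "counts": self.counts,
            "thresholds": self.thresholds,
            "proposals": self.proposals,
            "manifest": self.manifest,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))


def _hash_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()


def _build_manifest(bundle: CohortBundle, params: Mapping[str, float]) -> Dict[str, str]:
    manifest = {
        f"sha256_{name}": _hash_frame(getattr(bundle, name))
        for name in ("properties", "reference", "pkas", "reactivity", "docking")
    }
    manifest["parameters"] = json.dumps(dict(params), sort_keys=True)
    return manifest


def run_pipeline(
    bundle: CohortBundle,
    top_n: int = 25,
    ph: float = 7.4,
    relevance_threshold: float = 0.01,
) -> RunReport:
    """Run every stage on a cohort bundle and return the report.

    Stage order: missing-toxicity screen, selection/elimination scoring with
    thresholds at the parent molecule and the reference-set average,
    truncation to the ``top_n`` least-deviant survivors, speciation of the
    survivors at ``ph``, antioxidant classification of their relevant
    species, docking aggregation, and the final proposal list.
    """
    params = {"top_n": top_n, "ph": ph,
              "relevance_threshold": relevance_threshold}
    manifest = _build_manifest(bundle, params)
    counts: Dict[str, int] = {"built": len(bundle.properties)}

    kept, dropped = first_screen(bundle.properties)
    counts["screened_out"] = len(dropped)
    counts["kept"] = len(kept)
    logger.info("first screen: kept %d, dropped %d", len(kept), len(dropped))
    if kept.empty:
        return RunReport(status="empty cohort", counts=counts, manifest=manifest)

    ref_stats = ReferenceStats.from_table(bundle.reference)
    scores = score_table(kept, ref_stats)
    ref_scores = score_table(bundle.reference, ref_stats)
    reference_average = float(ref_scores["s_sel"].mean())
    parent_rows = scores[scores["id"] == bundle.parent_id]
    if parent_rows.empty:
        raise ValueError(
            f"parent compound {bundle.parent_id!r} missing after the first screen"
        )
    parent_score = float(parent_rows["s_sel"].iloc[0])
    thresholds = {"parent_s_sel": parent_score,
                  "reference_average_s_sel": reference_average}

    selected = rank_and_select(scores, top_n, parent_score, reference_average)
    counts["passed_selection"] = int(
        ((scores["s_sel"] > parent_score)
         & (scores["s_sel"] > reference_average)).sum()
    )
    counts["selected"] = len(selected)
    logger.info("selection: %d beat both thresholds, %d retained",
                counts["passed_selection"], counts["selected"])
    if selected.empty:
        return RunReport(status="empty selection", counts=counts, scores=scores,
                         selected=selected, thresholds=thresholds,
                         manifest=manifest)

    # speciation of the selected candidates
    pka_table = bundle.pkas.set_index("id")
    spec_rows = []
    profiles = {}
    for cid in selected["id"]:
        row = pka_table.loc[cid]
        ladder = [row[f"pka{i}"] for i in (1, 2, 3) if pd.notna(row.get(f"pka{i}"))]
        profile = species_fractions(ladder, ph=ph, compound_id=cid,
                                    n_basic=int(row.get("n_basic", 0)))
        profiles[cid] = profile
        relevant = set(relevant_species(profile, relevance_threshold))
        for label, charge in zip(profile.species, profile.charges):
            spec_rows.append({
                "id": cid, "species": label, "charge": charge,
                "fraction": profile.fractions[label],
                "relevant": int(label in relevant),
            })
    speciation = pd.DataFrame(spec_rows)
    counts["relevant_species"] = int(speciation["relevant"].sum())

    # antioxidant classification of relevant species with H-donor sites
    relevant_set = {
        (r["id"], r["species"]) for _, r in speciation.iterrows() if r["relevant"]
    }
    react = bundle.reactivity[bundle.reactivity["id"].isin(selected["id"])]
    if not react.empty:
        react = react[react.apply(
            lambda r: (r["id"], r["species"]) in relevant_set, axis=1
        )]
    records: List[ReactivityRecord] = []
    for (cid, label), grp in react.groupby(["id", "species"], sort=True):
        records.append(ReactivityRecord(
            id=cid, species=label, ip=float(grp["ip"].iloc[0]),
            bde_by_site={r["site"]: float(r["bde"]) for _, r in grp.iterrows()},
        ))
    ehdama_map = build_map(records, bundle.panel)
    by_compound: Dict[str, List[SpeciesClassification]] = {}
    for rec in records:
        by_compound.setdefault(rec.id, []).append(
            classify_species(rec, bundle.panel)
        )
    best = {cid: best_species_classification(cls)
            for cid, cls in by_compound.items()}
    counts["classified_species"] = len(records)

    # docking aggregation over relevant species
    dock = bundle.docking[bundle.docking["id"].isin(selected["id"])]
    affinity_records: List[AffinityRecord] = []
    for cid in selected["id"]:
        profile = profiles[cid]
        relevant = [s for s in profile.species if (cid, s) in relevant_set]
        sub = dock[(dock["id"] == cid) & (dock["species"].isin(relevant))]
        if sub.empty:
            continue
        per_enzyme = {
            enzyme: {
                r["species"]: float(r["dg_kcal_mol"])
                for _, r in sub[sub["enzyme"] == enzyme].iterrows()
            }
            for enzyme in ENZYMES
        }
        if any(not d for d in per_enzyme.values()):
            continue
        affinity_records.append(score_compound(
            cid, per_enzyme, profile.fractions, bundle.baselines
        ))
    affinity = pd.DataFrame([
        {"id": rec.id,
         **{f"dgw_{e}": rec.weighted[e] for e in ENZYMES},
         **{f"term_{e}": rec.terms[e] for e in ENZYMES},
         "s_poly": rec.s_poly}
        for rec in affinity_records
    ])
    psp = psp_table(affinity_records)
    counts["docked"] = len(affinity_records)

    s_poly = {rec.id: rec.s_poly for rec in affinity_records}
    proposals = [
        cid for cid in selected["id"]
        if best.get(cid) is not None
        and best[cid].dominates("trolox")
        and s_poly.get(cid, float("-inf")) > 0
    ]
    counts["proposed"] = len(proposals)
    logger.info("proposals: %d candidates dominate Trolox and out-bind the "
                "substrates", len(proposals))

    return RunReport(
        status="ok", counts=counts, scores=scores, selected=selected,
        speciation=speciation, ehdama_map=ehdama_map, affinity=affinity,
        psp=psp, proposals=proposals, thresholds=thresholds, manifest=manifest,
    )


def read_bundle(indir: str | Path) -> CohortBundle:
    """Load a bundle previously written by :meth:`CohortBundle.write`."""
    indir = Path(indir)
    meta = yaml.safe_load((indir / "bundle.yaml").read_text())
    refs = meta["reference_panel"]

    def _rec(name: str) -> ReactivityRecord:
        entry = refs[name]
        return ReactivityRecord(id=name, species=name, ip=float(entry["ip"]),
                                bde_by_site=dict(entry["bde_by_site"]))

    panel = ReferencePanel(
        trolox=_rec("trolox"),
        alpha_tocopherol=_rec("alpha_tocopherol"),
        ascorbate=_rec("ascorbate"),
        ooh_target=_rec("ooh_target"),
    )
    baselines = SubstrateBaseline(scores={
        e: float(v) for e, v in meta["substrate_baselines"].items()
    })
    cfg = SimulationConfig(ph=float(meta["ph"]),
                           relevance_threshold=float(meta["relevance_threshold"]))
    return CohortBundle(
        properties=pd.read_csv(indir / "properties.csv"),
        reference=pd.read_csv(indir / "reference.csv"),
        pkas=pd.read_csv(indir / "pkas.csv"),
        reactivity=pd.read_csv(indir / "reactivity.csv"),
        docking=pd.read_csv(indir / "docking.csv"),
        panel=panel,
        baselines=baselines,
        config=cfg,
        parent_id=meta.get("parent_id", "dQ1"),
    )
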