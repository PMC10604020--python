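"""Synthetic cohort generation: determinism, schemas, planting."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.stats import binom

from quinscreen.admet import TOXICITY_ENDPOINTS, first_screen
from quinscreen.ehdama import classify_species, ReactivityRecord
from quinscreen.pipeline import run_pipeline
from quinscreen.synthetic import (
    SimulationConfig,
    plant_known_winners,
    simulate_cohort,
)


class TestConfig:
    def test_validation_lists_fields(self):
        cfg = SimulationConfig(n_compounds=0, missing_tox_rate=1.5)
        with pytest.raises(ValueError) as err:
            cfg.validate()
        assert "n_compounds" in str(err.value)
        assert "missing_tox_rate" in str(err.value)

    def test_ranges_must_be_ordered(self):
        with pytest.raises(ValueError, match="ip_range"):
            SimulationConfig(ip_range=(115.0, 75.0)).validate()


class TestSimulateCohort:
    def test_same_seed_identical_bundles(self, small_cfg):
        a = simulate_cohort(small_cfg)
        b = simulate_cohort(small_cfg)
        for name in ("properties", "reference", "pkas", "reactivity", "docking"):
            assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self, small_cfg):
        a = simulate_cohort(small_cfg)
        b = simulate_cohort(SimulationConfig(seed=small_cfg.seed + 1,
                                             n_compounds=small_cfg.n_compounds))
        assert not a.properties.equals(b.properties)

    def test_zero_missing_rate_drops_nothing(self):
        cfg = SimulationConfig(seed=1, n_compounds=200, missing_tox_rate=0.0)
        bundle = simulate_cohort(cfg)
        kept, dropped = first_screen(bundle.properties)
        assert dropped.empty and len(kept) == 201  # cohort + parent

    def test_missing_rate_within_binomial_band(self):
        n, rate = 3000, 0.3
        cfg = SimulationConfig(seed=2, n_compounds=n, missing_tox_rate=rate)
        _, dropped = first_screen(simulate_cohort(cfg).properties)
        lo, hi = binom.ppf([0.005, 0.995], n, rate)
        assert lo <= len(dropped) <= hi

    def test_schema_invariants(self, small_cfg):
        """Generated tables satisfy every downstream type invariant."""
        bundle = simulate_cohort(small_cfg)
        props = bundle.properties
        # probabilities, SA scale, positive LD50 where present
        for col, lo, hi in (("mutagenicity", 0, 1), ("dev_tox", 0, 1),
                            ("sa", 0, 100)):
            vals = props[col].dropna()
            assert ((vals >= lo) & (vals <= hi)).all()
        assert (props["ld50"].dropna() > 0).all()
        for col in ("hbd", "hba", "rotb", "heavy_atoms", "carbons",
                    "heteroatoms", "rings"):
            assert (props[col] >= 0).all()
        # reference table complete
        assert not bundle.reference.isna().any().any()
        # pKa ladders strictly ascending within 0-3 values
        for _, row in bundle.pkas.iterrows():
            ladder = [row[f"pka{i}"] for i in (1, 2, 3)
                      if pd.notna(row[f"pka{i}"])]
            assert all(b > a for a, b in zip(ladder, ladder[1:]))
            assert len(ladder) <= 3
        # docking strictly negative, all three enzymes present per species
        assert (bundle.docking["dg_kcal_mol"] < 0).all()
        per_species = bundle.docking.groupby(["id", "species"])["enzyme"].nunique()
        assert (per_species == 3).all()
        # reactivity sites drawn from the declared inventory
        assert set(bundle.reactivity["site"]).issubset(
            {"phenol_OH", "amine_NH", "thiol_SH", "ester_CH3"}
        )

    def test_parent_row(self, small_cfg):
        bundle = simulate_cohort(small_cfg)
        parent = bundle.properties[bundle.properties["id"] == "dQ1"].iloc[0]
        # real quinoline descriptors, complete toxicity
        assert parent["mw"] == pytest.approx(129.16, abs=0.01)
        assert parent["rings"] == 2
        assert not any(pd.isna(parent[t]) for t in TOXICITY_ENDPOINTS)
        # no H-donor sites on the bare scaffold
        assert "dQ1" not in set(bundle.reactivity["id"])

    def test_write_round_trip(self, small_cfg, tmp_path):
        from quinscreen.pipeline import read_bundle

        bundle = simulate_cohort(small_cfg)
        bundle.write(tmp_path / "bundle")
        loaded = read_bundle(tmp_path / "bundle")
        assert_frame_equal(bundle.properties, loaded.properties)
        assert loaded.panel.trolox.ip == bundle.panel.trolox.ip
        assert loaded.baselines.scores == dict(bundle.baselines.scores)


class TestPlanting:
    def test_zero_planted(self, small_cfg):
        bundle, key = plant_known_winners(small_cfg, 0)
        assert key == []

    def test_answer_key_ids_exist(self, small_cfg):
        bundle, key = plant_known_winners(small_cfg, 4)
        assert len(key) == 4
        assert set(key) <= set(bundle.properties["id"])
        assert "dQ1" not in key

    def test_planted_dominate_trolox(self, small_cfg):
        bundle, key = plant_known_winners(small_cfg, 3)
        for cid in key:
            rows = bundle.reactivity[bundle.reactivity["id"] == cid]
            rec = ReactivityRecord(
                id=cid, species=rows["species"].iloc[0],
                ip=float(rows["ip"].iloc[0]),
                bde_by_site={r["site"]: float(r["bde"])
                             for _, r in rows.iterrows()},
            )
            assert classify_species(rec, bundle.panel).dominates("trolox")

    def test_planted_outbind_substrates(self, small_cfg):
        bundle, key = plant_known_winners(small_cfg, 3)
        for cid in key:
            rows = bundle.docking[bundle.docking["id"] == cid]
            for _, r in rows.iterrows():
                assert r["dg_kcal_mol"] < bundle.baselines.scores[r["enzyme"]]

    def test_recovery_small_cohort(self, small_cfg):
        bundle, key = plant_known_winners(small_cfg, 4)
        report = run_pipeline(bundle)
        assert set(key) <= set(report.proposals)

    def test_recovery_with_scaled_margins(self, small_cfg):
        """Margins x10 saturate at plausible bounds and stay recoverable."""
        import dataclasses

        cfg = dataclasses.replace(small_cfg, margin_scale=10.0)
        bundle, key = plant_known_winners(cfg, 4)
        sa = bundle.properties.set_index("id").loc[key, "sa"]
        assert (sa <= 99.0).all()
        probs = bundle.properties.set_index("id").loc[
            key, ["mutagenicity", "dev_tox"]]
        assert ((probs >= 0) & (probs <= 1)).all().all()
        report = run_pipeline(bundle)
        assert set(key) <= set(report.proposals)

    def test_k_validation(self, small_cfg):
        with pytest.raises(ValueError):
            plant_known_winners(small_cfg, small_cfg.n_compounds)
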