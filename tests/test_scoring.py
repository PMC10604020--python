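"""Selection and elimination scores against the reference set."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from quinscreen.admet import TOXICITY_ENDPOINTS
from quinscreen.scoring import (
    SCORED_PROPERTIES,
    ReferenceStats,
    elimination_score,
    rank_and_select,
    score_table,
    selection_score,
)


class TestElimination:
    def test_centroid_is_zero(self, centroid_vector, ref_stats):
        s_elim, comps = elimination_score(centroid_vector, ref_stats)
        assert s_elim == pytest.approx(0.0, abs=1e-12)
        assert all(abs(v) < 1e-12 for v in comps.values())

    def test_unit_deviation(self, centroid_vector, ref_stats):
        p = dataclasses.replace(
            centroid_vector, mw=ref_stats.means["mw"] + ref_stats.stds["mw"]
        )
        s_elim, comps = elimination_score(p, ref_stats)
        assert s_elim == pytest.approx(1.0, abs=1e-12)
        assert comps["e_mw"] == pytest.approx(1.0)

    def test_direction_agnostic(self, centroid_vector, ref_stats):
        up = dataclasses.replace(centroid_vector, logp=ref_stats.means["logp"] + 2.0)
        down = dataclasses.replace(centroid_vector, logp=ref_stats.means["logp"] - 2.0)
        assert elimination_score(up, ref_stats)[0] == pytest.approx(
            elimination_score(down, ref_stats)[0]
        )

    def test_matches_z_score_oracle(self, centroid_vector, ref_stats):
        """S_elim equals an independently computed sum of |z| values."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            values = {
                name: ref_stats.means[name] + rng.normal(0, 2) * ref_stats.stds[name]
                for name in SCORED_PROPERTIES
            }
            p = dataclasses.replace(centroid_vector, **values)
            expected = sum(
                abs(values[n] - ref_stats.means[n]) / ref_stats.stds[n]
                for n in SCORED_PROPERTIES
            )
            s_elim, comps = elimination_score(p, ref_stats)
            assert s_elim == pytest.approx(expected, abs=1e-9)
            # nested panels: S_ADMETSA = S_ADMET + SA coefficient exactly
            assert comps["S_ADMETSA"] == comps["S_ADMET"] + comps["e_sa"]
            assert comps["S_ADMET"] == pytest.approx(
                comps["S_ADME8"]
                + sum(comps[f"e_{t}"] for t in TOXICITY_ENDPOINTS),
                abs=1e-12,
            )
            assert s_elim == pytest.approx(
                sum(comps[f"e_{n}"] for n in SCORED_PROPERTIES), abs=1e-9
            )

    def test_linear_scaling(self, centroid_vector, ref_stats):
        p1 = dataclasses.replace(
            centroid_vector,
            mw=ref_stats.means["mw"] + 10, tpsa=ref_stats.means["tpsa"] + 5,
        )
        p3 = dataclasses.replace(
            centroid_vector,
            mw=ref_stats.means["mw"] + 30, tpsa=ref_stats.means["tpsa"] + 15,
        )
        assert elimination_score(p3, ref_stats)[0] == pytest.approx(
            3 * elimination_score(p1, ref_stats)[0]
        )

    def test_refuses_missing(self, centroid_vector, ref_stats):
        p = dataclasses.replace(centroid_vector, ld50=None)
        with pytest.raises(ValueError, match="ld50"):
            elimination_score(p, ref_stats)


class TestSelection:
    def test_hand_computed(self, centroid_vector, ref_stats):
        """Spreadsheet-style recomputation of the three-block score."""
        p = dataclasses.replace(
            centroid_vector,
            ld50=ref_stats.means["ld50"] + 1.0 * ref_stats.stds["ld50"],
            mutagenicity=ref_stats.means["mutagenicity"]
            - 0.5 * ref_stats.stds["mutagenicity"],
            sa=80.0,
        )
        # the centroid descriptor block passes all five rule sets
        adme_block = 4.0
        tox_block = np.mean([
            4 * norm.cdf(1.0),    # ld50: one sd safer
            4 * norm.cdf(0.5),    # mutagenicity: half a sd safer
            4 * norm.cdf(0.0),    # dev_tox at the mean
            4 * norm.cdf(0.0),    # bf at the mean
        ])
        sa_block = 4.0 * 80.0 / 100.0
        expected = (adme_block + tox_block + sa_block) / 3.0
        assert selection_score(p, ref_stats) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("field,delta,direction", [
        ("ld50", +200.0, +1),        # higher LD50 is safer -> higher score
        ("mutagenicity", +0.1, -1),  # higher probability is worse
        ("dev_tox", +0.1, -1),
        ("bf", +0.5, -1),            # more bioaccumulation is worse
        ("sa", +10.0, +1),           # easier synthesis is better
    ])
    def test_monotone_in_safety_and_ease(self, centroid_vector, ref_stats,
                                         field, delta, direction):
        base = selection_score(centroid_vector, ref_stats)
        perturbed = selection_score(
            dataclasses.replace(
                centroid_vector, **{field: getattr(centroid_vector, field) + delta}
            ),
            ref_stats,
        )
        assert direction * (perturbed - base) > 0


class TestReferenceStats:
    def test_needs_two_compounds(self):
        with pytest.raises(ValueError):
            ReferenceStats(means={"mw": 1.0}, stds={"mw": 1.0}, n_refs=1)

    def test_degenerate_property_rejected(self):
        with pytest.raises(ValueError, match="mw"):
            ReferenceStats(means={"mw": 1.0}, stds={"mw": 0.0}, n_refs=5)

    def test_from_table_excludes_constant_columns(self):
        table = pd.DataFrame({
            name: np.linspace(1, 2, 4) for name in SCORED_PROPERTIES
        })
        table["rotb"] = 5.0  # constant -> excluded with no error
        stats = ReferenceStats.from_table(table)
        assert "rotb" not in stats.means
        assert "mw" in stats.means


class TestRankAndSelect:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["id", "s_sel", "s_elim"])

    def test_all_below_thresholds(self):
        scores = self._scores([("a", 2.0, 5.0), ("b", 2.2, 4.0)])
        out = rank_and_select(scores, 10, parent_score=2.5, reference_average=2.4)
        assert out.empty

    def test_strict_threshold_and_order(self):
        scores = self._scores([
            ("a", 3.0, 6.0), ("b", 3.2, 4.0), ("c", 2.5, 1.0), ("d", 3.1, 4.0),
        ])
        out = rank_and_select(scores, 10, parent_score=2.5, reference_average=2.8)
        # c fails the filter (equal to parent is not "beating" it)
        assert list(out["id"]) == ["b", "d", "a"]  # s_elim ties -> higher s_sel first

    def test_tie_break_is_deterministic(self):
        scores = self._scores([
            ("x2", 3.0, 4.0), ("x1", 3.0, 4.0), ("x3", 3.0, 4.0),
        ])
        out = rank_and_select(scores, 10, 2.0, 2.0)
        assert list(out["id"]) == ["x1", "x2", "x3"]

    def test_exact_survivor_count_then_truncation(self):
        rows = [(f"g{i}", 3.0 + i * 0.01, float(i)) for i in range(12)]
        rows += [(f"bad{i}", 2.0, float(i)) for i in range(8)]
        scores = self._scores(rows)
        survivors = rank_and_select(scores, 100, 2.5, 2.5)
        assert len(survivors) == 12
        top = rank_and_select(scores, 5, 2.5, 2.5)
        assert list(top["id"]) == [f"g{i}" for i in range(5)]

    def test_top_n_validation(self):
        with pytest.raises(ValueError):
            rank_and_select(self._scores([("a", 3.0, 1.0)]), 0, 2.0, 2.0)


def test_score_table_round_trip(ref_stats, centroid_vector):
    """Scoring a table agrees with scoring its rows one by one."""
    rows = []
    rng = np.random.default_rng(9)
    for i in range(5):
        values = {
            name: ref_stats.means[name]
            + rng.normal(0, 1) * ref_stats.stds[name]
            for name in SCORED_PROPERTIES
        }
        values["sa"] = float(np.clip(values["sa"], 1, 99))
        values["ld50"] = abs(values["ld50"]) + 1
        values["mutagenicity"] = float(np.clip(values["mutagenicity"], 0, 1))
        values["dev_tox"] = float(np.clip(values["dev_tox"], 0, 1))
        rows.append({"id": f"c{i}", "carbons": 18, "heteroatoms": 5,
                     "rings": 3, **values})
    table = pd.DataFrame(rows)
    scored = score_table(table, ref_stats)
    for _, row in table.iterrows():
        values = {k: row[k] for k in SCORED_PROPERTIES}
        for count_field in ("hbd", "hba", "rotb", "heavy_atoms"):
            values[count_field] = int(round(values[count_field]))
        p = dataclasses.replace(centroid_vector, **values)
        expect = scored[scored["id"] == row["id"]].iloc[0]
        assert expect["s_elim"] == pytest.approx(
            elimination_score(p, ref_stats)[0], abs=1e-9
        )
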