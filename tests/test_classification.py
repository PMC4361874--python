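"""Helix-pair / section-pair summaries, normalisation and set comparison."""

from __future__ import annotations

import re

import numpy as np
import pytest

from tmconserve.classify import (
    compare_sets,
    possible_pair_counts,
    summarize_helix_pairs,
    summarize_section_pairs,
)
from tmconserve.conservation import rank_pairs, score_set
from tmconserve.frame import BWPosition
from tmconserve.structure_io import build_set
from tmconserve.synthetic import GeneratorSpec, HelixNoise, generate_ensemble, preset

INTRA = [f"{r}-{r}" for r in ("I", "II", "III", "IV", "V", "VI", "VII")]


@pytest.fixture(scope="module")
def ensemble(defn):
    spec = preset("rhodopsin_like")
    spec.seed = 13
    return generate_ensemble(spec, defn)


@pytest.fixture(scope="module")
def ranked(ensemble, defn):
    return rank_pairs(score_set(ensemble, defn), top_n=1000)


class TestPossiblePairCounts:
    def test_helix_level_partitions_universe(self, defn):
        counts = possible_pair_counts(defn, level="helix")
        assert len(counts) == 28
        assert counts.sum() == 19900
        assert counts["III-III"] == 561  # C(34,2)

    def test_adjacency_excluded_denominator(self, defn):
        counts = possible_pair_counts(defn, level="helix", exclude_adjacent=True)
        assert counts["III-III"] == 561 - 33
        assert counts.sum() == 19900 - 193

    def test_section_level_partitions_universe(self, defn):
        counts = possible_pair_counts(defn, level="section")
        assert len(counts) == 630
        assert counts.sum() == 19900
        assert counts["I1-VII5"] == 9
        assert counts["VI1-VII1"] == 90

    def test_missing_positions_shrink_bins(self, defn):
        present = set(defn.positions()) - {BWPosition(4, 39)}
        counts = possible_pair_counts(defn, present, level="helix")
        assert counts.sum() == 19701
        full = possible_pair_counts(defn, level="helix")
        assert counts["IV-IV"] == full["IV-IV"] - (defn.helix(4).length - 1)


class TestHelixPairSummary:
    def test_top_counts_partition_top_n(self, ranked, ensemble, defn):
        summary, _ = summarize_helix_pairs(ranked, ensemble, defn)
        assert summary["count_top"].sum() == 1000
        assert summary["count_all"].sum() == 19900
        assert ((summary["ratio"] >= 0) & (summary["ratio"] <= 1)).all()

    def test_cumulative_reaches_summary_counts(self, ranked, ensemble, defn):
        summary, cum = summarize_helix_pairs(ranked, ensemble, defn)
        finals = cum.groupby("label")["cum_count"].max()
        for row in summary.itertuples(index=False):
            if row.count_top:
                assert finals[row.label] == row.count_top

    def test_engineered_coupling_dominates_interhelical(self, ranked, ensemble, defn):
        """With helices I and VI jittering as one unit, I-VI holds the
        largest interhelical share of the top 1,000."""
        summary, _ = summarize_helix_pairs(ranked, ensemble, defn)
        s = summary.set_index("label")["count_top"]
        inter = s.drop(INTRA)
        assert inter.idxmax() == "I-VI"

    def test_enlarging_top_n_never_decreases_counts(self, ensemble, defn):
        stats = score_set(ensemble, defn)
        s500, _ = summarize_helix_pairs(rank_pairs(stats, top_n=500), ensemble, defn)
        s1000, _ = summarize_helix_pairs(rank_pairs(stats, top_n=1000), ensemble, defn)
        assert (s1000["count_top"].to_numpy() >= s500["count_top"].to_numpy()).all()

    def test_inconsistent_definition_rejected(self, ranked, ensemble):
        from tmconserve.frame import load_bundle_definition, default_definition

        cfg = {
            "helices": {
                h: {
                    "start": default_definition().helix(h).start + 100,
                    "end": default_definition().helix(h).end + 100,
                    "sections": list(default_definition().helix(h).section_sizes),
                    "extracellular_end": default_definition().helix(h).extracellular_end,
                }
                for h in range(1, 8)
            }
        }
        shifted = load_bundle_definition(cfg)
        with pytest.raises(ValueError, match="outside"):
            summarize_helix_pairs(ranked, ensemble, shifted)


class TestSectionPairSummary:
    def test_helix_iii_table_denominators(self, ranked, ensemble, defn):
        """The helix III 'all' column: cross-section products, C(7,2) for
        4-4, 83 pooled in others, 561 total."""
        table = summarize_section_pairs(ranked, ensemble, defn, helix_filter="III-III")
        col = table.set_index("label")["count_all"]
        assert col["III1-III2"] == 64
        assert col["III1-III3"] == 32
        assert col["III1-III4"] == 56
        assert col["III1-III5"] == 56
        assert col["III2-III3"] == 32
        assert col["III2-III4"] == 56
        assert col["III2-III5"] == 56
        assert col["III3-III4"] == 28
        assert col["III3-III5"] == 28
        assert col["III4-III4"] == 21
        assert col["III4-III5"] == 49
        assert col["others"] == 83  # 28 + 28 + 6 + 21
        assert col["total"] == 561

    def test_filtered_counts_partition_helix_total(self, ranked, ensemble, defn):
        table = summarize_section_pairs(ranked, ensemble, defn, helix_filter="III-III")
        body = table[~table["label"].isin(["total"])]
        total = table[table["label"] == "total"].iloc[0]
        assert body["count_top"].sum() == total["count_top"]
        assert body["count_all"].sum() == total["count_all"]

    def test_interhelical_filter_lists_25_bins(self, ranked, ensemble, defn):
        table = summarize_section_pairs(ranked, ensemble, defn, helix_filter="I-VI")
        assert len(table) == 26  # 25 bins + total
        assert table[table["label"] == "total"]["count_all"].iloc[0] == 31 * 31

    def test_unfiltered_summary_has_630_bins(self, ranked, ensemble, defn):
        table = summarize_section_pairs(ranked, ensemble, defn)
        assert len(table) == 630
        assert table["count_top"].sum() == 1000
        assert table["count_all"].sum() == 19900

    def test_sections_aggregate_back_to_helix_summary(self, ranked, ensemble, defn):
        helix_summary, _ = summarize_helix_pairs(ranked, ensemble, defn)
        sections = summarize_section_pairs(ranked, ensemble, defn)

        def helix_pair_of(label: str) -> str:
            a, b = label.split("-")
            return f"{re.sub(r'[0-9]+', '', a)}-{re.sub(r'[0-9]+', '', b)}"

        agg = sections.assign(hp=sections["label"].map(helix_pair_of)).groupby("hp")[
            ["count_top", "count_all"]
        ].sum()
        for row in helix_summary.itertuples(index=False):
            assert agg.loc[row.label, "count_top"] == row.count_top
            assert agg.loc[row.label, "count_all"] == row.count_all

    def test_unknown_helix_filter_errors(self, ranked, ensemble, defn):
        with pytest.raises(ValueError):
            summarize_section_pairs(ranked, ensemble, defn, helix_filter="VIII-IX")


class TestCompareSets:
    def test_identical_sets_give_zero_deltas(self, ranked, ensemble, defn):
        summary, _ = summarize_helix_pairs(ranked, ensemble, defn)
        out = compare_sets({"a": summary, "b": summary.copy()})
        assert np.allclose(out["delta"], 0.0)

    def test_mismatched_labels_error(self, ranked, ensemble, defn):
        summary, _ = summarize_helix_pairs(ranked, ensemble, defn)
        other = summary.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="labels"):
            compare_sets({"a": summary, "b": other})

    def test_leave_subgroup_out_recovers_shifted_helix(self, defn):
        """A subgroup with helix V displaced toward the extracellular side
        suppresses III-V conservation; removing the subgroup restores it,
        so III-V shows the largest positive ratio delta."""
        spec = GeneratorSpec(
            n_members=12,
            seed=21,
            default_noise=HelixNoise(trans_sigma=0.9, rot_sigma=3.0, residue_sigma=0.25),
            noise={
                3: HelixNoise(trans_sigma=0.15, rot_sigma=1.0, residue_sigma=0.04),
                5: HelixNoise(trans_sigma=0.15, rot_sigma=1.0, residue_sigma=0.10),
            },
        )
        full = generate_ensemble(spec, defn)
        shifted_members = []
        for i, m in enumerate(full.members):
            if i >= 8:  # the "subfamily" carrying the helix V offset
                for pos in list(m.coords_ca):
                    if pos.helix == 5:
                        m.coords_ca[pos] = m.coords_ca[pos] + np.array([0.0, 0.0, 3.0])
            shifted_members.append(m)
        with_sub = build_set(shifted_members, "with_sub")
        without_sub = build_set(shifted_members[:8], "without_sub")

        summaries = {}
        for ens in (with_sub, without_sub):
            r = rank_pairs(score_set(ens, defn), top_n=1000)
            summaries[ens.name], _ = summarize_helix_pairs(r, ens, defn)
        out = compare_sets(summaries).set_index("label")
        positive = out[out["delta"] > 0]
        assert out.loc["III-V", "delta"] > 0
        assert out.loc["III-V", "delta"] == positive["delta"].max()
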