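"""Structure parsing, alignment application, and set construction."""

from __future__ import annotations

import numpy as np
import pytest

from tmconserve.frame import BWPosition
from tmconserve.structure_io import (
    apply_alignment,
    build_set,
    mean_ca_bfactor,
    pick_lowest_bfactor,
    read_bundle_tsv,
    read_chain,
    serial_alignment_from_anchors,
    write_bundle_tsv,
)
from tmconserve.synthetic import GeneratorSpec, HelixNoise, generate_ensemble, write_ensemble_fixtures

from conftest import make_bundle


def _pdb_line(serial, name, altloc, resnum, x, y, z, b=20.0, occ=1.0, element="C"):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc:1s}ALA A{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


def _write_pdb(tmp_path, lines, name="test.pdb"):
    path = tmp_path / name
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


class TestReadChain:
    def test_altloc_a_wins_regardless_of_record_order(self, tmp_path):
        a_first = [
            _pdb_line(1, " CA ", "A", 1, 1.0, 0.0, 0.0),
            _pdb_line(2, " CA ", "B", 1, 9.0, 0.0, 0.0),
        ]
        b_first = list(reversed(a_first))
        for i, lines in enumerate([a_first, b_first]):
            path = _write_pdb(tmp_path, lines, name=f"alt{i}.pdb")
            records = read_chain(path, "A")
            xyz, _ = records[0].atoms["CA"]
            assert xyz[0] == pytest.approx(1.0)

    def test_blank_altloc_preferred_over_a(self, tmp_path):
        lines = [
            _pdb_line(1, " CA ", "A", 1, 9.0, 0.0, 0.0),
            _pdb_line(2, " CA ", " ", 1, 1.0, 0.0, 0.0),
        ]
        records = read_chain(_write_pdb(tmp_path, lines), "A")
        assert records[0].atoms["CA"][0][0] == pytest.approx(1.0)

    def test_missing_chain_names_available(self, tmp_path):
        path = _write_pdb(tmp_path, [_pdb_line(1, " CA ", " ", 1, 0, 0, 0)])
        with pytest.raises(KeyError, match="A"):
            read_chain(path, "Z")

    def test_complete_chain_yields_one_record_per_residue(self, tmp_path):
        lines = [
            _pdb_line(i + 1, " CA ", " ", i + 1, float(i), 0.0, 0.0) for i in range(200)
        ]
        records = read_chain(_write_pdb(tmp_path, lines), "A")
        assert len(records) == 200
        assert all("CA" in r.atoms for r in records)

    def test_residue_without_ca_is_flagged_absent_downstream(self, tmp_path, defn):
        lines = [_pdb_line(1, " N  ", " ", 1, 0, 0, 0, element="N")]
        records = read_chain(_write_pdb(tmp_path, lines), "A")
        assert "CA" not in records[0].atoms
        bundle = apply_alignment(records, {"1": "4.39"}, defn)
        assert BWPosition(4, 39) in bundle.missing


class TestApplyAlignment:
    def test_gap_pattern_lands_in_missing(self, tmp_path, defn):
        # chain modelling everything except the class-C style gaps
        gone = {"2.66", "2.67", "6.59", "6.60"}
        table = {}
        lines = []
        serial = 0
        for i, pos in enumerate(defn.positions()):
            table[str(i + 1)] = str(pos)
            if str(pos) in gone:
                continue
            serial += 1
            lines.append(_pdb_line(serial, " CA ", " ", i + 1, float(i), 0.0, 0.0))
        records = read_chain(_write_pdb(tmp_path, lines), "A")
        bundle = apply_alignment(records, table, defn)
        assert {str(p) for p in bundle.missing} == gone

    def test_duplicate_mapping_is_an_error(self, tmp_path, defn):
        lines = [
            _pdb_line(1, " CA ", " ", 1, 0, 0, 0),
            _pdb_line(2, " CA ", " ", 2, 1, 0, 0),
        ]
        records = read_chain(_write_pdb(tmp_path, lines), "A")
        with pytest.raises(ValueError, match="both map"):
            apply_alignment(records, {"1": "3.50", "2": "3.50"}, defn)

    def test_unmapped_residues_ignored(self, tmp_path, defn):
        lines = [
            _pdb_line(1, " CA ", " ", 1, 0, 0, 0),
            _pdb_line(2, " CA ", " ", 999, 1, 0, 0),
        ]
        records = read_chain(_write_pdb(tmp_path, lines), "A")
        bundle = apply_alignment(records, {"1": "3.50"}, defn)
        assert len(bundle.coords_ca) == 1

    def test_serial_extension_from_anchors_matches_enumeration(self, defn):
        anchors = {h: 100 * h for h in range(1, 8)}
        table = serial_alignment_from_anchors(anchors, defn)
        assert len(table) == 200
        # spot-check helix III: anchor 300 = 3.50, so 3.22 is residue 272
        assert table["272"] == BWPosition(3, 22)
        assert table["300"] == BWPosition(3, 50)
        assert table["305"] == BWPosition(3, 55)
        # full explicit enumeration agrees
        for h in range(1, 8):
            hd = defn.helix(h)
            for index in hd.indices():
                assert table[str(100 * h + index - 50)] == BWPosition(h, index)


class TestBFactors:
    def test_mean_is_arithmetic(self, defn):
        pos = list(defn.positions())[:3]
        b = make_bundle(
            {p: np.zeros(3) + i for i, p in enumerate(pos)},
            defn,
            bfactors={pos[0]: 10.0, pos[1]: 20.0, pos[2]: 30.0},
        )
        assert mean_ca_bfactor(b) == pytest.approx(20.0)

    def test_lowest_mean_chain_selected(self, defn):
        pos = list(defn.positions())[:4]
        hot = make_bundle({p: np.zeros(3) for p in pos}, defn, source_id="HOT",
                          bfactors={p: 50.0 for p in pos})
        cold = make_bundle({p: np.zeros(3) for p in pos}, defn, source_id="COLD",
                           bfactors={p: 30.0 for p in pos})
        assert pick_lowest_bfactor([hot, cold]).source_id == "COLD"

    def test_no_bfactors_errors(self, defn):
        b = make_bundle({list(defn.positions())[0]: np.zeros(3)}, defn)
        with pytest.raises(ValueError):
            mean_ca_bfactor(b)


class TestBuildSet:
    def _complete(self, defn, i):
        rng = np.random.default_rng(i)
        return make_bundle(
            {p: rng.normal(size=3) for p in defn.positions()}, defn, source_id=f"C{i}"
        )

    def _gappy(self, defn, i, gone):
        rng = np.random.default_rng(100 + i)
        keep = [p for p in defn.positions() if str(p) not in gone]
        return make_bundle({p: rng.normal(size=3) for p in keep}, defn, source_id=f"G{i}")

    def test_all_complete_gives_19900_pairs(self, defn):
        s = build_set([self._complete(defn, i) for i in range(3)], "s")
        assert s.n_pairs == 19900

    def test_one_member_lacking_439_gives_19701(self, defn):
        members = [self._complete(defn, i) for i in range(3)]
        members.append(self._gappy(defn, 0, {"4.39"}))
        assert build_set(members, "s").n_pairs == 19701

    def test_two_gap_patterns_give_18915(self, defn):
        members = [
            self._complete(defn, 0),
            self._gappy(defn, 0, {"4.39"}),
            self._gappy(defn, 1, {"2.66", "2.67", "6.59", "6.60"}),
        ]
        s = build_set(members, "s")
        assert len(s.common_positions) == 195
        assert s.n_pairs == 18915

    def test_common_positions_never_grow(self, defn):
        members = [self._complete(defn, 0), self._complete(defn, 1)]
        before = build_set(members, "s").common_positions
        after = build_set(members + [self._gappy(defn, 0, {"4.39"})], "s").common_positions
        assert after <= before

    def test_fewer_than_two_members_rejected(self, defn):
        with pytest.raises(ValueError):
            build_set([self._complete(defn, 0)], "s")


@pytest.fixture(scope="module")
def ensemble(defn):
    spec = GeneratorSpec(n_members=2, seed=7, default_noise=HelixNoise(0.2, 1.0, 0.1, 1.0))
    return generate_ensemble(spec, defn)


class TestRoundTrips:
    def test_pdb_round_trip_preserves_coordinates(self, tmp_path, defn, ensemble):
        """Writing a bundle to PDB and re-reading reproduces CA coordinates
        to the format's printed precision (1e-3 A)."""
        paths = write_ensemble_fixtures(ensemble, defn, tmp_path)
        member = ensemble.members[0]
        records = read_chain(paths[member.source_id], "A")
        resnum = {pos: str(i + 1) for i, pos in enumerate(defn.positions())}
        table = {resnum[p]: p for p in defn.positions()}
        reread = apply_alignment(records, table, defn)
        for pos in member.coords_ca:
            np.testing.assert_allclose(
                reread.coords_ca[pos], member.coords_ca[pos], atol=1.5e-3
            )
            np.testing.assert_allclose(
                reread.coords_n[pos], member.coords_n[pos], atol=1.5e-3
            )

    def test_bundle_tsv_round_trip(self, tmp_path, defn, ensemble):
        member = ensemble.members[0]
        path = tmp_path / "b.tsv"
        write_bundle_tsv(member, defn, path)
        reread = read_bundle_tsv(path, defn)
        assert set(reread.coords_ca) == set(member.coords_ca)
        for pos in member.coords_ca:
            np.testing.assert_allclose(reread.coords_ca[pos], member.coords_ca[pos], atol=1e-5)
        assert mean_ca_bfactor(reread) == pytest.approx(mean_ca_bfactor(member))
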