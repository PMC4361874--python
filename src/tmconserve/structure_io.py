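"""Reading structures and building BW-indexed bundles.

PDB and mmCIF files are parsed with gemmi.  For each requested chain the
backbone atoms (N, CA, C) of every residue are extracted together with the
CA temperature factor; where a residue has alternate conformers, only
conformer A is used.  A per-chain alignment table mapping author residue
numbers (with insertion codes) to BW positions then turns the raw records
into an :class:`AlignedBundle`, and two or more bundles sharing a
definition form an :class:`EnsembleSet` whose scoreable pair universe is
restricted to the positions present in every member.

Only the first model of multi-model entries is considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .frame import BundleDefinition, BWPosition

__all__ = [
    "ResidueRecord",
    "AlignedBundle",
    "EnsembleSet",
    "read_chain",
    "apply_alignment",
    "mean_ca_bfactor",
    "pick_lowest_bfactor",
    "build_set",
    "serial_alignment_from_anchors",
    "load_alignment_table",
    "load_set_manifest",
    "write_bundle_tsv",
    "read_bundle_tsv",
]

log = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class ResidueRecord:
    """Backbone atoms of one residue: name -> (xyz, B-factor)."""

    key: str  # author residue number + insertion code, e.g. "100" or "100A"
    name: str
    atoms: dict[str, tuple[np.ndarray, float]] = field(default_factory=dict)


@dataclass
class AlignedBundle:
    """One chain's backbone coordinates indexed by BW position.

    ``coords_ca`` holds every modelled position; positions of the governing
    definition that the chain lacks are listed in ``missing``.  N and C
    coordinates are optional and only needed for torsion analysis.
    """

    source_id: str
    chain_id: str
    coords_ca: dict[BWPosition, np.ndarray]
    coords_n: dict[BWPosition, np.ndarray] = field(default_factory=dict)
    coords_c: dict[BWPosition, np.ndarray] = field(default_factory=dict)
    bfactor_ca: dict[BWPosition, float] = field(default_factory=dict)
    missing: frozenset[BWPosition] = frozenset()

    @property
    def label(self) -> str:
        return f"{self.source_id}:{self.chain_id}"

    @property
    def present(self) -> frozenset[BWPosition]:
        return frozenset(self.coords_ca)

    def validate_against(self, defn: BundleDefinition) -> None:
        all_pos = set(defn.positions())
        covered = set(self.coords_ca) | set(self.missing)
        if covered != all_pos:
            raise ValueError(
                f"{self.label}: present+missing covers {len(covered)} positions, "
                f"definition has {len(all_pos)}"
            )
        for pos, xyz in self.coords_ca.items():
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"{self.label}: non-finite coordinates at {pos}")


@dataclass
class EnsembleSet:
    """A named set of aligned bundles scored together.

    ``common_positions`` is the intersection of present positions over all
    members; distances are only scored over this intersection, so a member
    with gaps shrinks the pair universe for the whole set (e.g. one member
    lacking 4.39 gives 199 common positions and 19,701 pairs).
    """

    name: str
    members: list[AlignedBundle]
    common_positions: frozenset[BWPosition]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_pairs(self) -> int:
        n = len(self.common_positions)
        return n * (n - 1) // 2


# ---------------------------------------------------------------------------
# parsing


def _residue_key(seqid: gemmi.SeqId) -> str:
    icode = seqid.icode.strip("\x00 ").strip()
    return f"{seqid.num}{icode}"


def read_chain(structure_file: str | Path, chain_id: str) -> list[ResidueRecord]:
    """Extract backbone records for one chain of a PDB or mmCIF file.

    Only the first model is read.  For atoms with alternate locations, the
    blank altloc is preferred and otherwise only conformer ``A`` is kept,
    independent of record order; residues whose CA exists only in other
    conformers are reported absent.  A residue without a CA atom is still
    returned (torsion assembly may use its N/C) but callers treat it as
    missing at the bundle level.
    """
    structure_file = Path(structure_file)
    st = gemmi.read_structure(str(structure_file))
    if len(st) == 0:
        raise ValueError(f"{structure_file}: no models")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model)
        raise KeyError(
            f"{structure_file}: no chain {chain_id!r} (available: {available})"
        )
    records: list[ResidueRecord] = []
    for res in chain:
        rec = ResidueRecord(key=_residue_key(res.seqid), name=res.name)
        for atom_name in BACKBONE_ATOMS:
            chosen = None
            for atom in res:
                if atom.name != atom_name:
                    continue
                alt = atom.altloc.strip("\x00")
                if alt == "":
                    chosen = atom  # blank altloc always wins
                    break
                if alt == "A" and chosen is None:
                    chosen = atom
            if chosen is not None:
                xyz = np.array([chosen.pos.x, chosen.pos.y, chosen.pos.z], dtype=float)
                rec.atoms[atom_name] = (xyz, float(chosen.b_iso))
        if "CA" not in rec.atoms:
            log.warning(
                "%s chain %s residue %s: no CA in conformer A; treated as absent",
                structure_file.name, chain_id, rec.key,
            )
        records.append(rec)
    return records


def apply_alignment(
    records: Sequence[ResidueRecord],
    alignment_table: Mapping[str, BWPosition | str],
    defn: BundleDefinition,
    *,
    source_id: str = "",
    chain_id: str = "",
) -> AlignedBundle:
    """Map raw residue records onto BW positions.

    ``alignment_table`` maps residue keys (author number + insertion code)
    to BW positions; residues without an entry are ignored.  Two residues
    mapped to one BW position is an error.  Definition positions with no
    mapped residue, or a mapped residue without a CA atom, land in
    ``missing``.
    """
    table: dict[str, BWPosition] = {}
    for key, pos in alignment_table.items():
        bw = BWPosition.parse(pos) if isinstance(pos, str) else pos
        defn.require(bw)
        table[str(key)] = bw

    coords_ca: dict[BWPosition, np.ndarray] = {}
    coords_n: dict[BWPosition, np.ndarray] = {}
    coords_c: dict[BWPosition, np.ndarray] = {}
    bfac: dict[BWPosition, float] = {}
    seen: dict[BWPosition, str] = {}
    for rec in records:
        bw = table.get(rec.key)
        if bw is None:
            continue
        if bw in seen:
            raise ValueError(
                f"residues {seen[bw]} and {rec.key} both map to BW position {bw}"
            )
        seen[bw] = rec.key
        if "CA" in rec.atoms:
            coords_ca[bw], bfac[bw] = rec.atoms["CA"]
        if "N" in rec.atoms:
            coords_n[bw] = rec.atoms["N"][0]
        if "C" in rec.atoms:
            coords_c[bw] = rec.atoms["C"][0]
    missing = frozenset(set(defn.positions()) - set(coords_ca))
    bundle = AlignedBundle(
        source_id=source_id,
        chain_id=chain_id,
        coords_ca=coords_ca,
        coords_n=coords_n,
        coords_c=coords_c,
        bfactor_ca=bfac,
        missing=missing,
    )
    bundle.validate_against(defn)
    return bundle


def serial_alignment_from_anchors(
    anchors: Mapping[int, int | str], defn: BundleDefinition
) -> dict[str, BWPosition]:
    """Expand per-helix *.50 anchor residue numbers into a full alignment.

    ``anchors`` maps helix number -> author residue number of the H.50
    residue.  Numbering is extended serially in both directions within each
    helix's BW range, without gap insertion.
    """
    table: dict[str, BWPosition] = {}
    for h, anchor in anchors.items():
        hd = defn.helix(int(h))
        anchor = int(anchor)
        for index in hd.indices():
            resnum = anchor + (index - 50)
            table[str(resnum)] = BWPosition(hd.helix, index)
    return table


# ---------------------------------------------------------------------------
# bundle/set level helpers


def mean_ca_bfactor(bundle: AlignedBundle) -> float:
    """Arithmetic mean CA temperature factor over present positions."""
    if not bundle.bfactor_ca:
        raise ValueError(f"{bundle.label}: no CA B-factors recorded")
    return float(np.mean(list(bundle.bfactor_ca.values())))


def pick_lowest_bfactor(bundles: Sequence[AlignedBundle]) -> AlignedBundle:
    """Select the chain with the lowest mean CA B-factor.

    Used when one entry offers several chains of the same receptor and a
    single representative is wanted; ties resolve to the first by label.
    """
    if not bundles:
        raise ValueError("no bundles to choose from")
    return min(bundles, key=lambda b: (mean_ca_bfactor(b), b.label))


def build_set(members: Sequence[AlignedBundle], name: str) -> EnsembleSet:
    """Assemble an ensemble; at least two members are required."""
    if len(members) < 2:
        raise ValueError(f"set {name!r} needs >= 2 members, got {len(members)}")
    common = frozenset.intersection(*(m.present for m in members))
    return EnsembleSet(name=name, members=list(members), common_positions=common)


# ---------------------------------------------------------------------------
# tabular interchange


def load_alignment_table(path: str | Path) -> dict[tuple[str, str], dict[str, BWPosition]]:
    """Read a TSV with columns source_id, chain_id, residue_number, bw_position.

    Returns a mapping (source_id, chain_id) -> {residue key -> BWPosition}.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"source_id", "chain_id", "residue_number", "bw_position"}
    if not required.issubset(df.columns):
        raise ValueError(f"alignment table {path} lacks columns {required - set(df.columns)}")
    out: dict[tuple[str, str], dict[str, BWPosition]] = {}
    for row in df.itertuples(index=False):
        key = (row.source_id, row.chain_id)
        out.setdefault(key, {})[str(row.residue_number)] = BWPosition.parse(row.bw_position)
    return out


def load_set_manifest(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns source_id, chain_id, set_name and optional path."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"source_id", "chain_id", "set_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"set manifest {path} lacks columns {required - set(df.columns)}")
    return df


def write_bundle_tsv(bundle: AlignedBundle, defn: BundleDefinition, path: str | Path) -> None:
    """Persist a bundle as a TSV, one row per present position."""
    rows = []
    for pos in defn.positions():
        if pos not in bundle.coords_ca:
            continue
        row: dict[str, object] = {"bw": str(pos)}
        for tag, coords in (("ca", bundle.coords_ca), ("n", bundle.coords_n), ("c", bundle.coords_c)):
            xyz = coords.get(pos)
            for ax, v in zip("xyz", (np.full(3, np.nan) if xyz is None else xyz)):
                row[f"{tag}_{ax}"] = v
        row["b_ca"] = bundle.bfactor_ca.get(pos, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_bundle_tsv(
    path: str | Path, defn: BundleDefinition, *, source_id: str = "", chain_id: str = ""
) -> AlignedBundle:
    """Load a bundle written by :func:`write_bundle_tsv`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"bw": str})
    coords_ca: dict[BWPosition, np.ndarray] = {}
    coords_n: dict[BWPosition, np.ndarray] = {}
    coords_c: dict[BWPosition, np.ndarray] = {}
    bfac: dict[BWPosition, float] = {}
    for row in df.itertuples(index=False):
        pos = BWPosition.parse(row.bw)
        coords_ca[pos] = np.array([row.ca_x, row.ca_y, row.ca_z], dtype=float)
        n = np.array([row.n_x, row.n_y, row.n_z], dtype=float)
        c = np.array([row.c_x, row.c_y, row.c_z], dtype=float)
        if np.all(np.isfinite(n)):
            coords_n[pos] = n
        if np.all(np.isfinite(c)):
            coords_c[pos] = c
        if np.isfinite(row.b_ca):
            bfac[pos] = float(row.b_ca)
    missing = frozenset(set(defn.positions()) - set(coords_ca))
    bundle = AlignedBundle(
        source_id=source_id or Path(path).stem,
        chain_id=chain_id,
        coords_ca=coords_ca,
        coords_n=coords_n,
        coords_c=coords_c,
        bfactor_ca=bfac,
        missing=missing,
    )
    bundle.validate_against(defn)
    return bundle
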