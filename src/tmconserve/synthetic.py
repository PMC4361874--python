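"""Synthetic 7TM backbone ensembles with controlled conservation structure.

The generator builds idealised heptahelical bundles so that every pipeline
stage can be exercised, and its statistical claims verified, without any
crystallographic input.  Each helix is grown as an ideal alpha-helix from
internal coordinates (standard backbone bond lengths/angles; phi = -57,
psi = -47, omega = 180 by default), which makes the construction torsions
exact ground truth for torsion-recovery tests.  Helix axes are placed on
an ellipse of ~11 A radius with the chain direction alternating across the
membrane; realism beyond the conservation statistics is not attempted.

Per member, three stochastic layers perturb the reference bundle:

* rigid-body jitter per helix (translation sigma in A, rotation sigma in
  degrees) -- helices listed together in a coupling group receive one
  joint draw, so their mutual distances stay conserved while the group
  moves as a unit relative to the rest of the bundle;
* per-atom isotropic coordinate noise (per-helix sigma, A), the only term
  that perturbs intrahelical distances;
* per-residue torsion noise (per-helix sigma, degrees) applied to the
  construction phi/psi.

All draws come from one seeded NumPy generator in a fixed order, and every
noise array is always drawn and then scaled by its sigma, so a given seed
yields the same underlying perturbation field at any noise setting.
Output can be kept in memory or written as PDB files plus the alignment
and set-manifest TSVs consumed by the structure reader.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .frame import BundleDefinition, BWPosition, default_definition
from .structure_io import AlignedBundle, EnsembleSet, build_set

__all__ = [
    "HelixNoise",
    "Kink",
    "GeneratorSpec",
    "preset",
    "PRESETS",
    "generate_ensemble",
    "write_ensemble_fixtures",
    "ideal_helix_backbone",
]

# backbone internal coordinates (A, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0


@dataclass(frozen=True)
class HelixNoise:
    """Per-helix noise sigmas; all must be non-negative."""

    trans_sigma: float = 0.3  # A, rigid-body translation
    rot_sigma: float = 2.0  # degrees, rigid-body rotation
    residue_sigma: float = 0.15  # A, per-atom isotropic coordinate noise
    torsion_sigma: float = 0.0  # degrees, construction phi/psi noise

    def __post_init__(self) -> None:
        for name in ("trans_sigma", "rot_sigma", "residue_sigma", "torsion_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Kink:
    """A kink: helix, BW index of the hinge, bend angle in degrees."""

    helix: int
    index: int
    angle: float


@dataclass
class GeneratorSpec:
    """Full description of a synthetic ensemble; the seed fixes the output.

    ``helix_geometry`` targets (rise A/residue, twist deg/residue, radius
    A) describe the ideal helix produced by the default construction
    torsions and are checked against the built geometry; ``phi``/``psi``
    are the actual construction angles.
    """

    n_members: int = 20
    seed: int = 0
    # helix geometry
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    phi: float = -57.0
    psi: float = -47.0
    # bundle layout
    layout_radius: float = 11.0
    layout_eccentricity: float = 0.85
    tilts: dict[int, float] = field(default_factory=dict)  # degrees per helix
    # noise
    noise: dict[int, HelixNoise] = field(default_factory=dict)
    default_noise: HelixNoise = field(default_factory=HelixNoise)
    couplings: list[frozenset[int]] = field(default_factory=list)
    kinks: list[Kink] = field(default_factory=list)
    # member index -> BW positions omitted from that member
    missing: dict[int, list[BWPosition]] = field(default_factory=dict)
    # B-factor model
    bfactor_base: float = 30.0
    bfactor_helix_offsets: dict[int, float] = field(default_factory=dict)

    def helix_noise(self, helix: int) -> HelixNoise:
        return self.noise.get(helix, self.default_noise)

    def validate(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        seen: set[int] = set()
        for group in self.couplings:
            if not group or not all(1 <= h <= 7 for h in group):
                raise ValueError(f"invalid coupling group {set(group)}")
            if seen & set(group):
                raise ValueError("coupling groups must be disjoint")
            seen |= set(group)


# ---------------------------------------------------------------------------
# geometry


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _nerf(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom d with given bond length |cd|, angle b-c-d and dihedral a-b-c-d."""
    theta = np.radians(angle)
    chi = np.radians(torsion)
    bc = _normalize(c - b)
    n = _normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def ideal_helix_backbone(
    n_res: int, phi: float | np.ndarray = -57.0, psi: float | np.ndarray = -47.0
) -> np.ndarray:
    """N/CA/C coordinates, shape (n_res, 3, 3), grown from internal coordinates.

    ``phi``/``psi`` may be scalars or per-residue arrays (phi[0] is unused
    by construction).  The default angles give a regular alpha-helix:
    consecutive CA-CA spacing ~3.8 A, rise ~1.5 A/residue, ~100 deg twist.
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (n_res,))
    psi_arr = np.broadcast_to(np.asarray(psi, dtype=float), (n_res,))
    atoms = np.zeros((n_res, 3, 3))
    theta = np.radians(ANGLE_N_CA_C)
    atoms[0, 0] = [0.0, 0.0, 0.0]  # N1
    atoms[0, 1] = [BOND_N_CA, 0.0, 0.0]  # CA1
    atoms[0, 2] = atoms[0, 1] + BOND_CA_C * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )  # C1, in-plane with the N-CA-C angle
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = atoms[i - 1]
        n_i = _nerf(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi_arr[i - 1])
        ca_i = _nerf(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _nerf(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_arr[i])
        atoms[i] = [n_i, ca_i, c_i]
    return atoms


def _fit_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares helix axis through CA coordinates, oriented N->C."""
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return centroid, axis


def _rotation_aligning(u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector u onto unit vector t (Rodrigues)."""
    u, t = _normalize(u), _normalize(t)
    v = np.cross(u, t)
    c = float(np.dot(u, t))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = _normalize(np.cross(u, perp))
        return _axis_angle(axis, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = _normalize(axis)
    a = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _build_helix_member(
    spec: GeneratorSpec,
    defn: BundleDefinition,
    helix: int,
    torsion_noise: np.ndarray,
) -> np.ndarray:
    """One helix's atoms (L, 3, 3) in its local frame: axis +z = extracellular."""
    hd = defn.helix(helix)
    length = hd.length
    sigma = spec.helix_noise(helix).torsion_sigma
    phis = spec.phi + sigma * torsion_noise[:, 0]
    psis = spec.psi + sigma * torsion_noise[:, 1]
    atoms = ideal_helix_backbone(length, phis, psis)
    ca = atoms[:, 1]
    centroid, axis = _fit_axis(ca)
    # extracellular side at +z: flip chains whose N-terminal end is extracellular
    target = np.array([0.0, 0.0, -1.0 if hd.extracellular_end == "first" else 1.0])
    rot = _rotation_aligning(axis, target)
    atoms = (atoms.reshape(-1, 3) - centroid) @ rot.T
    atoms = atoms.reshape(length, 3, 3)
    for kink in spec.kinks:
        if kink.helix != helix:
            continue
        if not hd.start <= kink.index <= hd.end:
            raise ValueError(f"kink at {kink.helix}.{kink.index} outside helix range")
        pivot_i = kink.index - hd.start
        pivot = atoms[pivot_i, 1].copy()
        rot_k = _axis_angle(np.array([1.0, 0.0, 0.0]), kink.angle)
        tail = atoms[pivot_i + 1 :].reshape(-1, 3)
        atoms[pivot_i + 1 :] = ((tail - pivot) @ rot_k.T + pivot).reshape(
            atoms[pivot_i + 1 :].shape
        )
    tilt = spec.tilts.get(helix, 0.0)
    if tilt:
        atoms = atoms.reshape(-1, 3) @ _axis_angle(np.array([0.0, 1.0, 0.0]), tilt).T
        atoms = atoms.reshape(length, 3, 3)
    return atoms


def _layout_centers(spec: GeneratorSpec) -> dict[int, np.ndarray]:
    centers = {}
    for h in range(1, 8):
        theta = 2.0 * np.pi * (h - 1) / 7.0
        centers[h] = np.array(
            [
                spec.layout_radius * np.cos(theta),
                spec.layout_radius * spec.layout_eccentricity * np.sin(theta),
                0.0,
            ]
        )
    return centers


def _rigid_groups(spec: GeneratorSpec) -> list[frozenset[int]]:
    grouped: set[int] = set().union(*spec.couplings) if spec.couplings else set()
    groups = [frozenset(g) for g in spec.couplings]
    groups += [frozenset({h}) for h in range(1, 8) if h not in grouped]
    return sorted(groups, key=min)


def _geometry_self_check(spec: GeneratorSpec, atoms: np.ndarray) -> None:
    """Sanity-check a noiseless helix against the declared geometry targets."""
    ca = atoms[:, 1]
    d1 = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if not np.all(np.abs(d1 - 3.8) < 0.1):
        warnings.warn("consecutive CA spacing outside 3.8 +/- 0.1 A", stacklevel=2)
    if len(ca) > 4:
        d4 = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
        if not np.all(np.abs(d4 - 6.2) < 0.4):
            warnings.warn("i,i+4 CA spacing outside 6.2 +/- 0.4 A", stacklevel=2)
    centroid, axis = _fit_axis(ca)
    rise = np.abs(np.diff((ca - centroid) @ axis)).mean()
    radial = ca - centroid - np.outer((ca - centroid) @ axis, axis)
    radius = np.linalg.norm(radial, axis=1).mean()
    if abs(rise - spec.rise) > 0.15:
        warnings.warn(f"helical rise {rise:.2f} A differs from target {spec.rise}", stacklevel=2)
    if abs(radius - spec.radius) > 0.35:
        warnings.warn(f"helix radius {radius:.2f} A differs from target {spec.radius}", stacklevel=2)


def generate_ensemble(
    spec: GeneratorSpec,
    defn: BundleDefinition | None = None,
    *,
    name: str = "synthetic",
    source_prefix: str = "SYN",
) -> EnsembleSet:
    """Generate a deterministic synthetic ensemble.

    Members differ only through the seeded stochastic terms.  Positions in
    ``spec.missing`` are omitted from the corresponding member, shrinking
    the set's common-position universe exactly as unmodelled residues in a
    crystal structure would.
    """
    defn = defn or default_definition()
    spec.validate()
    for positions in spec.missing.values():
        for pos in positions:
            defn.require(pos)
    rng = np.random.default_rng(spec.seed)
    centers = _layout_centers(spec)
    groups = _rigid_groups(spec)
    lengths = {h: defn.helix(h).length for h in range(1, 8)}

    _geometry_self_check(
        spec, ideal_helix_backbone(max(lengths.values()), spec.phi, spec.psi)
    )

    members: list[AlignedBundle] = []
    clash_warned = False
    for m in range(spec.n_members):
        # fixed draw order: torsion fields, atom fields, then rigid transforms
        torsion_noise = {h: rng.standard_normal((lengths[h], 2)) for h in range(1, 8)}
        atom_noise = {h: rng.standard_normal((lengths[h], 3, 3)) for h in range(1, 8)}
        rigid: dict[frozenset[int], tuple[np.ndarray, np.ndarray, float]] = {}
        for group in groups:
            trans = rng.standard_normal(3)
            axis = rng.standard_normal(3)
            angle = float(rng.standard_normal())
            rigid[group] = (trans, axis, angle)

        helix_atoms: dict[int, np.ndarray] = {}
        for h in range(1, 8):
            atoms = _build_helix_member(spec, defn, h, torsion_noise[h])
            helix_atoms[h] = atoms + centers[h]
        for group in groups:
            noise_ref = spec.helix_noise(min(group))
            trans_raw, axis_raw, angle_raw = rigid[group]
            trans = noise_ref.trans_sigma * trans_raw
            angle = noise_ref.rot_sigma * angle_raw
            rot = _axis_angle(axis_raw, angle)
            pivot = np.mean([centers[h] for h in group], axis=0)
            for h in group:
                flat = helix_atoms[h].reshape(-1, 3)
                helix_atoms[h] = ((flat - pivot) @ rot.T + pivot + trans).reshape(
                    helix_atoms[h].shape
                )
        for h in range(1, 8):
            helix_atoms[h] = (
                helix_atoms[h] + spec.helix_noise(h).residue_sigma * atom_noise[h]
            )

        if m == 0 and not clash_warned:
            cas = [helix_atoms[h][:, 1] for h in range(1, 8)]
            for i in range(7):
                for j in range(i + 1, 7):
                    dmin = np.min(
                        np.linalg.norm(cas[i][:, None, :] - cas[j][None, :, :], axis=-1)
                    )
                    if dmin < 2.0:
                        warnings.warn(
                            f"helices {i + 1} and {j + 1} clash (min CA-CA {dmin:.2f} A)",
                            stacklevel=2,
                        )
                        clash_warned = True

        omitted = set(spec.missing.get(m, []))
        coords_ca: dict[BWPosition, np.ndarray] = {}
        coords_n: dict[BWPosition, np.ndarray] = {}
        coords_c: dict[BWPosition, np.ndarray] = {}
        bfac: dict[BWPosition, float] = {}
        for h in range(1, 8):
            hd = defn.helix(h)
            b = spec.bfactor_base + spec.bfactor_helix_offsets.get(h, 0.0)
            for i, index in enumerate(hd.indices()):
                pos = BWPosition(h, index)
                if pos in omitted:
                    continue
                coords_n[pos] = helix_atoms[h][i, 0]
                coords_ca[pos] = helix_atoms[h][i, 1]
                coords_c[pos] = helix_atoms[h][i, 2]
                bfac[pos] = b
        bundle = AlignedBundle(
            source_id=f"{source_prefix}{m:03d}",
            chain_id="A",
            coords_ca=coords_ca,
            coords_n=coords_n,
            coords_c=coords_c,
            bfactor_ca=bfac,
            missing=frozenset(set(defn.positions()) - set(coords_ca)),
        )
        members.append(bundle)
    if len(members) == 1:
        return EnsembleSet(name=name, members=members, common_positions=members[0].present)
    return build_set(members, name)


# ---------------------------------------------------------------------------
# fixture files


def write_ensemble_fixtures(
    ensemble: EnsembleSet, defn: BundleDefinition, out_dir: str | Path
) -> dict[str, Path]:
    """Write PDB files plus alignment-table and set-manifest TSVs.

    Residues are numbered sequentially over the canonical position order
    (so the alignment table is an explicit residue-number -> BW mapping),
    written as poly-alanine backbones with the modelled B-factors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    resnum = {pos: i + 1 for i, pos in enumerate(defn.positions())}
    align_rows = []
    manifest_rows = []
    paths: dict[str, Path] = {}
    for member in ensemble.members:
        st = gemmi.Structure()
        st.name = member.source_id
        model = gemmi.Model(1)
        chain = gemmi.Chain(member.chain_id)
        for pos in defn.positions():
            if pos not in member.coords_ca:
                continue
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(resnum[pos], " ")
            for atom_name, coords, element in (
                ("N", member.coords_n, "N"),
                ("CA", member.coords_ca, "C"),
                ("C", member.coords_c, "C"),
            ):
                xyz = coords.get(pos)
                if xyz is None:
                    continue
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = member.bfactor_ca.get(pos, 0.0)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        path = out_dir / f"{member.source_id}.pdb"
        st.write_pdb(str(path))
        paths[member.source_id] = path
        for pos in defn.positions():
            if pos in member.coords_ca:
                align_rows.append(
                    {
                        "source_id": member.source_id,
                        "chain_id": member.chain_id,
                        "residue_number": resnum[pos],
                        "bw_position": str(pos),
                    }
                )
        manifest_rows.append(
            {
                "source_id": member.source_id,
                "chain_id": member.chain_id,
                "set_name": ensemble.name,
                "path": path.name,
            }
        )
    pd.DataFrame(align_rows).to_csv(out_dir / "alignment.tsv", sep="\t", index=False)
    pd.DataFrame(manifest_rows).to_csv(out_dir / "sets.tsv", sep="\t", index=False)
    paths["alignment"] = out_dir / "alignment.tsv"
    paths["manifest"] = out_dir / "sets.tsv"
    return paths


# ---------------------------------------------------------------------------
# presets


def _rhodopsin_like(defn: BundleDefinition) -> GeneratorSpec:
    """Homogeneous-family conditions: conserved helix III, variable IV/VII,
    helices I and VI moving as a coupled unit."""
    return GeneratorSpec(
        n_members=20,
        default_noise=HelixNoise(trans_sigma=0.5, rot_sigma=2.0, residue_sigma=0.15),
        noise={
            1: HelixNoise(trans_sigma=0.3, rot_sigma=1.5, residue_sigma=0.12),
            3: HelixNoise(trans_sigma=0.3, rot_sigma=1.5, residue_sigma=0.02),
            4: HelixNoise(trans_sigma=1.0, rot_sigma=4.0, residue_sigma=0.45),
            6: HelixNoise(trans_sigma=0.3, rot_sigma=1.5, residue_sigma=0.12),
            7: HelixNoise(trans_sigma=1.0, rot_sigma=4.0, residue_sigma=0.45),
        },
        couplings=[frozenset({1, 6})],
    )


def _mixed_family(defn: BundleDefinition) -> GeneratorSpec:
    """Heterogeneous conditions: larger overall jitter and a kinked helix
    VI, mimicking the spread of a multi-family set."""
    spec = _rhodopsin_like(defn)
    spec.default_noise = HelixNoise(trans_sigma=0.9, rot_sigma=3.5, residue_sigma=0.25)
    spec.noise = {
        1: HelixNoise(trans_sigma=0.5, rot_sigma=2.0, residue_sigma=0.18),
        3: HelixNoise(trans_sigma=0.5, rot_sigma=2.0, residue_sigma=0.04),
        4: HelixNoise(trans_sigma=1.4, rot_sigma=5.0, residue_sigma=0.55),
        6: HelixNoise(trans_sigma=0.5, rot_sigma=2.0, residue_sigma=0.18),
        7: HelixNoise(trans_sigma=1.4, rot_sigma=5.0, residue_sigma=0.55),
    }
    spec.kinks = [Kink(helix=6, index=50, angle=12.0)]
    return spec


def _gapped(defn: BundleDefinition) -> GeneratorSpec:
    """Mixed-family conditions plus the characteristic gap patterns: one
    member lacking 4.39 and another lacking 2.66/2.67 and 6.59/6.60."""
    spec = _mixed_family(defn)
    spec.missing = {
        0: [BWPosition(4, 39)],
        1: [
            BWPosition(2, 66),
            BWPosition(2, 67),
            BWPosition(6, 59),
            BWPosition(6, 60),
        ],
    }
    return spec


PRESETS = {
    "rhodopsin_like": _rhodopsin_like,
    "mixed_family": _mixed_family,
    "gapped": _gapped,
}


def preset(name: str, defn: BundleDefinition | None = None) -> GeneratorSpec:
    """A named, fully-specified generator spec; see :data:`PRESETS`."""
    defn = defn or default_definition()
    try:
        factory = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return factory(defn)
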