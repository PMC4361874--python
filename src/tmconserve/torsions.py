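"""Backbone torsion angles and their cross-ensemble circular dispersion.

phi(i) is the dihedral C(i-1)-N(i)-CA(i)-C(i) and psi(i) is
N(i)-CA(i)-C(i)-N(i+1), computed directly from coordinates with the IUPAC
sign convention.  Within the 7TM bundle each helix is an isolated segment
(loops are not part of the data model), so phi is undefined at the first
position of every helix and psi at the last.

Across an ensemble, the per-position dispersion of each angle is the
circular standard deviation (computed through the mean resultant length,
so that -179 deg and +179 deg are 2 deg apart, not 358 deg); a minimal
arc-range alternative is provided.  Per-position dispersions are then
averaged arithmetically over each of the 35 helix sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import circstd

from .frame import ROMAN, BundleDefinition, BWPosition
from .structure_io import AlignedBundle, EnsembleSet

__all__ = [
    "dihedral",
    "torsions_for_bundle",
    "circular_deviation",
    "section_torsion_deviation",
    "TorsionDeviationTable",
]

log = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-8


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points.

    Raises ``ValueError`` when three consecutive points are collinear, in
    which case the angle is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise ValueError("collinear points: dihedral undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if angle <= -180.0 else float(angle)


def torsions_for_bundle(
    bundle: AlignedBundle, defn: BundleDefinition
) -> dict[BWPosition, tuple[float, float]]:
    """Per-position (phi, psi) of one bundle; NaN where undefined.

    Requires N and C backbone coordinates.  phi needs the preceding
    residue's C and psi the following residue's N, both within the same
    helix; positions at segment termini or next to a gap get NaN for the
    affected angle.
    """
    if not bundle.coords_n or not bundle.coords_c:
        raise ValueError(f"{bundle.label}: N/C backbone coordinates unavailable")

    def atom(pos: BWPosition, name: str) -> np.ndarray | None:
        src = {"N": bundle.coords_n, "CA": bundle.coords_ca, "C": bundle.coords_c}[name]
        return src.get(pos)

    out: dict[BWPosition, tuple[float, float]] = {}
    for pos in defn.positions():
        if pos not in bundle.coords_ca:
            continue
        hd = defn.helix(pos.helix)
        prev_pos = BWPosition(pos.helix, pos.index - 1) if pos.index > hd.start else None
        next_pos = BWPosition(pos.helix, pos.index + 1) if pos.index < hd.end else None
        n, ca, c = atom(pos, "N"), atom(pos, "CA"), atom(pos, "C")
        phi = psi = np.nan
        if n is None or c is None:
            log.warning("%s: missing backbone atom at %s; torsions absent", bundle.label, pos)
        else:
            c_prev = atom(prev_pos, "C") if prev_pos else None
            if c_prev is not None:
                try:
                    phi = dihedral(c_prev, n, ca, c)
                except ValueError:
                    log.warning("%s: collinear backbone at %s (phi)", bundle.label, pos)
            n_next = atom(next_pos, "N") if next_pos else None
            if n_next is not None:
                try:
                    psi = dihedral(n, ca, c, n_next)
                except ValueError:
                    log.warning("%s: collinear backbone at %s (psi)", bundle.label, pos)
        out[pos] = (phi, psi)
    return out


def circular_deviation(angles_deg: np.ndarray, *, method: str = "circular_sd") -> float:
    """Dispersion of a set of angles in degrees, respecting wrap-around.

    ``circular_sd`` (default) is the circular standard deviation via the
    mean resultant length; ``arc_range`` is the length of the smallest arc
    containing all angles.  Both are invariant to adding 360 deg to any
    subset of the values.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < 2:
        return float("nan")
    if method == "circular_sd":
        return float(circstd(a, low=-180.0, high=180.0))
    if method == "arc_range":
        s = np.sort(np.mod(a, 360.0))
        gaps = np.diff(np.concatenate([s, [s[0] + 360.0]]))
        return float(360.0 - gaps.max())
    raise ValueError(f"unknown method {method!r}")


@dataclass
class TorsionDeviationTable:
    """Cross-ensemble torsion dispersion, per position and per section.

    ``per_position``: bw, helix, section, n_phi, n_psi, dev_phi, dev_psi
    (degrees; NaN when fewer than two members define the angle).
    ``per_section``: 35 rows with the arithmetic mean of the per-position
    deviations inside each section.
    """

    per_position: pd.DataFrame
    per_section: pd.DataFrame
    method: str


def section_torsion_deviation(
    ensemble: EnsembleSet,
    defn: BundleDefinition,
    *,
    method: str = "circular_sd",
) -> TorsionDeviationTable:
    """Circular phi/psi deviation across members, averaged over 35 sections.

    A position where an angle is defined in fewer than two members is
    excluded from its section mean (logged).
    """
    if ensemble.n_members < 2:
        raise ValueError("need >= 2 members")
    member_torsions = [torsions_for_bundle(m, defn) for m in ensemble.members]

    rows = []
    for pos in defn.positions():
        phis = np.array([t[pos][0] for t in member_torsions if pos in t])
        psis = np.array([t[pos][1] for t in member_torsions if pos in t])
        n_phi = int(np.isfinite(phis).sum())
        n_psi = int(np.isfinite(psis).sum())
        dev_phi = circular_deviation(phis, method=method) if n_phi >= 2 else float("nan")
        dev_psi = circular_deviation(psis, method=method) if n_psi >= 2 else float("nan")
        if 0 < n_phi < 2 or 0 < n_psi < 2:
            log.info("position %s defined in <2 members; excluded from section mean", pos)
        rows.append(
            {
                "bw": str(pos),
                "helix": pos.helix,
                "section": defn.section_of(pos),
                "n_phi": n_phi,
                "n_psi": n_psi,
                "dev_phi": dev_phi,
                "dev_psi": dev_psi,
            }
        )
    per_position = pd.DataFrame(rows)

    sec_rows = []
    for h in range(1, 8):
        for s in range(1, 6):
            sel = per_position[(per_position["helix"] == h) & (per_position["section"] == s)]
            sec_rows.append(
                {
                    "helix": h,
                    "section": s,
                    "label": f"{ROMAN[h]}{s}",
                    "dev_phi": float(np.nanmean(sel["dev_phi"])) if sel["dev_phi"].notna().any() else float("nan"),
                    "dev_psi": float(np.nanmean(sel["dev_psi"])) if sel["dev_psi"].notna().any() else float("nan"),
                    "n_positions": len(sel),
                }
            )
    per_section = pd.DataFrame(sec_rows)
    return TorsionDeviationTable(per_position=per_position, per_section=per_section, method=method)
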