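"""Shared fixtures: bundle definitions and hand-buildable ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from tmconserve.frame import BundleDefinition, BWPosition, default_definition
from tmconserve.structure_io import AlignedBundle, EnsembleSet, build_set


@pytest.fixture(scope="session")
def defn() -> BundleDefinition:
    return default_definition()


def make_bundle(
    coords: dict[BWPosition, np.ndarray],
    defn: BundleDefinition,
    *,
    source_id: str = "X",
    chain_id: str = "A",
    bfactors: dict[BWPosition, float] | None = None,
) -> AlignedBundle:
    """An AlignedBundle holding only the given CA coordinates; the rest missing."""
    missing = frozenset(set(defn.positions()) - set(coords))
    bundle = AlignedBundle(
        source_id=source_id,
        chain_id=chain_id,
        coords_ca={p: np.asarray(x, dtype=float) for p, x in coords.items()},
        bfactor_ca=dict(bfactors or {}),
        missing=missing,
    )
    bundle.validate_against(defn)
    return bundle


def make_ensemble(
    member_coords: list[dict[BWPosition, np.ndarray]],
    defn: BundleDefinition,
    *,
    name: str = "test",
) -> EnsembleSet:
    members = [
        make_bundle(c, defn, source_id=f"M{i}") for i, c in enumerate(member_coords)
    ]
    return build_set(members, name)


@pytest.fixture()
def small_positions(defn) -> list[BWPosition]:
    """A 10-position subset spanning several helices and sections."""
    pos = list(defn.positions())
    return [pos[i] for i in (0, 5, 30, 40, 70, 95, 120, 150, 170, 199)]


@pytest.fixture()
def random_small_ensemble(defn, small_positions) -> EnsembleSet:
    """5 members x 10 positions with seeded random coordinates."""
    rng = np.random.default_rng(42)
    member_coords = [
        {p: rng.normal(scale=10.0, size=3) for p in small_positions} for _ in range(5)
    ]
    return make_ensemble(member_coords, defn)
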