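"""The 7TM coordinate frame.

G protein-coupled receptors share a bundle of seven transmembrane (TM)
helices.  Residues are indexed by Ballesteros-Weinstein (BW) numbering:
the most conserved residue of helix H is H.50 and the rest of the helix is
numbered serially in both directions, with no gap insertion.  A bundle
definition fixes, for each helix, an inclusive BW index range and a
partition into five contiguous horizontal "sections", numbered 1
(extracellular) to 5 (intracellular).  Because the polypeptide alternates
direction across the membrane, the definition records per helix which end
of the ascending index range faces the extracellular side.

This module provides the position/pair value types, bundle-definition
loading and validation, pair enumeration, sequence adjacency, and the
classification of a residue pair into one of the 28 helix-pair bins or
one of the 630 section-pair bins.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "BWPosition",
    "PositionPair",
    "HelixDefinition",
    "BundleDefinition",
    "BundleDefinitionError",
    "ROMAN",
    "default_definition",
    "load_bundle_definition",
    "enumerate_pairs",
    "is_adjacent",
    "count_adjacent",
    "classify_pair",
]

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII"}
ROMAN_INV = {v: k for k, v in ROMAN.items()}
N_HELICES = 7
N_SECTIONS = 5


class BundleDefinitionError(ValueError):
    """Raised when a bundle-definition config violates its invariants."""


@functools.total_ordering
@dataclass(frozen=True)
class BWPosition:
    """A Ballesteros-Weinstein position, e.g. ``BWPosition(3, 50)`` is 3.50.

    Ordered by helix, then by index within the helix; rendered as
    ``"<helix>.<index>"``.
    """

    helix: int
    index: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= N_HELICES:
            raise ValueError(f"helix must be 1..7, got {self.helix}")
        if self.index <= 0:
            raise ValueError(f"BW index must be positive, got {self.index}")

    @classmethod
    def parse(cls, text: str) -> "BWPosition":
        """Parse ``"3.50"`` into ``BWPosition(3, 50)``."""
        try:
            helix_s, index_s = str(text).strip().split(".")
            return cls(int(helix_s), int(index_s))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"not a BW position: {text!r}") from exc

    def __str__(self) -> str:
        return f"{self.helix}.{self.index}"

    def __lt__(self, other: "BWPosition") -> bool:
        return (self.helix, self.index) < (other.helix, other.index)


@dataclass(frozen=True)
class PositionPair:
    """An unordered pair of distinct BW positions, stored canonically (a < b)."""

    a: BWPosition
    b: BWPosition

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"pair members must differ, got {self.a} twice")
        if self.b < self.a:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @classmethod
    def of(cls, a: BWPosition | str, b: BWPosition | str) -> "PositionPair":
        if isinstance(a, str):
            a = BWPosition.parse(a)
        if isinstance(b, str):
            b = BWPosition.parse(b)
        return cls(a, b)

    def __str__(self) -> str:
        return f"{self.a}-{self.b}"


@dataclass(frozen=True)
class HelixDefinition:
    """One helix of the bundle: BW range, 5-section partition, orientation.

    ``section_sizes`` are listed from the extracellular side (section 1) to
    the intracellular side (section 5).  ``extracellular_end`` states which
    end of the ascending BW index range is extracellular: ``"first"`` for
    helices whose N-terminal end is extracellular (I, III, V, VII in the
    canonical topology) and ``"last"`` for the others.
    """

    helix: int
    start: int
    end: int
    section_sizes: tuple[int, int, int, int, int]
    extracellular_end: str  # "first" | "last"

    def __post_init__(self) -> None:
        name = f"helix {ROMAN.get(self.helix, self.helix)}"
        if self.end < self.start:
            raise BundleDefinitionError(f"{name}: end {self.end} < start {self.start}")
        if len(self.section_sizes) != N_SECTIONS:
            raise BundleDefinitionError(
                f"{name}: expected {N_SECTIONS} sections, got {len(self.section_sizes)}"
            )
        if any(s <= 0 for s in self.section_sizes):
            raise BundleDefinitionError(f"{name}: sections must be non-empty: {self.section_sizes}")
        if sum(self.section_sizes) != self.length:
            raise BundleDefinitionError(
                f"{name}: section sizes {self.section_sizes} sum to "
                f"{sum(self.section_sizes)} but the range {self.start}..{self.end} "
                f"has {self.length} positions"
            )
        if self.extracellular_end not in ("first", "last"):
            raise BundleDefinitionError(
                f"{name}: extracellular_end must be 'first' or 'last', got {self.extracellular_end!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def indices(self) -> range:
        """Ascending BW indices of this helix."""
        return range(self.start, self.end + 1)

    def section_of(self, index: int) -> int:
        """Section number (1 extracellular .. 5 intracellular) of a BW index."""
        if not self.start <= index <= self.end:
            raise KeyError(f"{self.helix}.{index} outside helix range {self.start}..{self.end}")
        # offset from the extracellular end of the helix
        if self.extracellular_end == "first":
            offset = index - self.start
        else:
            offset = self.end - index
        acc = 0
        for sec, size in enumerate(self.section_sizes, start=1):
            acc += size
            if offset < acc:
                return sec
        raise AssertionError("unreachable: sections cover the range")


@dataclass(frozen=True)
class BundleDefinition:
    """The full 7-helix frame governing an analysis.

    The shipped default covers 200 BW positions.  Helix III runs 3.22-3.55
    (34 positions, sections sized 8/8/4/7/7); section sizes range from 3
    (sections I-1 and VII-5) to 10 (section VI-1).
    """

    helices: tuple[HelixDefinition, ...]
    declared_size: int | None = None

    def __post_init__(self) -> None:
        nums = [h.helix for h in self.helices]
        if sorted(nums) != list(range(1, N_HELICES + 1)):
            raise BundleDefinitionError(f"need helices 1..7 exactly once, got {nums}")
        object.__setattr__(
            self, "helices", tuple(sorted(self.helices, key=lambda h: h.helix))
        )
        if self.declared_size is not None and self.n_positions != self.declared_size:
            sums = ", ".join(
                f"{ROMAN[h.helix]}={h.length}" for h in self.helices
            )
            raise BundleDefinitionError(
                f"declared bundle size {self.declared_size} != total positions "
                f"{self.n_positions} (per-helix: {sums})"
            )

    def helix(self, number: int) -> HelixDefinition:
        return self.helices[number - 1]

    @property
    def n_positions(self) -> int:
        return sum(h.length for h in self.helices)

    @functools.cached_property
    def _positions(self) -> tuple[BWPosition, ...]:
        return tuple(
            BWPosition(h.helix, i) for h in self.helices for i in h.indices()
        )

    def positions(self) -> tuple[BWPosition, ...]:
        """All BW positions in canonical (helix, index) order."""
        return self._positions

    def __contains__(self, pos: BWPosition) -> bool:
        h = self.helices[pos.helix - 1]
        return h.start <= pos.index <= h.end

    def require(self, pos: BWPosition) -> None:
        if pos not in self:
            raise KeyError(f"position {pos} outside the bundle definition")

    def section_of(self, pos: BWPosition) -> int:
        self.require(pos)
        return self.helix(pos.helix).section_of(pos.index)

    def section_label(self, pos: BWPosition) -> str:
        """Section bin label, e.g. ``"III4"`` for a position in helix III section 4."""
        return f"{ROMAN[pos.helix]}{self.section_of(pos)}"

    # -- pair-level classification ------------------------------------------

    def helix_pair_label(self, pair: PositionPair) -> str:
        """One of the 28 unordered helix-pair labels, e.g. ``"I-VI"``."""
        h1, h2 = sorted((pair.a.helix, pair.b.helix))
        return f"{ROMAN[h1]}-{ROMAN[h2]}"

    def section_pair_label(self, pair: PositionPair) -> str:
        """One of the 630 unordered section-pair labels, e.g. ``"I4-VI2"``."""
        ka = (pair.a.helix, self.section_of(pair.a))
        kb = (pair.b.helix, self.section_of(pair.b))
        (h1, s1), (h2, s2) = sorted((ka, kb))
        return f"{ROMAN[h1]}{s1}-{ROMAN[h2]}{s2}"

    def all_helix_pair_labels(self) -> list[str]:
        """The 28 helix-pair labels (7 intrahelical + 21 interhelical), canonical order."""
        return [
            f"{ROMAN[h1]}-{ROMAN[h2]}"
            for h1, h2 in itertools.combinations_with_replacement(range(1, 8), 2)
        ]

    def all_section_pair_labels(self) -> list[str]:
        """The 630 section-pair labels (105 intrahelical + 525 interhelical)."""
        keys = [(h, s) for h in range(1, 8) for s in range(1, 6)]
        return [
            f"{ROMAN[h1]}{s1}-{ROMAN[h2]}{s2}"
            for (h1, s1), (h2, s2) in itertools.combinations_with_replacement(keys, 2)
        ]

    def section_size(self, helix: int, section: int) -> int:
        return self.helix(helix).section_sizes[section - 1]


# ---------------------------------------------------------------------------
# config loading


def _parse_helix(number: int, raw: Mapping) -> HelixDefinition:
    try:
        return HelixDefinition(
            helix=int(number),
            start=int(raw["start"]),
            end=int(raw["end"]),
            section_sizes=tuple(int(s) for s in raw["sections"]),
            extracellular_end=str(raw["extracellular_end"]),
        )
    except KeyError as exc:
        raise BundleDefinitionError(f"helix {number}: missing field {exc}") from exc


def load_bundle_definition(source: str | Path | Mapping) -> BundleDefinition:
    """Load and validate a bundle definition from YAML text, a path, or a dict.

    The config lists seven helices, each with an inclusive BW index range,
    five section sizes (extracellular to intracellular) and the membrane
    orientation of the range.  An optional ``bundle_size`` is cross-checked
    against the per-helix totals.
    """
    if isinstance(source, Mapping):
        data = source
    else:
        path = Path(source)
        if path.exists():
            text = path.read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping) or "helices" not in data:
        raise BundleDefinitionError("config must be a mapping with a 'helices' entry")
    helices = data["helices"]
    if len(helices) != N_HELICES:
        raise BundleDefinitionError(f"need {N_HELICES} helices, got {len(helices)}")
    parsed = tuple(_parse_helix(num, raw) for num, raw in sorted(helices.items(), key=lambda kv: int(kv[0])))
    declared = data.get("bundle_size")
    return BundleDefinition(parsed, declared_size=None if declared is None else int(declared))


@functools.lru_cache(maxsize=1)
def default_definition() -> BundleDefinition:
    """The shipped default 200-position bundle definition."""
    text = resources.files("tmconserve.data").joinpath("default_bundle.yaml").read_text()
    return load_bundle_definition(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# pair-level operations


def enumerate_pairs(
    defn: BundleDefinition, present: Iterable[BWPosition] | None = None
) -> list[PositionPair]:
    """All unordered pairs of distinct present positions, canonically ordered.

    ``present`` defaults to every position of the definition; for a
    present-set of size n the result has n(n-1)/2 pairs.
    """
    if present is None:
        pos = list(defn.positions())
    else:
        pos = sorted(set(present))
        for p in pos:
            defn.require(p)
    if not pos:
        raise ValueError("present set is empty")
    return [PositionPair(a, b) for a, b in itertools.combinations(pos, 2)]


def is_adjacent(pair: PositionPair, defn: BundleDefinition) -> bool:
    """True iff the two positions are consecutive BW indices in the same helix.

    Junction pairs spanning two helices are never adjacent, so the default
    200-position bundle has 200 - 7 = 193 adjacent pairs.
    """
    defn.require(pair.a)
    defn.require(pair.b)
    return pair.a.helix == pair.b.helix and pair.b.index - pair.a.index == 1


def count_adjacent(
    defn: BundleDefinition, present: Iterable[BWPosition] | None = None
) -> int:
    """Number of adjacent pairs among the present positions."""
    return sum(1 for p in enumerate_pairs(defn, present) if is_adjacent(p, defn))


def classify_pair(pair: PositionPair, defn: BundleDefinition) -> tuple[str, str]:
    """Return (helix-pair label, section-pair label) for a pair."""
    return defn.helix_pair_label(pair), defn.section_pair_label(pair)


def parse_helix_pair(label: str) -> tuple[int, int]:
    """Parse ``"I-VI"`` into ``(1, 6)``."""
    try:
        a, b = label.split("-")
        h1, h2 = ROMAN_INV[a.strip()], ROMAN_INV[b.strip()]
    except (ValueError, KeyError) as exc:
        raise ValueError(f"not a helix-pair label: {label!r}") from exc
    return tuple(sorted((h1, h2)))  # type: ignore[return-value]
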