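"""Helix-pair and section-pair enrichment of top-ranked pairs.

The top-N most distance-conserved pairs are binned by the helices (28
unordered helix pairs) or the sections (630 unordered section pairs) their
two residues belong to.  Raw counts are normalised by the number of pairs
each bin could possibly contribute over the ensemble's common positions,
giving a ratio comparable across bins of different size.

Denominator convention: by default ``count_all`` counts every combinatorial
pair in a bin, including sequence-adjacent ones, while the numerator comes
from an adjacency-excluded ranking.  This mirrors reporting in which a
helix's intrahelical total is the plain binomial count (C(34,2) = 561 for
a 34-residue helix) even though adjacent pairs never reach the ranked
list.  Set ``denominator_excludes_adjacent=True`` for fully consistent
numerator/denominator universes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import RankedPairTable
from .frame import ROMAN, BundleDefinition, BWPosition, parse_helix_pair
from .structure_io import EnsembleSet

__all__ = [
    "possible_pair_counts",
    "summarize_helix_pairs",
    "summarize_section_pairs",
    "compare_sets",
]


def _present_positions(
    source: EnsembleSet | Iterable[BWPosition], defn: BundleDefinition
) -> list[BWPosition]:
    if isinstance(source, EnsembleSet):
        present = source.common_positions
    else:
        present = set(source)
    pos = sorted(present)
    for p in pos:
        defn.require(p)
    if len(pos) < 2:
        raise ValueError("need at least 2 present positions")
    return pos


def _pair_label_arrays(
    positions: Sequence[BWPosition], defn: BundleDefinition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(helix_pair, section_pair, adjacent) label arrays over all pairs."""
    helix = np.array([p.helix for p in positions])
    index = np.array([p.index for p in positions])
    section = np.array([defn.section_of(p) for p in positions])
    ia, ib = np.triu_indices(len(positions), k=1)
    ha, hb = helix[ia], helix[ib]
    sa, sb = section[ia], section[ib]
    adjacent = (ha == hb) & (index[ib] - index[ia] == 1)
    hp = np.array([f"{ROMAN[a]}-{ROMAN[b]}" for a, b in zip(ha, hb)])
    swap = (ha == hb) & (sa > sb)
    s_lo = np.where(swap, sb, sa)
    s_hi = np.where(swap, sa, sb)
    sp = np.array(
        [f"{ROMAN[a]}{x}-{ROMAN[b]}{y}" for a, x, b, y in zip(ha, s_lo, hb, s_hi)]
    )
    return hp, sp, adjacent


def possible_pair_counts(
    defn: BundleDefinition,
    present: EnsembleSet | Iterable[BWPosition] | None = None,
    *,
    level: str = "helix",
    exclude_adjacent: bool = False,
) -> pd.Series:
    """Total possible pairs per helix-pair or section-pair bin.

    Counts run over the given present positions (default: the whole
    definition), so missing positions shrink the affected bins.  Every bin
    label appears, zero-filled where no pair is possible.
    """
    if level not in ("helix", "section"):
        raise ValueError(f"level must be 'helix' or 'section', got {level!r}")
    pos = _present_positions(
        present if present is not None else defn.positions(), defn
    )
    hp, sp, adjacent = _pair_label_arrays(pos, defn)
    labels = hp if level == "helix" else sp
    if exclude_adjacent:
        labels = labels[~adjacent]
    all_labels = (
        defn.all_helix_pair_labels() if level == "helix" else defn.all_section_pair_labels()
    )
    counts = pd.Series(labels).value_counts()
    return counts.reindex(all_labels, fill_value=0).rename("count_all")


def _check_consistent(ranked: RankedPairTable, defn: BundleDefinition) -> None:
    pos_ok = {str(p) for p in defn.positions()}
    found = set(ranked.table["bw_a"]).union(ranked.table["bw_b"])
    stray = found - pos_ok
    if stray:
        raise ValueError(
            f"ranked table refers to positions outside the bundle definition: "
            f"{sorted(stray)[:5]}..."
        )


def summarize_helix_pairs(
    ranked: RankedPairTable,
    ensemble: EnsembleSet | Iterable[BWPosition],
    defn: BundleDefinition,
    *,
    denominator_excludes_adjacent: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-N composition by helix pair, normalised by possible pairs.

    Returns ``(summary, cumulative)``: a 28-row summary with columns
    label/count_top/count_all/ratio, and a long-form cumulative table with
    one row per top-ranked pair (rank, label, cum_count, cum_ratio) for
    cumulative-ratio plots.
    """
    _check_consistent(ranked, defn)
    top = ranked.top
    count_all = possible_pair_counts(
        defn, ensemble, level="helix", exclude_adjacent=denominator_excludes_adjacent
    )
    count_top = (
        top["helix_pair"].value_counts().reindex(count_all.index, fill_value=0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(count_all > 0, count_top / count_all, 0.0)
    summary = pd.DataFrame(
        {
            "label": count_all.index,
            "count_top": count_top.to_numpy(),
            "count_all": count_all.to_numpy(),
            "ratio": ratio,
        }
    )
    cum = top[["rank", "helix_pair"]].copy().rename(columns={"helix_pair": "label"})
    cum["cum_count"] = cum.groupby("label").cumcount() + 1
    totals = summary.set_index("label")["count_all"]
    cum["cum_ratio"] = cum["cum_count"] / cum["label"].map(totals).to_numpy()
    return summary, cum.reset_index(drop=True)


def summarize_section_pairs(
    ranked: RankedPairTable,
    ensemble: EnsembleSet | Iterable[BWPosition],
    defn: BundleDefinition,
    *,
    helix_filter: str | tuple[int, int] | None = None,
    denominator_excludes_adjacent: bool = False,
    same_section_detail: Iterable[int] = (4,),
) -> pd.DataFrame:
    """Top-N composition by section pair.

    Without a filter, all 630 section-pair bins are returned.  With a
    ``helix_filter`` (e.g. ``"III-III"`` or ``"I-VI"``), only that helix
    pair's section bins are kept.  For an intrahelical filter the listing
    mirrors the conventional table layout: every cross-section bin is shown
    individually, same-section bins only for the sections named in
    ``same_section_detail`` (default: section 4, the conserved
    middle-to-intracellular band), the remaining same-section bins are
    pooled into an ``others`` row, and a ``total`` row closes the table.
    """
    _check_consistent(ranked, defn)
    top = ranked.top
    count_all = possible_pair_counts(
        defn, ensemble, level="section", exclude_adjacent=denominator_excludes_adjacent
    )
    count_top = (
        top["section_pair"].value_counts().reindex(count_all.index, fill_value=0)
    )
    df = pd.DataFrame({"count_top": count_top, "count_all": count_all})

    if helix_filter is None:
        out = df.reset_index(names="label")
        out["ratio"] = np.where(out["count_all"] > 0, out["count_top"] / out["count_all"], 0.0)
        return out

    h1, h2 = parse_helix_pair(helix_filter) if isinstance(helix_filter, str) else tuple(sorted(helix_filter))
    for h in (h1, h2):
        if not 1 <= h <= 7:
            raise ValueError(f"unknown helix {h} in filter {helix_filter!r}")
    r1, r2 = ROMAN[h1], ROMAN[h2]

    def lbl(s1: int, s2: int) -> str:
        return f"{r1}{s1}-{r2}{s2}"

    rows: list[dict[str, object]] = []
    if h1 == h2:
        detail = set(int(s) for s in same_section_detail)
        listed: list[tuple[int, int]] = [
            (s1, s2)
            for s1 in range(1, 6)
            for s2 in range(s1, 6)
            if s1 != s2 or s1 in detail
        ]
        others = [(s, s) for s in range(1, 6) if s not in detail]
        for s1, s2 in listed:
            rows.append(
                {
                    "section_a": str(s1),
                    "section_b": str(s2),
                    "label": lbl(s1, s2),
                    "count_top": int(df.loc[lbl(s1, s2), "count_top"]),
                    "count_all": int(df.loc[lbl(s1, s2), "count_all"]),
                }
            )
        rows.append(
            {
                "section_a": "others",
                "section_b": "",
                "label": "others",
                "count_top": int(sum(df.loc[lbl(s, s), "count_top"] for s, _ in others)),
                "count_all": int(sum(df.loc[lbl(s, s), "count_all"] for s, _ in others)),
            }
        )
    else:
        for s1 in range(1, 6):
            for s2 in range(1, 6):
                rows.append(
                    {
                        "section_a": str(s1),
                        "section_b": str(s2),
                        "label": lbl(s1, s2),
                        "count_top": int(df.loc[lbl(s1, s2), "count_top"]),
                        "count_all": int(df.loc[lbl(s1, s2), "count_all"]),
                    }
                )
    out = pd.DataFrame(rows)
    out.loc[len(out)] = {
        "section_a": "total",
        "section_b": "",
        "label": "total",
        "count_top": int(out["count_top"].sum()),
        "count_all": int(out["count_all"].sum()),
    }
    out["ratio"] = np.where(out["count_all"] > 0, out["count_top"] / out["count_all"], 0.0)
    return out


def compare_sets(summaries: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-bin ratio differences between named set summaries.

    All summaries must share the same bin labels.  Ratios are joined as
    ``ratio_<name>`` columns; with exactly two sets a ``delta`` column
    (second minus first) is added and rows are sorted by ``|delta|``
    descending.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    names = list(summaries)
    base_labels = list(summaries[names[0]]["label"])
    out = pd.DataFrame({"label": base_labels})
    for name in names:
        df = summaries[name]
        if list(df["label"]) != base_labels:
            raise ValueError(
                f"summary {name!r} has different bin labels than {names[0]!r}"
            )
        out[f"ratio_{name}"] = df["ratio"].to_numpy()
    if len(names) == 2:
        out["delta"] = out[f"ratio_{names[1]}"] - out[f"ratio_{names[0]}"]
        out = (
            out.reindex(out["delta"].abs().sort_values(ascending=False, kind="mergesort").index)
            .reset_index(drop=True)
        )
    return out
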