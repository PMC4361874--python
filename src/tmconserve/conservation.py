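"""Distance-conservation scoring across a structure ensemble.

For every unordered pair of BW positions present in all members of an
ensemble, the Euclidean CA-CA distance is measured in each member and the
mean, standard deviation, minimum and maximum are taken across members.
The conservation score of a pair is the inverse coefficient of variation,

    score = mean / sd,

a dimensionless quantity: a pair whose distance averages 20 A with a
0.4 A standard deviation scores 50.  Pairs of sequence-adjacent residues
sit ~3.8 A apart in any helix and score highly for trivial reasons, so
ranking excludes them by default before the top-N cut.

The standard deviation is the population SD (divide by n).  A pair with
zero SD (e.g. an ensemble of identical copies) gets a capped sentinel
score and a flag rather than infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .frame import ROMAN, BundleDefinition, BWPosition, PositionPair
from .structure_io import AlignedBundle, EnsembleSet

__all__ = [
    "DEFAULT_SCORE_CAP",
    "PairStatsColumns",
    "RankedPairTable",
    "ScoreProfile",
    "pair_distance",
    "score_set",
    "rank_pairs",
    "score_distance_profile",
]

DEFAULT_SCORE_CAP = 1e6

#: Columns of the pair-statistics table produced by :func:`score_set`.
PairStatsColumns = [
    "bw_a", "bw_b", "helix_a", "idx_a", "helix_b", "idx_b",
    "helix_pair", "section_pair", "mean", "sd", "min", "max",
    "score", "sd_zero", "adjacent", "n_members",
]


def pair_distance(bundle: AlignedBundle, pair: PositionPair) -> float:
    """Euclidean CA-CA distance (A) of one pair in one bundle."""
    for pos in (pair.a, pair.b):
        if pos not in bundle.coords_ca:
            raise KeyError(f"{bundle.label}: position {pos} not present")
    d = bundle.coords_ca[pair.a] - bundle.coords_ca[pair.b]
    return float(np.linalg.norm(d))


def score_set(
    ensemble: EnsembleSet,
    defn: BundleDefinition,
    *,
    sd_mode: str = "population",
    score_cap: float = DEFAULT_SCORE_CAP,
) -> pd.DataFrame:
    """Per-pair distance statistics and conservation scores for an ensemble.

    Pairs are restricted to the positions common to every member.  Returns
    one row per pair with the columns in :data:`PairStatsColumns`;
    ``sd_mode`` selects the population (default) or sample SD convention.
    """
    if ensemble.n_members < 2:
        raise ValueError("need >= 2 members to compute an SD")
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"sd_mode must be 'population' or 'sample', got {sd_mode!r}")
    positions = sorted(ensemble.common_positions)
    if len(positions) < 2:
        raise ValueError("fewer than 2 common positions; nothing to score")
    for pos in positions:
        defn.require(pos)

    coords = np.stack(
        [np.stack([m.coords_ca[p] for p in positions]) for m in ensemble.members]
    )  # (M, P, 3)
    dists = np.stack([pdist(c) for c in coords])  # (M, K), K = P(P-1)/2

    mean = dists.mean(axis=0)
    sd = dists.std(axis=0, ddof=0 if sd_mode == "population" else 1)
    dmin = dists.min(axis=0)
    dmax = dists.max(axis=0)
    # robust zero detection: identical members can leave an ulp-sized SD
    sd_zero = sd <= 1e-9 * np.maximum(mean, 1.0)
    with np.errstate(divide="ignore"):
        score = np.where(sd_zero, score_cap, mean / np.where(sd_zero, 1.0, sd))
    score = np.minimum(score, score_cap)

    ia, ib = np.triu_indices(len(positions), k=1)  # same ordering as pdist
    helix = np.array([p.helix for p in positions])
    index = np.array([p.index for p in positions])
    section = np.array([defn.section_of(p) for p in positions])
    bw_str = np.array([str(p) for p in positions])

    ha, hb = helix[ia], helix[ib]
    sa, sb = section[ia], section[ib]
    adjacent = (ha == hb) & (index[ib] - index[ia] == 1)

    helix_pair = [f"{ROMAN[a]}-{ROMAN[b]}" for a, b in zip(ha, hb)]
    # canonical section-pair order: by (helix, section) of each end
    swap = (ha == hb) & (sa > sb)
    s_lo = np.where(swap, sb, sa)
    s_hi = np.where(swap, sa, sb)
    section_pair = [
        f"{ROMAN[a]}{x}-{ROMAN[b]}{y}" for a, x, b, y in zip(ha, s_lo, hb, s_hi)
    ]

    return pd.DataFrame(
        {
            "bw_a": bw_str[ia],
            "bw_b": bw_str[ib],
            "helix_a": ha,
            "idx_a": index[ia],
            "helix_b": hb,
            "idx_b": index[ib],
            "helix_pair": helix_pair,
            "section_pair": section_pair,
            "mean": mean,
            "sd": sd,
            "min": dmin,
            "max": dmax,
            "score": score,
            "sd_zero": sd_zero,
            "adjacent": adjacent,
            "n_members": ensemble.n_members,
        }
    )


@dataclass
class RankedPairTable:
    """Pair statistics sorted by descending score, with ranks assigned.

    ``table`` holds every ranked row (adjacent pairs removed first when
    ``exclude_adjacent``); ``top`` is the head used for classification.
    ``n_stats`` is the size of the unfiltered pair universe, so
    ``retained_fraction`` is top-N / universe (1,000 of 19,900 = 5.0%).
    """

    table: pd.DataFrame
    top_n: int
    exclude_adjacent: bool
    n_stats: int

    @property
    def top(self) -> pd.DataFrame:
        return self.table.head(self.top_n)

    @property
    def retained_fraction(self) -> float:
        return min(self.top_n, len(self.table)) / self.n_stats


def rank_pairs(
    stats: pd.DataFrame, *, exclude_adjacent: bool = True, top_n: int = 1000
) -> RankedPairTable:
    """Sort pair statistics by descending score and assign ranks.

    Adjacency exclusion happens before ranks are assigned, so rank 1 is the
    best non-adjacent pair.  Ties break deterministically by canonical pair
    order, making the result independent of input row order.
    """
    if stats.empty:
        raise ValueError("empty statistics table")
    df = stats[~stats["adjacent"]] if exclude_adjacent else stats
    df = df.sort_values(
        ["score", "helix_a", "idx_a", "helix_b", "idx_b"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    if top_n > len(df):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(df)} ranked pairs; returning all",
            stacklevel=2,
        )
    return RankedPairTable(
        table=df, top_n=min(top_n, len(df)), exclude_adjacent=exclude_adjacent,
        n_stats=len(stats),
    )


@dataclass
class ScoreProfile:
    """Histogram views of a pair-statistics table.

    ``score_hist`` bins scores (capped zero-SD rows are excluded) with
    counts and ascending cumulative counts, each with and without adjacent
    pairs; ``dist_hist`` bins mean distances; ``scatter`` is the
    (mean, score, adjacent) export for score-versus-distance plots.
    """

    score_hist: pd.DataFrame
    dist_hist: pd.DataFrame
    scatter: pd.DataFrame


def score_distance_profile(
    stats: pd.DataFrame, *, score_bin: float = 5.0, dist_bin: float = 0.5
) -> ScoreProfile:
    """Score and mean-distance distributions of a scored pair table."""
    if stats.empty:
        raise ValueError("empty statistics table")

    finite = stats[~stats["sd_zero"]]

    def _hist(values: np.ndarray, adj: np.ndarray, width: float) -> pd.DataFrame:
        if len(values) == 0:
            return pd.DataFrame(
                columns=["lo", "hi", "count_all", "count_nonadj", "cum_all", "cum_nonadj"]
            )
        lo = np.floor(values.min() / width) * width
        hi = np.ceil(values.max() / width) * width
        edges = np.arange(lo, hi + width, width)
        if len(edges) < 2:
            edges = np.array([lo, lo + width])
        c_all, _ = np.histogram(values, bins=edges)
        c_non, _ = np.histogram(values[~adj], bins=edges)
        return pd.DataFrame(
            {
                "lo": edges[:-1],
                "hi": edges[1:],
                "count_all": c_all,
                "count_nonadj": c_non,
                "cum_all": np.cumsum(c_all),
                "cum_nonadj": np.cumsum(c_non),
            }
        )

    score_hist = _hist(
        finite["score"].to_numpy(), finite["adjacent"].to_numpy(), score_bin
    )
    dist_hist = _hist(
        stats["mean"].to_numpy(), stats["adjacent"].to_numpy(), dist_bin
    )
    scatter = stats[["mean", "score", "adjacent"]].copy()
    return ScoreProfile(score_hist=score_hist, dist_hist=dist_hist, scatter=scatter)
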