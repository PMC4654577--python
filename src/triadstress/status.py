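"""Status-rank aggregation for conversing triads.

Each triad member is ranked 1 (high) to 3 (low) on seven component
measures: gestalt status perceptions by three independent judges,
speaking seconds, topics introduced, speaking-turn count, and the
combined peer evaluation. A pair of members is consistently
differentiated only when at least four of the seven components strictly
order them the same way; otherwise the pair is a tie. Ties score 1.5
when shared at the top and 2.5 at the bottom, so triad ranks always sum
to 6.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import ceil
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "COMPONENT_NAMES",
    "StatusComponents",
    "StatusRanks",
    "rank_components",
    "pairwise_compare",
    "aggregate_ranks",
    "tally_ties",
]

COMPONENT_NAMES = (
    "judge_1",
    "judge_2",
    "judge_3",
    "speaking_time",
    "topics",
    "turn_count",
    "peer_evaluation",
)


@dataclass
class StatusComponents:
    """Component rank vectors for one triad.

    ``components`` maps a component name to a rank vector over the three
    members (1 = high, 3 = low; within-component ties allowed and share
    the better rank, e.g. (1, 1, 3)).
    """

    triad_id: str
    members: Tuple[str, str, str]
    components: Dict[str, Sequence[float]]

    def __post_init__(self) -> None:
        if len(self.members) != 3:
            raise ValueError("a triad has exactly 3 members")
        for name, ranks in self.components.items():
            if len(ranks) != 3:
                raise ValueError(f"component {name!r} must rank all 3 members")

    @property
    def names(self) -> List[str]:
        return list(self.components)


@dataclass
class StatusRanks:
    """Final aggregated ranks and hierarchy class for one triad."""

    triad_id: str
    members: Tuple[str, str, str]
    ranks: Tuple[float, float, float]
    hierarchy_class: str  # transitive | top-tie | bottom-tie | flat | unresolved

    def __post_init__(self) -> None:
        if abs(sum(self.ranks) - 6.0) > 1e-9:
            raise ValueError("triad ranks must sum to 6")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.members, self.ranks))


def rank_components(raw: Dict[str, Sequence[float]], triad_id: str = "",
                    members: Sequence[str] = ("A", "B", "C")) -> StatusComponents:
    """Convert raw component measures (higher = better) to 1–3 ranks.

    Ties share the better rank and push later ranks down, so
    (200, 200, 100) ranks as (1, 1, 3).
    """
    comps = {}
    for name, vals in raw.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size != 3:
            raise ValueError(f"component {name!r} needs 3 values")
        comps[name] = tuple(rankdata(-vals, method="min").astype(float))
    return StatusComponents(triad_id, tuple(members), comps)


def pairwise_compare(components: StatusComponents, a: str, b: str,
                     threshold_frac: float = 4.0 / 7.0,
                     strict: bool = False) -> str:
    """Pairwise status outcome: ``"a_over_b"``, ``"b_over_a"`` or ``"tie"``.

    One member is over the other iff at least ``ceil(threshold_frac * k)``
    of the k available components strictly rank him better. With
    ``strict=True`` the majority reading additionally requires zero
    components ordered the other way.
    """
    if a == b:
        raise ValueError("cannot compare a member with himself")
    ia, ib = components.members.index(a), components.members.index(b)
    k = len(components.components)
    need = max(1, ceil(threshold_frac * k - 1e-9))
    a_wins = sum(1 for r in components.components.values() if r[ia] < r[ib])
    b_wins = sum(1 for r in components.components.values() if r[ib] < r[ia])
    if a_wins >= need and (not strict or b_wins == 0):
        return "a_over_b"
    if b_wins >= need and (not strict or a_wins == 0):
        return "b_over_a"
    return "tie"


def _fallback_ranks(components: StatusComponents) -> Tuple[float, ...]:
    """Mean-component-rank fallback for cyclic/inconsistent pairwise
    patterns; maps the resulting order to the 1/1.5/2/2.5/3 scale so the
    triad still sums to 6."""
    mean_rank = np.mean([list(r) for r in components.components.values()], axis=0)
    order = rankdata(mean_rank, method="min")
    patt = tuple(sorted(order))
    if patt == (1, 2, 3):
        return tuple(float(o) for o in order)
    if patt == (1, 1, 3):
        return tuple(1.5 if o == 1 else 3.0 for o in order)
    if patt == (1, 2, 2):
        return tuple(1.0 if o == 1 else 2.5 for o in order)
    return (2.0, 2.0, 2.0)


def aggregate_ranks(components: StatusComponents,
                    threshold_frac: float = 4.0 / 7.0,
                    strict: bool = False) -> StatusRanks:
    """Aggregate the seven components into final triad ranks.

    The three pairwise outcomes determine the hierarchy:

    * a full order gives ranks (1, 2, 3) — class ``transitive``;
    * a tied top pair, both over the third, gives (1.5, 1.5, 3) — ``top-tie``;
    * a clear first over a tied bottom pair gives (1, 2.5, 2.5) — ``bottom-tie``;
    * three ties give (2, 2, 2) — ``flat``;
    * any other (cyclic or inconsistent) pattern is classed
      ``unresolved`` and receives mean-component-rank fallback ranks.
    """
    m = components.members
    wins = {x: 0.0 for x in m}
    ties: List[Tuple[str, str]] = []
    for a, b in combinations(m, 2):
        res = pairwise_compare(components, a, b, threshold_frac, strict)
        if res == "a_over_b":
            wins[a] += 1
        elif res == "b_over_a":
            wins[b] += 1
        else:
            ties.append((a, b))

    n_tie = len(ties)
    ranks = None
    cls = "unresolved"
    w = [wins[x] for x in m]
    if n_tie == 0 and sorted(w) == [0, 1, 2]:
        ranks = tuple(3.0 - wi for wi in w)
        cls = "transitive"
    elif n_tie == 1:
        (a, b) = ties[0]
        if wins[a] == wins[b] == 1 and sorted(w) == [0, 1, 1]:
            # top pair tied, both over third
            ranks = tuple(1.5 if x in (a, b) else 3.0 for x in m)
            cls = "top-tie"
        elif wins[a] == wins[b] == 0 and sorted(w) == [0, 0, 2]:
            # bottom pair tied under a clear first
            ranks = tuple(1.0 if x not in (a, b) else 2.5 for x in m)
            cls = "bottom-tie"
    elif n_tie == 3:
        ranks = (2.0, 2.0, 2.0)
        cls = "flat"
    if ranks is None:
        ranks = _fallback_ranks(components)
        cls = "unresolved"
    return StatusRanks(components.triad_id, m, ranks, cls)


def tally_ties(all_ranks: Sequence[StatusRanks]) -> Tuple[int, int]:
    """Count tied member pairs over all triads.

    Returns ``(n_ties, n_possible_pairs)`` with 3 pairs per triad; a
    pair is tied when the two members share a final rank.
    """
    if not all_ranks:
        return 0, 0
    ties = 0
    for sr in all_ranks:
        for i, j in combinations(range(3), 2):
            if sr.ranks[i] == sr.ranks[j]:
                ties += 1
    return ties, 3 * len(all_ranks)


def ranks_frame(all_ranks: Sequence[StatusRanks]) -> pd.DataFrame:
    """Tidy frame (triad, member, final_rank, class) mirroring the
    published final-ranking table structure."""
    rows = []
    for sr in all_ranks:
        for member, rank in zip(sr.members, sr.ranks):
            rows.append(
                {
                    "triad": sr.triad_id,
                    "member": member,
                    "final_rank": rank,
                    "class": sr.hierarchy_class,
                }
            )
    return pd.DataFrame(rows)
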