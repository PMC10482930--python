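"""Monthly retweet-network influence: unique-retweeter degree and rankings.

Influence is measured as node degree in the monthly retweet graph, where an
edge runs from each retweeter to the user they retweeted and duplicate
retweets by the same user collapse to one edge.  A user's degree is therefore
the number of *distinct* users who retweeted them that month; self-retweets
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .events import RetweetEvent


@dataclass(frozen=True, slots=True)
class DegreeTable:
    """Unique-retweeter degree per user for one month (or the full period)."""

    month: str | None
    degrees: Mapping[str, int]


@dataclass(frozen=True, slots=True)
class RankedList:
    """Top-k users for one month, rank 1 = highest degree; degrees non-increasing.

    ``short`` flags a ranking truncated by population (fewer than k users).
    """

    month: str | None
    users: tuple[str, ...]
    degrees: tuple[int, ...] = ()
    short: bool = False

    def __post_init__(self):
        if self.degrees and any(
            a < b for a, b in zip(self.degrees, self.degrees[1:])
        ):
            raise ValueError("degrees must be non-increasing along the ranking")


def build_degree_table(events: Iterable[RetweetEvent], month: str | None = None) -> DegreeTable:
    """Count distinct retweeters per source user over the given events.

    Every user appearing in any event (as retweeter or source) gets an entry;
    users who were never retweeted by someone else have degree 0.
    """
    g = nx.DiGraph()
    for e in events:
        g.add_node(e.retweeter_id)
        g.add_node(e.source_user_id)
        if e.retweeter_id != e.source_user_id:  # self-retweets carry no influence
            g.add_edge(e.retweeter_id, e.source_user_id)
    return DegreeTable(month=month, degrees={u: d for u, d in g.in_degree()})


def influence_ranking(table: DegreeTable, k: int) -> RankedList:
    """Top-k users by degree; ties broken by lexicographic user identifier.

    If the table holds fewer than ``k`` users the full ranking is returned
    with ``short=True``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(table.degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return RankedList(
        month=table.month,
        users=tuple(u for u, _ in ranked),
        degrees=tuple(d for _, d in ranked),
        short=len(ranked) < k,
    )
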