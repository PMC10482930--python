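"""Seeded stance propagation through the retweet graph, plus coverage stats.

Starting from a seed set of manually tagged users (pro-use / anti-use), labels
spread outward one hop at a time: at hop h, every still-unlabelled user who
retweeted at least one user labelled by the end of hop h−1 is assigned the
stance they retweeted more often (with multiplicity); an exact tie gives
``undetermined``.  Labels freeze once assigned, undetermined users do not
transmit, and propagation stops at ``max_hops`` or when a hop labels no one.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .events import RetweetEvent
from .influence import RankedList

logger = logging.getLogger(__name__)

PRO = "pro_use"
ANTI = "anti_use"
UNDETERMINED = "undetermined"
STANCES = (PRO, ANTI, UNDETERMINED)


@dataclass(frozen=True, slots=True)
class StanceLabel:
    """A user's stance with the hop it was assigned at (0 = seed)."""

    user: str
    stance: str
    hop: int = 0
    is_seed: bool = False

    def __post_init__(self):
        if self.stance not in STANCES:
            raise ValueError(f"unknown stance {self.stance!r}")


@dataclass(frozen=True, slots=True)
class CoverageStats:
    """Population coverage of the propagated labels.

    ``coverage_pct`` and ``pro_share_pct`` are raw percentages; round to one
    decimal for reporting via :meth:`as_report`.
    """

    total_users: int
    n_pro: int
    n_anti: int

    @property
    def coverage_pct(self) -> float:
        return 100.0 * (self.n_pro + self.n_anti) / self.total_users

    @property
    def pro_share_pct(self) -> float:
        labelled = self.n_pro + self.n_anti
        return 100.0 * self.n_pro / labelled if labelled else 0.0

    def as_report(self) -> dict:
        return {
            "total_users": self.total_users,
            "n_pro": self.n_pro,
            "n_anti": self.n_anti,
            "coverage_pct": round(self.coverage_pct, 1),
            "pro_share_pct": round(self.pro_share_pct, 1),
        }


def propagate_stance(
    events: Iterable[RetweetEvent],
    seeds: Iterable[StanceLabel],
    max_hops: int,
) -> dict[str, StanceLabel]:
    """Propagate seed labels through the retweet graph by majority retweet.

    ``events`` should be the full-period stream for one language.  Seed users
    absent from the event set are kept (with a warning) but cannot receive
    retweets, so they transmit nothing.  Returns every labelled user,
    seeds included; users who never retweeted a labelled user are absent.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    if max_hops < 1:
        raise ValueError(f"max_hops must be >= 1, got {max_hops}")

    retweet_counts: dict[str, Counter] = defaultdict(Counter)
    participants: set[str] = set()
    for e in events:
        retweet_counts[e.retweeter_id][e.source_user_id] += 1
        participants.add(e.retweeter_id)
        participants.add(e.source_user_id)

    labels: dict[str, StanceLabel] = {}
    for seed in seeds:
        if seed.user not in participants:
            logger.warning("seed user %s absent from event set; kept", seed.user)
        labels[seed.user] = StanceLabel(seed.user, seed.stance, hop=0, is_seed=True)

    for hop in range(1, max_hops + 1):
        # labels fixed at the end of the previous hop; undetermined users
        # never transmit
        transmitters = {u: lab.stance for u, lab in labels.items() if lab.stance in (PRO, ANTI)}
        new: dict[str, StanceLabel] = {}
        for user, ctr in retweet_counts.items():
            if user in labels:
                continue
            n_pro = n_anti = 0
            for source, mult in ctr.items():
                stance = transmitters.get(source)
                if stance == PRO:
                    n_pro += mult
                elif stance == ANTI:
                    n_anti += mult
            if n_pro == 0 and n_anti == 0:
                continue
            if n_pro > n_anti:
                stance = PRO
            elif n_anti > n_pro:
                stance = ANTI
            else:
                stance = UNDETERMINED
            new[user] = StanceLabel(user, stance, hop=hop, is_seed=False)
        if not new:
            break
        labels.update(new)
    return labels


def coverage_stats(labels: Mapping[str, StanceLabel] | Iterable[StanceLabel], total_users: int) -> CoverageStats:
    """Coverage of the labelled population: 100·(n_pro+n_anti)/total_users."""
    if total_users <= 0:
        raise ValueError(f"total_users must be positive, got {total_users}")
    values = labels.values() if isinstance(labels, Mapping) else labels
    n_pro = n_anti = 0
    for lab in values:
        if lab.stance == PRO:
            n_pro += 1
        elif lab.stance == ANTI:
            n_anti += 1
    if n_pro + n_anti > total_users:
        raise ValueError("labelled users exceed the stated population size")
    return CoverageStats(total_users=total_users, n_pro=n_pro, n_anti=n_anti)


def stance_timeseries(
    rankings: Sequence[RankedList],
    labels: Mapping[str, StanceLabel],
    k: int = 10,
) -> list[tuple[str, int, int, int]]:
    """Per-month (pro, anti, undetermined) counts among the top-k ranked users.

    Unlabelled top-k users count as undetermined, so the three counts sum to
    the number of ranked users considered each month (k unless short).
    """
    out: list[tuple[str, int, int, int]] = []
    for ranking in sorted(rankings, key=lambda r: r.month or ""):
        top = ranking.users[:k]
        n_pro = n_anti = n_und = 0
        for user in top:
            lab = labels.get(user)
            if lab is not None and lab.stance == PRO:
                n_pro += 1
            elif lab is not None and lab.stance == ANTI:
                n_anti += 1
            else:
                n_und += 1
        out.append((ranking.month or "", n_pro, n_anti, n_und))
    return out
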