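"""Rank Biased Overlap (RBO) between ranked user lists and monthly churn series.

RBO compares two rankings S and T as a geometrically weighted average of
their prefix-overlap proportions,

    RBO(S, T, p) = (1 − p) Σ_d p^(d−1) · A_d,

where A_d = |S[:d] ∩ T[:d]| / d and 0 < p < 1.  Early ranks dominate the sum,
so the score is most sensitive to churn among the top-ranked (most
influential) users.  The *truncated* variant evaluates the sum to a finite
depth, where identical lists score 1 − p^depth; the *extrapolated* variant
adds p^depth · A_depth so that identical lists score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .influence import RankedList

VARIANTS = ("truncated", "extrapolated")


@dataclass(frozen=True, slots=True)
class RBOResult:
    """An RBO score together with the parameters it was evaluated at."""

    score: float
    p: float
    depth: int
    variant: str

    def __post_init__(self):
        if not (-1e-12 <= self.score <= 1.0 + 1e-12):
            raise ValueError(f"RBO score out of [0, 1]: {self.score}")


def _as_items(ranking: RankedList | Sequence[str]) -> tuple[str, ...]:
    if isinstance(ranking, RankedList):
        return ranking.users
    return tuple(ranking)


def rbo(
    s: RankedList | Sequence[str],
    t: RankedList | Sequence[str],
    p: float = 0.9,
    depth: int | None = None,
    variant: str = "extrapolated",
) -> RBOResult:
    """RBO between two duplicate-free rankings, evaluated to ``depth``.

    ``depth`` defaults to the length of the shorter list and may not exceed
    it.  Symmetric in its list arguments.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly inside (0, 1), got {p}")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    s_items, t_items = _as_items(s), _as_items(t)
    for name, items in (("S", s_items), ("T", t_items)):
        if len(set(items)) != len(items):
            raise ValueError(f"list {name} contains duplicate entries")
    max_depth = min(len(s_items), len(t_items))
    if depth is None:
        depth = max_depth
    if not 1 <= depth <= max_depth:
        raise ValueError(f"depth must lie in [1, {max_depth}], got {depth}")

    seen_s: set[str] = set()
    seen_t: set[str] = set()
    overlap = 0
    acc = 0.0
    a_d = 0.0
    weight = 1.0  # p^(d-1)
    for d in range(1, depth + 1):
        x, y = s_items[d - 1], t_items[d - 1]
        if x == y:
            overlap += 1
        else:
            if x in seen_t:
                overlap += 1
            if y in seen_s:
                overlap += 1
        seen_s.add(x)
        seen_t.add(y)
        a_d = overlap / d
        acc += weight * a_d
        weight *= p
    score = (1.0 - p) * acc
    if variant == "extrapolated":
        score += (p**depth) * a_d
    return RBOResult(score=min(score, 1.0), p=p, depth=depth, variant=variant)


def monthly_rbo_series(
    rankings: Sequence[RankedList],
    p: float = 0.9,
    k: int = 10,
    variant: str = "extrapolated",
) -> list[tuple[str, RBOResult]]:
    """RBO between each consecutive month pair, attributed to the later month.

    Rankings are compared on their top-``k`` prefixes; months whose lists are
    shorter than ``k`` are compared at the available depth.  Fewer than two
    months yields an empty series.
    """
    ordered = sorted(rankings, key=lambda r: r.month or "")
    series: list[tuple[str, RBOResult]] = []
    for prev, cur in zip(ordered, ordered[1:]):
        depth = min(k, len(prev.users), len(cur.users))
        if depth == 0:
            continue
        result = rbo(prev.users[:depth], cur.users[:depth], p=p, depth=depth, variant=variant)
        series.append((cur.month or "", result))
    return series
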