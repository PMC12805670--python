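"""Shortest common super-hypersequence (SCH) computation.

Two hyperelements may be matched iff one contains the other; matching
emits the superset.  The pairwise problem is solved exactly by dynamic
programming with the fixed scoring match 0 / mismatch forbidden / gap 1
(a mismatch of incomparable sets is simply not a legal transition, which
sidesteps any "large number" arithmetic).  More than two rows are folded
by progressive alignment, which is a heuristic: the result is always a
common super-hypersequence but not necessarily a shortest one.
"""

from __future__ import annotations

import heapq
import math
from functools import reduce
from typing import Optional, Sequence

from .encoding import HyperElement, Hypersequence

__all__ = [
    "element_match",
    "pairwise_sch",
    "progressive_sch",
    "exact_sch",
    "is_superhypersequence",
]


def element_match(e1: HyperElement, e2: HyperElement
                  ) -> tuple[bool, Optional[HyperElement]]:
    """Containment matching: (matchable, merged superset)."""
    if e1 <= e2:
        return True, e2
    if e2 <= e1:
        return True, e1
    return False, None


_MATCH, _TAKE2, _TAKE1 = 0, 1, 2  # traceback moves, in tie-break priority


def pairwise_sch(s1: Hypersequence, s2: Hypersequence) -> Hypersequence:
    """Exact shortest common super-hypersequence of two rows.

    The result length is ``len(s1) + len(s2) - matches`` and is optimal
    for two sequences.  Tie-breaking prefers a match over a gap in the
    first row over a gap in the second, so the output is deterministic.
    """
    n, m = len(s1), len(s2)
    if n == 0:
        return tuple(s2)
    if m == 0:
        return tuple(s1)
    INF = n + m + 1
    # cost[i][j] = length of a shortest super-hypersequence of s1[:i], s2[:j]
    cost = [[0] * (m + 1) for _ in range(n + 1)]
    move = [[_TAKE1] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        cost[i][0] = i
        move[i][0] = _TAKE1
    for j in range(1, m + 1):
        cost[0][j] = j
        move[0][j] = _TAKE2
    for i in range(1, n + 1):
        a = s1[i - 1]
        row = cost[i]
        above = cost[i - 1]
        mrow = move[i]
        for j in range(1, m + 1):
            b = s2[j - 1]
            best = INF
            bestmove = _TAKE1
            if a <= b or b <= a:
                best = above[j - 1] + 1
                bestmove = _MATCH
            c2 = row[j - 1] + 1
            if c2 < best:
                best, bestmove = c2, _TAKE2
            c1 = above[j] + 1
            if c1 < best:
                best, bestmove = c1, _TAKE1
            row[j] = best
            mrow[j] = bestmove
    out: list[HyperElement] = []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == _MATCH:
            a, b = s1[i - 1], s2[j - 1]
            out.append(b if a <= b else a)
            i -= 1
            j -= 1
        elif mv == _TAKE2:
            out.append(s2[j - 1])
            j -= 1
        else:
            out.append(s1[i - 1])
            i -= 1
    out.reverse()
    return tuple(out)


def progressive_sch(rows: Sequence[Hypersequence]) -> Hypersequence:
    """Fold :func:`pairwise_sch` over the rows in the given order.

    A common super-hypersequence of every input row; identical to the
    pairwise result for up to two rows.
    """
    if not rows:
        raise ValueError("progressive_sch requires at least one row")
    return reduce(pairwise_sch, [tuple(r) for r in rows])


def exact_sch(rows: Sequence[Hypersequence], taxon: str,
              max_states: int = 200_000) -> Optional[Hypersequence]:
    """Exact cheapest common super-hypersequence of one taxon's rows.

    Uniform-cost search over index vectors.  Each step emits one of the
    current front elements and advances every row whose front it
    contains; emitting anything other than a maximal front only adds
    cost, so this move set preserves optimality.  The step cost is the
    number of members other than ``taxon`` in the emitted element —
    exactly the reticulation references the merged row contributes.
    Returns ``None`` when the state-space bound ``max_states`` would be
    exceeded, so callers can fall back to progressive alignment.
    """
    parts = [tuple(r) for r in rows]
    if not parts:
        raise ValueError("exact_sch requires at least one row")
    bound = 1
    for p in parts:
        bound *= len(p) + 1
        if bound > max_states:
            return None
    k = len(parts)
    start = (0,) * k
    goal = tuple(len(p) for p in parts)
    dist: dict[tuple, int] = {start: 0}
    prev: dict[tuple, tuple] = {start: (None, None)}
    heap: list[tuple[int, tuple]] = [(0, start)]
    while heap:
        cost, state = heapq.heappop(heap)
        if state == goal:
            break
        if cost > dist.get(state, math.inf):
            continue
        fronts = [(i, parts[i][state[i]]) for i in range(k)
                  if state[i] < len(parts[i])]
        seen = set()
        for _, e in fronts:
            if e in seen:
                continue
            seen.add(e)
            nxt = list(state)
            for i, f in fronts:
                if f <= e:
                    nxt[i] += 1
            nxt = tuple(nxt)
            ncost = cost + len(e - {taxon})
            if ncost < dist.get(nxt, math.inf):
                dist[nxt] = ncost
                prev[nxt] = (state, e)
                heapq.heappush(heap, (ncost, nxt))
    out: list[HyperElement] = []
    state = goal
    while prev[state][0] is not None:
        state, e = prev[state]
        out.append(e)
    out.reverse()
    return tuple(out)


def is_superhypersequence(sup: Hypersequence, sub: Hypersequence) -> bool:
    """Order-preserving embedding test with containment matching.

    Greedy leftmost matching is exact for subsequence embedding.
    """
    j = 0
    for element in sup:
        if j < len(sub):
            e = sub[j]
            if e <= element or element <= e:
                j += 1
    return j == len(sub)
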