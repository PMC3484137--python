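"""Rate-class partitions for the reversible-jump model space.

A partition assigns each of the eight dependent-model rates to a class;
rates in one class share a single value.  An optional zero class pins
its members to rate 0.  Assignments are stored as integer vectors
(class index per rate, -1 for the zero class); the canonical form
labels each class by its smallest member so equal partitions compare
equal.

A sampled partition realises the independent model exactly when the
four independence pairs (q12,q34), (q21,q43), (q13,q24), (q31,q42) each
share a class (model identity is structural, not numerical coincidence).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from typing import Iterator

import numpy as np

from .ctmc import INDEPENDENCE_PAIR_INDICES, RATE_NAMES

__all__ = [
    "canonical_partition", "partition_string", "is_independent_partition",
    "iter_partitions", "bell_number", "count_model_space",
]

N_RATES = len(RATE_NAMES)
ZERO = -1


def canonical_partition(assign) -> tuple[int, ...]:
    """Label each class by its smallest member index (zero class stays -1)."""
    assign = list(assign)
    out = []
    for i, c in enumerate(assign):
        if c == ZERO:
            out.append(ZERO)
        else:
            out.append(min(j for j, cj in enumerate(assign) if cj == c))
    return tuple(out)


def partition_string(assign) -> str:
    """Human-readable form, e.g. ``{q12,q34}{q13}Z{q21}``."""
    canon = canonical_partition(assign)
    classes: dict[int, list[str]] = {}
    for i, c in enumerate(canon):
        classes.setdefault(c, []).append(RATE_NAMES[i])
    parts = []
    for c in sorted(classes):
        body = "{" + ",".join(classes[c]) + "}"
        parts.append("Z" + body if c == ZERO else body)
    return "".join(parts)


def is_independent_partition(assign) -> bool:
    assign = list(assign)
    return all(assign[a] == assign[b] for a, b in INDEPENDENCE_PAIR_INDICES)


def iter_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of n elements as restricted-growth strings."""
    a = [0] * n

    def rec(i: int, mx: int):
        if i == n:
            yield tuple(a)
            return
        for c in range(mx + 2):
            a[i] = c
            yield from rec(i + 1, max(mx, c))
    yield from rec(1, 0) if n > 1 else iter([(0,)] if n == 1 else [()])


@lru_cache(maxsize=None)
def bell_number(n: int) -> int:
    """Bell number via the Bell-triangle recurrence."""
    if n == 0:
        return 1
    row = [1]
    for _ in range(n - 1):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        row = new
    return row[-1]


def _iter_model_space(zero_class: bool) -> Iterator[tuple[int, ...]]:
    if not zero_class:
        yield from iter_partitions(N_RATES)
        return
    idx = list(range(N_RATES))
    for k in range(N_RATES + 1):
        for zeroed in combinations(idx, k):
            rest = [i for i in idx if i not in zeroed]
            if not rest:
                yield tuple([ZERO] * N_RATES)
                continue
            for sub in iter_partitions(len(rest)):
                a = [ZERO] * N_RATES
                for pos, c in zip(rest, sub):
                    a[pos] = c + 1  # keep clear of the zero marker
                yield tuple(a)


def count_model_space(zero_class_enabled: bool = False) -> tuple[int, int]:
    """(total partitions, independent partitions) by exact enumeration."""
    total = indep = 0
    for a in _iter_model_space(zero_class_enabled):
        total += 1
        if is_independent_partition(a):
            indep += 1
    return total, indep
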