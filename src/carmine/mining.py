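"""Closed frequent itemset enumeration.

A frequent itemset J is *closed* when no proper superset has the same tidset;
the closed sets determine the support of every frequent itemset, so rules are
generated from them without information loss. The closed family is unique, so
any correct enumerator is interchangeable; two are provided:

``lcm``
    Depth-first prefix-preserving closure extension (the LCM scheme), driven
    by integer-bitmask tidsets. Cost per search node is O(m^2) bit
    intersections, which is what you want for databases with few dozen items
    and up to a few hundred transactions (the clinical tables here).

``rowset``
    Enumeration of transaction subsets: every closed itemset is the item
    intersection of the rows of its tidset, so for tiny databases (here, the
    per-group expression sub-databases with at most ~10 rows) all 2^n - 1 row
    subsets are intersected and deduplicated with vectorised numpy. Cost is
    independent of the number of items per node, which is what you want for
    thousands of gene items over a handful of subjects.

``brute_force_closed`` is an intentionally naive oracle over all 2^m itemsets,
kept for verification only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .transactions import Item, TransactionDB, item_sort_key

_ROWSET_MAX_N = 16
_BRUTE_MAX_M = 20


@dataclass(frozen=True)
class ClosedItemset:
    """A closed frequent itemset with its supporting transactions."""

    itemset: frozenset[Item]
    tidset: frozenset[int]  # 1-based

    @property
    def support(self) -> int:
        return len(self.tidset)

    def sort_key(self):
        return (-self.support, tuple(sorted(self.itemset, key=item_sort_key)))


@dataclass(frozen=True)
class MiningParams:
    """User-set mining thresholds: an absolute minimum support count and a
    minimum confidence fraction."""

    min_sup: int
    min_conf: float

    def __post_init__(self) -> None:
        if self.min_sup < 1:
            raise ValueError(f"min_sup must be >= 1, got {self.min_sup}")
        # min_conf > 1 is permitted and simply yields no rule: handy for
        # switching rule generation off without touching the mining stage.
        if self.min_conf <= 0:
            raise ValueError(f"min_conf must be > 0, got {self.min_conf}")


def closure(db: TransactionDB, itemset: Iterable[Item]) -> frozenset[Item]:
    """The maximal superset of ``itemset`` with the same tidset.

    Undefined (raises ``ValueError``) when the tidset is empty: there is no
    meaningful intersection over zero transactions.
    """
    mask = db.contains_mask(itemset)
    if not mask.any():
        raise ValueError("closure undefined for an itemset with empty tidset")
    common = db.matrix[mask].all(axis=0)
    return frozenset(db.items[j] for j in np.flatnonzero(common))


def mine_closed(
    db: TransactionDB,
    min_sup: int,
    method: Literal["auto", "lcm", "rowset"] = "auto",
) -> list[ClosedItemset]:
    """All closed itemsets of ``db`` with support >= ``min_sup``.

    The empty itemset appears in the output iff it is its own closure, i.e.
    no item is present in every transaction. Output order is deterministic:
    support descending, then canonical item order.
    """
    if min_sup < 1:
        raise ValueError(f"min_sup must be >= 1, got {min_sup}")
    if min_sup > db.n:
        warnings.warn(
            f"min_sup={min_sup} exceeds the {db.n} transactions; no itemset can be frequent"
        )
        return []
    if method == "auto":
        method = "rowset" if db.n <= 12 else "lcm"
    if method == "rowset":
        found = _mine_rowset(db, min_sup)
    elif method == "lcm":
        found = _mine_lcm(db, min_sup)
    else:
        raise ValueError(f"unknown method {method!r}")
    found.sort(key=ClosedItemset.sort_key)
    return found


def _mine_rowset(db: TransactionDB, min_sup: int) -> list[ClosedItemset]:
    if db.n > _ROWSET_MAX_N:
        raise ValueError(
            f"rowset enumeration is exponential in n; refusing n={db.n} > {_ROWSET_MAX_N}"
        )
    rows = db.matrix
    n = db.n
    seen: set[bytes] = set()
    out: list[ClosedItemset] = []
    for submask in range(1, 1 << n):
        if submask.bit_count() < min_sup:
            # the tidset of the intersection of these rows is >= this subset,
            # but any closed set with support >= min_sup is also generated by
            # the subset equal to its full tidset, so small subsets are moot
            continue
        idx = [i for i in range(n) if submask >> i & 1]
        inter = rows[idx].all(axis=0)
        key = inter.tobytes()
        if key in seen:
            continue
        seen.add(key)
        cols = np.flatnonzero(inter)
        contains = rows[:, cols].all(axis=1) if cols.size else np.ones(n, dtype=bool)
        supp = int(contains.sum())
        if supp < min_sup:
            continue
        itemset = frozenset(db.items[j] for j in cols.tolist())
        tids = frozenset((np.flatnonzero(contains) + 1).tolist())
        out.append(ClosedItemset(itemset, tids))
    return out


def _tids_from_mask(mask: int) -> frozenset[int]:
    out = []
    i = 1
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return frozenset(out)


def _mine_lcm(db: TransactionDB, min_sup: int) -> list[ClosedItemset]:
    masks = db.item_masks()
    m = db.m
    full = (1 << db.n) - 1
    out: list[ClosedItemset] = []

    def clo(tid: int) -> list[int]:
        return [j for j in range(m) if masks[j] & tid == tid]

    def emit(items: list[int], tid: int) -> None:
        out.append(
            ClosedItemset(frozenset(db.items[j] for j in items), _tids_from_mask(tid))
        )

    def rec(P: list[int], P_set: set[int], tid: int, core: int) -> None:
        emit(P, tid)
        for i in range(core + 1, m):
            if i in P_set:
                continue
            t2 = tid & masks[i]
            if t2.bit_count() < min_sup:
                continue
            Q = clo(t2)
            # prefix-preserving check: the closure may only add items >= i
            # beyond those already in P, otherwise this branch is a duplicate
            if all(j in P_set or j >= i for j in Q):
                rec(Q, set(Q), t2, i)

    root = clo(full)
    rec(root, set(root), full, -1)
    return out


def brute_force_closed(db: TransactionDB, min_sup: int) -> list[ClosedItemset]:
    """Oracle: enumerate all 2^m itemsets, keep the frequent ones, filter to
    those no single-item extension of which preserves the tidset.

    Refuses item universes larger than 20 (exponential blowup guard).
    """
    if min_sup < 1:
        raise ValueError(f"min_sup must be >= 1, got {min_sup}")
    if db.m > _BRUTE_MAX_M:
        raise ValueError(
            f"brute force is exponential in the item universe; refusing m={db.m} > {_BRUTE_MAX_M}"
        )
    if min_sup > db.n:
        warnings.warn(f"min_sup={min_sup} exceeds the {db.n} transactions")
        return []
    masks = db.item_masks()
    full = (1 << db.n) - 1
    tids: list[int] = [0] * (1 << db.m)
    tids[0] = full
    for s in range(1, 1 << db.m):
        low = (s & -s).bit_length() - 1
        tids[s] = tids[s & (s - 1)] & masks[low]
    out: list[ClosedItemset] = []
    for s in range(1 << db.m):
        tid = tids[s]
        if tid.bit_count() < min_sup:
            continue
        closed = all(
            s >> i & 1 or masks[i] & tid != tid for i in range(db.m)
        )
        if closed:
            itemset = frozenset(db.items[j] for j in range(db.m) if s >> j & 1)
            out.append(ClosedItemset(itemset, _tids_from_mask(tid)))
    out.sort(key=ClosedItemset.sort_key)
    return out
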