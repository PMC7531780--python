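"""Binary transaction databases with tid-set indexing.

A transaction is one subject's set of attribute=value *items* (e.g. ``FPG=3``
for an established-diabetes fasting-glucose code, or ``229026_at=1`` for an
over-expressed probeset). The database is conceptually a binary matrix with
one row per transaction and one column per item; every itemset query reduces
to an intersection of per-item transaction-id sets (tidsets).

Transaction identifiers are 1-based in every public return value, matching
the usual set notation X = {1..n}; internally a boolean matrix and integer
bitmasks are used.
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np


class Item(NamedTuple):
    """An attribute=value pair.

    ``value`` is a category code for clinical attributes, or a signed unit for
    gene items (+1 = over-expressed, -1 = under-expressed).
    """

    attribute: str
    value: int

    def __str__(self) -> str:  # "FPG=3", "229026_at=-1"
        return f"{self.attribute}={self.value}"


_ITEM_RE = re.compile(r"^\s*(?P<attr>.+?)\s*=\s*(?P<val>[+-]?\d+)\s*$")


def parse_item(text: str) -> Item:
    """Parse ``"attr=value"`` back into an :class:`Item`."""
    m = _ITEM_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse item from {text!r}")
    return Item(m.group("attr"), int(m.group("val")))


def item_sort_key(item: Item) -> tuple[str, int]:
    """Canonical item order: lexicographic by (attribute, value)."""
    return (item.attribute, item.value)


def format_itemset(itemset: Iterable[Item]) -> str:
    return ", ".join(str(i) for i in sorted(itemset, key=item_sort_key))


def validate_itemset(items: Iterable[Item], context: str = "itemset") -> frozenset[Item]:
    """Check that no attribute appears twice (an attribute cannot take two
    values simultaneously) and return the canonical frozenset."""
    fs = frozenset(items)
    seen: dict[str, int] = {}
    for it in sorted(fs, key=item_sort_key):
        if it.attribute in seen:
            raise ValueError(
                f"duplicate attribute {it.attribute!r} in {context}: "
                f"values {seen[it.attribute]} and {it.value}"
            )
        seen[it.attribute] = it.value
    return fs


class TransactionDB:
    """A set of transactions over a universe of items.

    Parameters
    ----------
    transactions:
        One iterable of :class:`Item` per transaction. Attribute names must be
        unique within a transaction.
    labels:
        Optional class label per transaction (patient group 1-5 here).
    """

    def __init__(
        self,
        transactions: Sequence[Iterable[Item]],
        labels: Optional[Sequence[int]] = None,
    ) -> None:
        if len(transactions) == 0:
            raise ValueError("empty database: no transactions given")
        if labels is not None and len(labels) != len(transactions):
            raise ValueError(
                f"{len(labels)} labels for {len(transactions)} transactions"
            )
        itemsets = [
            validate_itemset(t, context=f"transaction {i + 1}")
            for i, t in enumerate(transactions)
        ]
        universe = sorted(set().union(*itemsets), key=item_sort_key)
        index = {item: j for j, item in enumerate(universe)}
        matrix = np.zeros((len(itemsets), len(universe)), dtype=bool)
        for i, t in enumerate(itemsets):
            for item in t:
                matrix[i, index[item]] = True
        self.items: list[Item] = universe
        self.item_index: dict[Item, int] = index
        self.matrix: np.ndarray = matrix
        self.labels: Optional[list[int]] = list(labels) if labels is not None else None
        self._masks: Optional[list[int]] = None

    # -- basic queries ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def transaction(self, tid: int) -> frozenset[Item]:
        """Itemset of 1-based transaction ``tid``."""
        row = self.matrix[tid - 1]
        return frozenset(self.items[j] for j in np.flatnonzero(row))

    def _columns(self, itemset: Iterable[Item]) -> list[int]:
        cols = []
        for item in itemset:
            j = self.item_index.get(item)
            if j is None:
                raise KeyError(f"unknown item {item.attribute}={item.value}")
            cols.append(j)
        return cols

    def contains_mask(self, itemset: Iterable[Item]) -> np.ndarray:
        """Boolean vector: which transactions contain all items of ``itemset``."""
        cols = self._columns(itemset)
        if not cols:
            return np.ones(self.n, dtype=bool)
        return self.matrix[:, cols].all(axis=1)

    def tidset(self, itemset: Iterable[Item]) -> frozenset[int]:
        """J-down: 1-based ids of transactions containing every item of J."""
        return frozenset((np.flatnonzero(self.contains_mask(itemset)) + 1).tolist())

    def support(self, itemset: Iterable[Item]) -> int:
        """sigma(J) = |J-down|; the empty itemset has support n."""
        return int(self.contains_mask(itemset).sum())

    # -- bitmask view (used by the depth-first closed miner) ---------------

    def item_masks(self) -> list[int]:
        """Per-item tidsets as integer bitmasks (bit i = transaction i+1)."""
        if self._masks is None:
            masks = []
            for j in range(self.m):
                bits = 0
                for i in np.flatnonzero(self.matrix[:, j]).tolist():
                    bits |= 1 << i
                masks.append(bits)
            self._masks = masks
        return self._masks

    # -- derived databases -------------------------------------------------

    def restrict_items(self, keep) -> "TransactionDB":
        """Sub-database over the items for which ``keep(item)`` is true.

        Transactions are preserved positionally (a transaction may become
        empty); labels carry over.
        """
        kept = [it for it in self.items if keep(it)]
        cols = [self.item_index[it] for it in kept]
        sub = TransactionDB.__new__(TransactionDB)
        sub.items = kept
        sub.item_index = {it: j for j, it in enumerate(kept)}
        sub.matrix = self.matrix[:, cols].copy()
        sub.labels = None if self.labels is None else list(self.labels)
        sub._masks = None
        return sub

    def restrict_transactions(self, rows: Sequence[int]) -> "TransactionDB":
        """Sub-database of the given 1-based transaction ids (in order)."""
        idx = [r - 1 for r in rows]
        for r in idx:
            if not 0 <= r < self.n:
                raise IndexError(f"transaction id {r + 1} out of range 1..{self.n}")
        sub = TransactionDB.__new__(TransactionDB)
        sub.items = list(self.items)
        sub.item_index = dict(self.item_index)
        sub.matrix = self.matrix[idx, :].copy()
        sub.labels = None if self.labels is None else [self.labels[r] for r in idx]
        sub._masks = None
        return sub

    def class_transactions(self, label: int) -> list[int]:
        """1-based ids of transactions carrying ``label``."""
        if self.labels is None:
            raise ValueError("database has no class labels")
        return [i + 1 for i, lab in enumerate(self.labels) if lab == label]


def build_db(
    transactions: Sequence[Iterable[Item]],
    labels: Optional[Sequence[int]] = None,
) -> TransactionDB:
    """Build a :class:`TransactionDB`, rejecting malformed input.

    Raises ``ValueError`` for an empty transaction list or for a transaction
    holding two values of the same attribute (the diagnostic names the
    transaction and the attribute).
    """
    return TransactionDB(transactions, labels=labels)
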