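"""Gene-expression preprocessing: range filter, z-normalisation, ternary items.

The expression input is an RMA-summarised probeset x subject matrix. Three
ordered steps turn it into gene items that live in the same universe as the
clinical codes:

1. range filter — drop probes whose profile varies by less than a threshold
   (default 0.1) between its maximum and minimum; near-flat profiles carry no
   usable signal,
2. z-normalisation — each remaining profile is centred and scaled to unit
   *sample* standard deviation (n-1 denominator),
3. ternary discretisation — a normalised value strictly above +1 becomes an
   over-expressed item (probe, +1), strictly below -1 an under-expressed item
   (probe, -1); anything in between yields no item.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .transactions import Item


@dataclass
class ExpressionMatrix:
    """Probes x subjects real-valued matrix with a subject -> group mapping.

    ``values`` is a DataFrame indexed by probe id with one column per subject.
    """

    values: pd.DataFrame
    groups: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated probe ids: {list(dupes[:5])}")
        if self.values.isna().any().any():
            r, c = np.argwhere(self.values.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at probe {self.values.index[r]!r}, "
                f"subject {self.values.columns[c]!r}"
            )

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def group_of(self, subject: str) -> int:
        if self.groups is None:
            raise ValueError("expression matrix carries no subject->group mapping")
        return self.groups[subject]


def range_filter(matrix: ExpressionMatrix, threshold: float = 0.1) -> ExpressionMatrix:
    """Keep probe g iff max(g) - min(g) >= threshold.

    The removal condition is strict ("variation less than the threshold"), so
    a profile with range exactly equal to the threshold survives.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    vals = matrix.values.to_numpy()
    rng = vals.max(axis=1) - vals.min(axis=1)
    keep = rng >= threshold
    return ExpressionMatrix(matrix.values.loc[keep], matrix.groups)


def znormalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Row-wise zero-mean, unit sample-sd (ddof=1) normalisation.

    A zero-variance profile cannot be scaled; the error directs the caller to
    run the range filter first.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("normalisation needs at least 2 subjects")
    sd = vals.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = matrix.values.index[np.flatnonzero(sd == 0)[0]]
        raise ValueError(
            f"zero-variance profile {bad!r}; apply range_filter before znormalize"
        )
    normed = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(normed, index=matrix.values.index, columns=matrix.values.columns),
        matrix.groups,
    )


def ternary_discretize(
    matrix: ExpressionMatrix, hi: float = 1.0, lo: float = -1.0
) -> list[set[Item]]:
    """Per-subject gene items: (probe, +1) where the normalised value is
    strictly above ``hi``, (probe, -1) strictly below ``lo``, nothing
    otherwise. Returns one item set per subject, in column order."""
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    vals = matrix.values.to_numpy()
    probes = matrix.probes
    out: list[set[Item]] = []
    for c in range(vals.shape[1]):
        col = vals[:, c]
        items = {Item(probes[r], 1) for r in np.flatnonzero(col > hi)}
        items |= {Item(probes[r], -1) for r in np.flatnonzero(col < lo)}
        out.append(items)
    return out
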