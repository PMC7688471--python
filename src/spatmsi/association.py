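"""Cluster–zone association: contingency tables and Cramér's V.

Links the unsupervised segmentation of the tissue to the discrete drug
distribution map: pixels are cross-tabulated by their LISA zone (HH/LL/HL/LH)
against their cluster label, and the strength of the association is measured
with Cramér's V, a chi-square-based coefficient in [0, 1] for two nominal
variables.

Because only a small fraction of pixels falls in the transitional HL/LH
quadrants, V is by default computed on the HH/LL rows only: the association
between the spatially smooth high-drug and low-drug regions and the tissue
subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial import ZONES

__all__ = [
    "ContingencyTable",
    "zone_cluster_table",
    "cramers_v",
    "PACLITAXEL_XENOGRAFT_ZONE_TABLES",
]

#: Published zone x cluster pixel percentages (HH, LL, HL, LH rows; clusters
#: 1-5 columns) for six ovarian (A2780) xenograft tumour images from a
#: paclitaxel distribution MSI study.  Used as worked-example input and by
#: the reproduction script; percentages as printed (rounded to 2 decimals).
PACLITAXEL_XENOGRAFT_ZONE_TABLES: dict[int, pd.DataFrame] = {
    img: pd.DataFrame(
        rows,
        index=pd.Index(ZONES, name="zone"),
        columns=pd.Index([1, 2, 3, 4, 5], name="cluster"),
    )
    for img, rows in {
        1: [
            [8.28, 23.50, 0.58, 5.75, 3.50],
            [4.48, 4.92, 7.90, 5.26, 3.46],
            [3.36, 7.85, 0.87, 2.68, 1.22],
            [2.87, 5.46, 2.44, 2.58, 2.88],
        ],
        2: [
            [18.15, 13.34, 0.31, 2.98, 1.94],
            [0.86, 9.39, 0.80, 7.49, 15.93],
            [2.83, 8.50, 0.09, 1.60, 3.76],
            [2.89, 3.57, 0.43, 2.10, 3.01],
        ],
        3: [
            [14.69, 13.55, 0.05, 5.77, 2.19],
            [4.20, 11.57, 0.66, 9.22, 14.78],
            [4.02, 7.19, 0.036, 1.56, 1.69],
            [1.38, 2.65, 0.29, 1.79, 2.69],
        ],
        4: [
            [21.55, 17.09, 0.09, 1.95, 3.89],
            [3.67, 1.91, 2.29, 6.20, 18.62],
            [3.12, 2.20, 0.21, 1.93, 3.16],
            [3.30, 3.44, 0.67, 1.40, 3.29],
        ],
        5: [
            [16.41, 20.53, 2.49, 4.20, 2.95],
            [2.20, 3.10, 11.89, 2.33, 2.15],
            [3.51, 4.43, 2.89, 1.43, 1.79],
            [3.36, 5.99, 3.13, 2.74, 2.44],
        ],
        6: [
            [15.04, 23.57, 1.53, 0.99, 3.23],
            [4.04, 4.12, 13.44, 2.05, 4.37],
            [3.71, 6.59, 2.12, 1.19, 2.23],
            [2.85, 3.64, 2.83, 0.98, 1.44],
        ],
    }.items()
}


@dataclass
class ContingencyTable:
    """Zone x cluster cross-tabulation with its association statistics."""

    table: pd.DataFrame
    normalize: str
    chi2: float | None = None
    v: float | None = None


def zone_cluster_table(
    zones: np.ndarray, labels: np.ndarray, normalize: str = "counts"
) -> ContingencyTable:
    """Cross-tabulate LISA zones against cluster labels over mask pixels.

    Rows are the four zones in canonical HH, LL, HL, LH order (absent zones
    appear as zero rows); columns are the sorted cluster labels.  With
    ``normalize="fractions"`` cells sum to one over the whole table.
    """
    zones = np.asarray(zones)
    labels = np.asarray(labels)
    if zones.shape[0] != labels.shape[0]:
        raise ValueError(
            f"zone map has {zones.shape[0]} pixels but cluster image has "
            f"{labels.shape[0]}; the maps must share one mask"
        )
    if normalize not in ("counts", "fractions"):
        raise ValueError(f"unknown normalize {normalize!r}")
    tab = pd.crosstab(pd.Series(zones, name="zone"), pd.Series(labels, name="cluster"))
    tab = tab.reindex(index=list(ZONES), fill_value=0)
    tab.index.name = "zone"
    if normalize == "fractions":
        tab = tab / tab.values.sum()
    return ContingencyTable(table=tab, normalize=normalize)


def cramers_v(
    table: ContingencyTable | pd.DataFrame | np.ndarray,
    rows_subset: tuple[str, ...] | None = ("HH", "LL"),
) -> float:
    """Cramér's V of a (subset of a) zone x cluster table.

    chi2 is the Pearson statistic against independence expectations formed
    from the subset table's own margins, and V = sqrt(chi2 / (T * min(r-1,
    c-1))) with T the subset total.  V is invariant to rescaling all cells,
    so counts and fractions (or percentages) give the same value.  Zero
    margin rows/columns are dropped with a warning before computing.

    Parameters
    ----------
    table : ContingencyTable, DataFrame or array
    rows_subset : tuple of zone labels or None
        Rows to keep (default the spatially smooth HH/LL zones); None keeps
        all rows.  Ignored for plain arrays without a zone index.
    """
    if isinstance(table, ContingencyTable):
        df = table.table
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        # plain array: rows are taken as already subset by the caller
        df = pd.DataFrame(np.asarray(table, dtype=float))
        rows_subset = None

    if rows_subset is not None:
        present = [r for r in rows_subset if r in df.index]
        if len(present) < len(rows_subset):
            missing = set(rows_subset) - set(present)
            warnings.warn(f"requested zones absent from table: {sorted(missing)}")
        df = df.loc[present]

    obs = df.to_numpy(dtype=float)
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns before chi-square")
        obs = obs[np.ix_(row_ok, col_ok)]
    r, c = obs.shape
    if r < 2 or c < 2:
        raise ValueError(f"need at least a 2x2 table after dropping zero margins, got {r}x{c}")
    total = obs.sum()
    if total <= 0:
        raise ValueError("contingency table total must be positive")

    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    v = float(np.sqrt(chi2 / (total * min(r - 1, c - 1))))
    return v
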