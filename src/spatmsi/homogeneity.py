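"""Size-zone homogeneity of cluster label images.

A "size zone" is a connected component of pixels carrying the same cluster
label.  The homogeneity ratio of a cluster is the fraction of the tissue
occupied by that cluster's zones of at least ``nu`` pixels: small scattered
speckles do not count, so a higher ratio means the cluster forms large,
spatially continuous regions.  This is the cluster-image variant of a drug
homogeneity index originally defined on continuous intensity maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["size_zones", "homogeneity_ratio", "homogeneity_report"]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def _label_grid(label_grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(label_grid)
    if grid.ndim != 2:
        raise ValueError("cluster label image must be a 2D grid")
    return grid


def size_zones(label_grid: np.ndarray, cluster: int, connectivity: int = 8) -> np.ndarray:
    """Sizes (pixels) of the connected components of one cluster, descending.

    ``label_grid`` is a 2D integer grid of cluster labels with anything
    outside the tissue marked NaN (float grid) or a non-cluster sentinel.
    An absent cluster yields an empty array.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    grid = _label_grid(label_grid)
    member = np.zeros(grid.shape, dtype=bool)
    valid = ~pd.isna(grid)
    member[valid] = np.asarray(grid[valid] == cluster)
    labeled, nzones = ndimage.label(member, structure=_STRUCTURES[connectivity])
    if nzones == 0:
        return np.array([], dtype=int)
    sizes = np.bincount(labeled.ravel())[1:]
    return np.sort(sizes)[::-1]


def homogeneity_ratio(
    label_grid: np.ndarray,
    cluster: int,
    nu: int = 5,
    connectivity: int = 8,
    tissue_total: int | None = None,
) -> float:
    """Qualifying size-zone fraction of the tissue for one cluster.

    ratio = (sum of zone sizes >= nu) / tissue_total.  ``tissue_total``
    defaults to the number of labelled (non-NaN) pixels in the grid; pass it
    explicitly when the grid is a per-model crop of a larger section.
    """
    if nu < 1:
        raise ValueError(f"nu (minimum qualifying zone size) must be >= 1, got {nu}")
    grid = _label_grid(label_grid)
    if tissue_total is None:
        tissue_total = int((~pd.isna(grid)).sum())
    if tissue_total <= 0:
        raise ValueError("tissue_total must be positive")
    zones = size_zones(grid, cluster, connectivity=connectivity)
    return float(zones[zones >= nu].sum()) / tissue_total


def homogeneity_report(
    label_grid: np.ndarray,
    clusters: list[int] | None = None,
    nu: int = 5,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Per-cluster zone statistics for one section as a tidy table."""
    grid = _label_grid(label_grid)
    valid = ~pd.isna(grid)
    total = int(valid.sum())
    if clusters is None:
        clusters = sorted(int(c) for c in np.unique(np.asarray(grid[valid], dtype=int)))
    rows = []
    for c in clusters:
        zones = size_zones(grid, c, connectivity=connectivity)
        rows.append(
            {
                "cluster": c,
                "nu": nu,
                "n_zones": len(zones),
                "largest_zone": int(zones[0]) if len(zones) else 0,
                "cluster_pixels": int(zones.sum()),
                "homogeneity_ratio": homogeneity_ratio(
                    grid, c, nu=nu, connectivity=connectivity, tissue_total=total
                ),
            }
        )
    return pd.DataFrame(rows)
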