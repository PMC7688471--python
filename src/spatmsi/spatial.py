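"""Distance-band spatial weights and raster spatial statistics.

Everything here operates on pixel rasters: a set of (row, col) integer
coordinates in pixel units and one value per pixel.  The spatial weight
matrix W is the shared ingredient of every spatial method in the package —
global Moran's I, spatial correlograms, LISA (Moran-scatter) maps and the
spatial lag/error regressions in :mod:`spatmsi.regression`.

Weights are binary within a Euclidean distance threshold (two pixels are
neighbours when ``0 < d(i, j) <= threshold``), optionally row-standardised
so every non-isolate row sums to one.  The binary relation is symmetric by
construction; row standardisation breaks symmetry but keeps the spectrum
real because W is then similar to a symmetric matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "SpatialWeights",
    "build_weights",
    "spatial_lag",
    "moran_i",
    "MoranResult",
    "spatial_correlogram",
    "CorrelogramResult",
    "lisa_map",
    "LISAMap",
    "ZONES",
]

#: LISA quadrant labels in canonical order.
ZONES = ("HH", "LL", "HL", "LH")


@dataclass
class SpatialWeights:
    """Neighbour structure over pixel coordinates.

    Attributes
    ----------
    matrix : scipy.sparse.csr_matrix
        The weight matrix W (binary 0/1 or row-standardised).
    coords : ndarray, shape (n, 2)
        Pixel (row, col) coordinates the weights were built from.
    threshold : float
        Distance band in pixel units.
    style : {"binary", "row_standardized"}
    """

    matrix: sparse.csr_matrix
    coords: np.ndarray
    threshold: float
    style: str
    _eigvals: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights, the S0 normaliser of Moran's I."""
        return float(self.matrix.sum())

    @property
    def cardinalities(self) -> np.ndarray:
        """Number of neighbours per pixel (of the binary relation)."""
        return np.asarray((self.matrix != 0).sum(axis=1)).ravel()

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatially lagged values Wz; isolates get lag 0."""
        z = np.asarray(z, dtype=float)
        if z.shape[0] != self.n:
            raise ValueError(
                f"value vector has length {z.shape[0]}, weights have {self.n} pixels"
            )
        return self.matrix @ z

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the row-standardised weight matrix (cached).

        W_rs = D^-1 A with A the symmetric binary adjacency and D the degree
        matrix, so W_rs is similar to the symmetric D^-1/2 A D^-1/2 and has a
        real spectrum; isolates contribute zero eigenvalues.  Used for the
        feasible parameter interval and the log-determinant term of the
        spatial regression likelihoods.
        """
        if self._eigvals is None:
            adj = (self.matrix != 0).astype(float).tocsr()
            deg = np.asarray(adj.sum(axis=1)).ravel()
            with np.errstate(divide="ignore"):
                inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
            d = sparse.diags(inv_sqrt)
            sym = (d @ adj @ d).toarray()
            sym = (sym + sym.T) / 2.0  # enforce exact symmetry for eigvalsh
            self._eigvals = np.linalg.eigvalsh(sym)
        return self._eigvals

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()


def build_weights(
    coords: np.ndarray, threshold: float = 5.0, style: str = "row_standardized"
) -> SpatialWeights:
    """Build distance-band weights over pixel coordinates.

    Neighbours are pixels at Euclidean distance in ``(0, threshold]``.

    Parameters
    ----------
    coords : array-like, shape (n, 2)
        (row, col) pixel coordinates.
    threshold : float
        Lag distance in pixel units; must be >= 1.
    style : {"binary", "row_standardized"}
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1 (pixel units), got {threshold}")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 pixels to build spatial weights")
    if style not in ("binary", "row_standardized"):
        raise ValueError(f"unknown style {style!r}")

    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if pairs.size:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        w = sparse.csr_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    else:
        w = sparse.csr_matrix((n, n))

    if style == "row_standardized":
        rowsum = np.asarray(w.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            inv = np.where(rowsum > 0, 1.0 / np.maximum(rowsum, 1e-300), 0.0)
        w = sparse.diags(inv) @ w
        w = w.tocsr()

    return SpatialWeights(matrix=w, coords=coords, threshold=float(threshold), style=style)


def autoscale(x: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with the population (ddof=0) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot autoscale a constant variable (zero variance)")
    return (x - x.mean()) / sd


def spatial_lag(w: SpatialWeights, z: np.ndarray) -> np.ndarray:
    """Spatially lagged variable Wz (weighted neighbour aggregate)."""
    return w.lag(z)


@dataclass
class MoranResult:
    """Global Moran's I with its building blocks."""

    i: float
    z: np.ndarray
    lag: np.ndarray
    n: int
    s0: float


def moran_i(x: np.ndarray, w: SpatialWeights) -> MoranResult:
    """Global spatial autocorrelation index.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z = x - mean(x).
    Under spatial randomness E[I] = -1/(n-1); positive values indicate that
    similar intensities cluster in space.
    """
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise ValueError("Moran's I undefined for a constant variable")
    z = autoscale(x)
    lag = w.lag(z)
    num = float(z @ lag)
    den = float(z @ z)
    i = (w.n / w.s0) * num / den
    return MoranResult(i=i, z=z, lag=lag, n=w.n, s0=w.s0)


@dataclass
class CorrelogramResult:
    """Moran's I as a function of lag distance (annulus neighbourhoods)."""

    lags: np.ndarray
    i: np.ndarray
    n_pairs: np.ndarray


def spatial_correlogram(
    x: np.ndarray, coords: np.ndarray, max_lag: int = 15
) -> CorrelogramResult:
    """Moran's I per distance annulus d-1 < dist <= d for d = 1..max_lag.

    Each lag uses its own row-standardised annulus weight matrix.  Lags whose
    annulus is empty for every pixel yield NaN with a warning.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    coords = np.asarray(coords, dtype=float)
    x = np.asarray(x, dtype=float)
    n = coords.shape[0]
    tree = cKDTree(coords)

    lags = np.arange(1, max_lag + 1)
    ivals = np.full(max_lag, np.nan)
    npairs = np.zeros(max_lag, dtype=int)

    prev = tree.query_pairs(r=0.0, output_type="ndarray")
    prev_set = {tuple(p) for p in prev}
    for k, d in enumerate(lags):
        cur = tree.query_pairs(r=float(d), output_type="ndarray")
        cur_set = {tuple(p) for p in cur}
        ring = cur_set - prev_set
        prev_set = cur_set
        npairs[k] = 2 * len(ring)
        if not ring:
            warnings.warn(f"empty annulus at lag distance {d}; Moran I set to NaN")
            continue
        arr = np.array(sorted(ring))
        i_idx = np.concatenate([arr[:, 0], arr[:, 1]])
        j_idx = np.concatenate([arr[:, 1], arr[:, 0]])
        w = sparse.csr_matrix((np.ones(i_idx.size), (i_idx, j_idx)), shape=(n, n))
        rowsum = np.asarray(w.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            inv = np.where(rowsum > 0, 1.0 / np.maximum(rowsum, 1e-300), 0.0)
        w = (sparse.diags(inv) @ w).tocsr()
        sw = SpatialWeights(matrix=w, coords=coords, threshold=float(d), style="row_standardized")
        ivals[k] = moran_i(x, sw).i

    return CorrelogramResult(lags=lags, i=ivals, n_pairs=npairs)


@dataclass
class LISAMap:
    """Per-pixel Moran-scatter quadrant labels.

    ``zones`` holds one of "HH", "LL", "HL", "LH" per pixel: the sign of the
    autoscaled value paired with the sign of its spatial lag.  HH/LL pixels
    sit in spatially smooth high/low regions of the source image.
    """

    zones: np.ndarray
    z: np.ndarray
    lag: np.ndarray
    coords: np.ndarray
    threshold: float

    def counts(self) -> dict[str, int]:
        return {zone: int(np.sum(self.zones == zone)) for zone in ZONES}

    def to_grid(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Render zones on a 2D grid; cells off the mask get ''."""
        rc = self.coords.astype(int)
        if shape is None:
            shape = (rc[:, 0].max() + 1, rc[:, 1].max() + 1)
        grid = np.full(shape, "", dtype="<U2")
        grid[rc[:, 0], rc[:, 1]] = self.zones
        return grid


def lisa_map(x: np.ndarray, w: SpatialWeights) -> LISAMap:
    """Classify pixels into Moran-scatter quadrants.

    z is the autoscaled variable and lag = Wz its spatial lag.  Quadrants:
    HH if z > 0 and lag > 0; LL if z <= 0 and lag <= 0; HL if z > 0 and
    lag <= 0; LH if z <= 0 and lag > 0.  Values exactly at the mean go to
    the low side (deterministic tie-break; ties have measure zero on real
    intensities).
    """
    x = np.asarray(x, dtype=float)
    z = autoscale(x)
    lag = w.lag(z)
    zones = np.empty(z.shape[0], dtype="<U2")
    hi = z > 0
    lag_hi = lag > 0
    zones[hi & lag_hi] = "HH"
    zones[~hi & ~lag_hi] = "LL"
    zones[hi & ~lag_hi] = "HL"
    zones[~hi & lag_hi] = "LH"
    return LISAMap(zones=zones, z=z, lag=lag, coords=w.coords, threshold=w.threshold)
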