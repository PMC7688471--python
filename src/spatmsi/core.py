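"""Domain types and I/O for MSI pixel rasters.

An :class:`MSIDataset` couples a 2D pixel grid with one mass spectrum per
pixel plus per-pixel block labels (tumour model, section/slice, treatment
arm).  Spectra are profile-mode (m/z, intensity) arrays; coordinates are
0-based (row, col) integers, row-major, and all distances downstream are
Euclidean in pixel units.

Readers cover imzML (via pyimzml), the Analyze 7.5 hdr/img/t2m triplet used
by older MALDI imaging software (via nibabel plus a raw m/z-axis read), and
an already-binned tabular CSV format with header columns
``x,y,model_id,slice_id,treatment`` followed by one column per m/z bin
centre.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MSIDataset",
    "IonImage",
    "BinScheme",
    "FeatureTable",
    "load_msi",
    "save_imzml",
    "build_tissue_mask",
    "extract_ion_image",
]

PIXEL_COLUMNS = ["x", "y", "model_id", "slice_id", "treatment"]


@dataclass
class BinScheme:
    """Adaptive m/z bins derived from reference-spectrum peaks.

    Each bin is (lower, upper, center, origin) with origin one of ``peak``
    (a single detected peak), ``merged`` (a chain of peaks closer than the
    merge tolerance collapsed into one bin) or ``gap`` (filler bin tiling a
    wide inter-peak gap).  Bins are non-overlapping and ordered by centre.
    """

    bins: pd.DataFrame  # columns: lower, upper, center, origin
    merge_tol: float
    gap_bin_width: float

    def __post_init__(self):
        b = self.bins
        if not (b["lower"] < b["upper"]).all():
            raise ValueError("every bin must satisfy lower < upper")
        if not b["center"].is_monotonic_increasing:
            raise ValueError("bins must be ordered by center")
        if (b["lower"].to_numpy()[1:] < b["upper"].to_numpy()[:-1] - 1e-12).any():
            raise ValueError("bins must not overlap")

    @property
    def centers(self) -> np.ndarray:
        return self.bins["center"].to_numpy()

    def __len__(self) -> int:
        return len(self.bins)

    def assign(self, mz: np.ndarray) -> np.ndarray:
        """Bin index for each m/z value, -1 where no bin covers it.

        Bin intervals are treated as [lower, upper].
        """
        mz = np.atleast_1d(np.asarray(mz, dtype=float))
        lower = self.bins["lower"].to_numpy()
        upper = self.bins["upper"].to_numpy()
        idx = np.searchsorted(lower, mz, side="right") - 1
        idx_clipped = np.clip(idx, 0, len(lower) - 1)
        ok = (idx >= 0) & (mz <= upper[idx_clipped])
        return np.where(ok, idx_clipped, -1)


@dataclass
class MSIDataset:
    """Pixel grid plus per-pixel profile spectra and block labels."""

    coords: np.ndarray  # (n, 2) int, (row, col)
    spectra: list[tuple[np.ndarray, np.ndarray]]  # (mz, intensity) per pixel
    model_id: np.ndarray
    slice_id: np.ndarray
    treatment: np.ndarray
    mask: np.ndarray | None = None  # 2D bool grid
    pixel_size: float | None = None  # micrometres, metadata only
    feature_table: "FeatureTable | None" = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=int)
        uniq = {tuple(rc) for rc in self.coords}
        if len(uniq) != len(self.coords):
            seen: set[tuple[int, int]] = set()
            for rc in self.coords:
                key = (int(rc[0]), int(rc[1]))
                if key in seen:
                    raise ValueError(f"duplicate pixel coordinate {key}")
                seen.add(key)
        for k, (mz, _) in enumerate(self.spectra):
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError(f"spectrum at pixel index {k}: m/z not strictly increasing")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (int(self.coords[:, 0].max()) + 1, int(self.coords[:, 1].max()) + 1)

    def pixel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.coords[:, 1],
                "y": self.coords[:, 0],
                "model_id": self.model_id,
                "slice_id": self.slice_id,
                "treatment": self.treatment,
            }
        )


@dataclass
class IonImage:
    """One bin's intensity rendered on the pixel grid (NaN off the mask)."""

    grid: np.ndarray
    bin_id: int
    center: float | None = None

    def values(self, coords: np.ndarray) -> np.ndarray:
        rc = np.asarray(coords, dtype=int)
        return self.grid[rc[:, 0], rc[:, 1]]


@dataclass
class FeatureTable:
    """Pixels x bins intensity matrix with its pixel index.

    The drug bin, once identified, is held apart in ``drug_values`` /
    ``drug_center`` and is never part of the clustering feature columns.
    """

    matrix: np.ndarray  # (n_pixels, n_bins)
    centers: np.ndarray  # (n_bins,) bin centres in Daltons
    pixels: pd.DataFrame  # columns PIXEL_COLUMNS
    bins: BinScheme | None = None
    drug_values: np.ndarray | None = None
    drug_center: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.matrix.shape != (len(self.pixels), len(self.centers)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.pixels)} pixels x {len(self.centers)} bins"
            )
        if self.matrix.shape[1] and np.isnan(self.matrix).all(axis=0).any():
            raise ValueError("feature table contains an all-NaN column")

    @property
    def coords(self) -> np.ndarray:
        """(row, col) pixel coordinates."""
        return self.pixels[["y", "x"]].to_numpy(dtype=int)

    @property
    def grid_shape(self) -> tuple[int, int]:
        rc = self.coords
        return (int(rc[:, 0].max()) + 1, int(rc[:, 1].max()) + 1)

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def column(self, bin_id) -> np.ndarray:
        return self.matrix[:, self._col_index(bin_id)]

    def _col_index(self, bin_id) -> int:
        if isinstance(bin_id, (int, np.integer)):
            if not 0 <= bin_id < self.n_bins:
                raise KeyError(f"bin index {bin_id} out of range [0, {self.n_bins})")
            return int(bin_id)
        hits = np.flatnonzero(np.isclose(self.centers, float(bin_id)))
        if hits.size == 0:
            raise KeyError(f"no bin with centre m/z {bin_id}")
        return int(hits[0])

    def replace_matrix(self, matrix: np.ndarray, centers: np.ndarray | None = None,
                       pixels: pd.DataFrame | None = None) -> "FeatureTable":
        return FeatureTable(
            matrix=matrix,
            centers=self.centers if centers is None else centers,
            pixels=self.pixels if pixels is None else pixels,
            bins=self.bins,
            drug_values=self.drug_values,
            drug_center=self.drug_center,
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        df = self.pixels.copy()
        for k, c in enumerate(self.centers):
            df[f"{c:.6g}"] = self.matrix[:, k]
        if self.drug_values is not None:
            df[f"drug_{self.drug_center:.6g}"] = self.drug_values
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureTable":
        df = pd.read_csv(path)
        missing = [c for c in PIXEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table CSV missing mandatory columns {missing}")
        value_cols = [c for c in df.columns if c not in PIXEL_COLUMNS]
        drug_cols = [c for c in value_cols if c.startswith("drug_")]
        feat_cols = [c for c in value_cols if not c.startswith("drug_")]
        centers = np.array([float(c) for c in feat_cols])
        ft = cls(
            matrix=df[feat_cols].to_numpy(dtype=float),
            centers=centers,
            pixels=df[PIXEL_COLUMNS].copy(),
        )
        if drug_cols:
            ft.drug_values = df[drug_cols[0]].to_numpy(dtype=float)
            ft.drug_center = float(drug_cols[0].removeprefix("drug_"))
        return ft


# ---------------------------------------------------------------------------
# readers / writers


def load_msi(path: str | os.PathLike, format: str | None = None, **labels) -> MSIDataset:
    """Load an MSI dataset from imzML, Analyze 7.5 or a binned CSV table.

    ``format`` is inferred from the file extension when omitted.  Extra
    keyword arguments (``model_id``, ``slice_id``, ``treatment``) set block
    labels for formats that do not carry them (one value per dataset).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".imzml": "imzml", ".hdr": "analyze75", ".img": "analyze75",
                  ".csv": "table"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer MSI format from extension {ext!r}")
    if format == "imzml":
        return _load_imzml(path, **labels)
    if format == "analyze75":
        return _load_analyze75(path, **labels)
    if format == "table":
        ft = FeatureTable.from_csv(path)
        spectra = [
            (ft.centers.copy(), ft.matrix[k].copy()) for k in range(ft.n_pixels)
        ]
        ds = MSIDataset(
            coords=ft.coords,
            spectra=spectra,
            model_id=ft.pixels["model_id"].to_numpy(),
            slice_id=ft.pixels["slice_id"].to_numpy(),
            treatment=ft.pixels["treatment"].to_numpy(),
        )
        ds.feature_table = ft
        return ds
    raise ValueError(f"unknown MSI format {format!r}")


def _labels_for(n: int, labels: dict) -> dict:
    out = {}
    for key, default in (("model_id", "M1"), ("slice_id", "S1"), ("treatment", "untreated")):
        out[key] = np.full(n, labels.get(key, default), dtype=object)
    return out


def _load_imzml(path: str, **labels) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # malformed XML / ibd mismatch
        raise ValueError(f"unreadable imzML file {path!r}: {exc}") from exc
    coords = []
    spectra = []
    for idx, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(idx)
        coords.append((int(y) - 1, int(x) - 1))  # imzML coordinates are 1-based
        spectra.append((np.asarray(mz, dtype=float), np.asarray(inten, dtype=float)))
    lab = _labels_for(len(coords), labels)
    return MSIDataset(coords=np.array(coords), spectra=spectra, **lab)


def save_imzml(ds: MSIDataset, path: str | os.PathLike) -> None:
    """Write a dataset as continuous-or-processed imzML (round-trip partner)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(os.fspath(path), mz_dtype=np.float64,
                     intensity_dtype=np.float64) as writer:
        for (r, c), (mz, inten) in zip(ds.coords, ds.spectra):
            writer.addSpectrum(mz, inten, (int(c) + 1, int(r) + 1, 1))


def _load_analyze75(path: str, **labels) -> MSIDataset:
    """Read the hdr/img/t2m triplet of Analyze 7.5 MSI exports.

    The .img volume holds one spectrum per pixel along its first axis and
    the .t2m sidecar the shared m/z axis as little-endian float32.
    """
    import nibabel as nib

    base = os.path.splitext(path)[0]
    t2m = base + ".t2m"
    if not os.path.exists(t2m):
        raise ValueError(f"Analyze 7.5 MSI data requires the m/z sidecar {t2m!r}")
    mz = np.fromfile(t2m, dtype="<f4").astype(float)
    if mz.size == 0 or not np.all(np.diff(mz) > 0):
        raise ValueError(f"m/z axis in {t2m!r} is empty or not strictly increasing")
    try:
        img = nib.load(base + ".hdr")
    except Exception as exc:
        raise ValueError(f"unreadable Analyze 7.5 volume {base!r}: {exc}") from exc
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3 or data.shape[0] != mz.size:
        raise ValueError(
            f"Analyze volume shape {data.shape} does not match m/z axis length {mz.size}"
        )
    _, nx, ny = data.shape
    coords = []
    spectra = []
    for ix in range(nx):
        for iy in range(ny):
            coords.append((iy, ix))
            spectra.append((mz.copy(), data[:, ix, iy].astype(float)))
    lab = _labels_for(len(coords), labels)
    return MSIDataset(coords=np.array(coords), spectra=spectra, **lab)


# ---------------------------------------------------------------------------
# masking and ion images


def build_tissue_mask(
    ds: MSIDataset,
    mz_window: tuple[float, float] = (281.1, 281.44),
    method: str = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Threshold a tissue-marker ion window into a boolean tissue mask.

    Sums intensity inside ``mz_window`` per pixel, thresholds (Otsu by
    default, or a manual cut-off), then applies a 3x3 morphological closing
    to fill single-pixel holes.  The default window targets a lipid ion
    that reliably marks tissue against the glass slide.
    """
    lo, hi = mz_window
    mins = min(s[0][0] for s in ds.spectra if len(s[0]))
    maxs = max(s[0][-1] for s in ds.spectra if len(s[0]))
    if hi < mins or lo > maxs:
        raise ValueError(
            f"marker window {mz_window} outside acquired m/z range [{mins}, {maxs}]"
        )
    marker = np.zeros(ds.n_pixels)
    for k, (mz, inten) in enumerate(ds.spectra):
        sel = (mz >= lo) & (mz <= hi)
        marker[k] = inten[sel].sum()
    if marker.max() == marker.min():
        raise ValueError("tissue marker signal is constant; no separable threshold")

    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(marker)
    elif method == "manual":
        if threshold is None:
            raise ValueError("manual masking requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown masking method {method!r}")

    grid = np.zeros(ds.grid_shape, dtype=bool)
    grid[ds.coords[:, 0], ds.coords[:, 1]] = marker > thr
    if not grid.any():
        raise ValueError("tissue mask is empty at the chosen threshold")
    # closing fills single-pixel holes; the union keeps it extensive at the
    # grid border, where scipy's zero padding would otherwise erode tissue
    grid = grid | ndimage.binary_closing(grid, structure=np.ones((3, 3), dtype=bool))
    # closing cannot grow outside the acquired pixel set
    acquired = np.zeros(ds.grid_shape, dtype=bool)
    acquired[ds.coords[:, 0], ds.coords[:, 1]] = True
    return grid & acquired


def extract_ion_image(ft: FeatureTable, bin_id) -> IonImage:
    """Render one feature column (or the drug column) on the pixel grid."""
    if isinstance(bin_id, str) and bin_id == "drug":
        if ft.drug_values is None:
            raise KeyError("feature table carries no drug column")
        values = ft.drug_values
        col, center = -1, ft.drug_center
    else:
        col = ft._col_index(bin_id)
        values = ft.matrix[:, col]
        center = float(ft.centers[col])
    grid = np.full(ft.grid_shape, np.nan)
    rc = ft.coords
    grid[rc[:, 0], rc[:, 1]] = values
    return IonImage(grid=grid, bin_id=col, center=center)
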