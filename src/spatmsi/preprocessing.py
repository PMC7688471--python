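"""Spectral pre-processing: reference spectrum, peak picking, adaptive
binning, and the per-ion / per-pixel cleaning chain.

The pipeline mirrors standard MALDI-MSI practice on profile-mode spectra:

1. a maximum-intensity reference spectrum over all tissue pixels captures
   the location and shape of every ion peak in the dataset;
2. the reference is wavelet-denoised (least-asymmetric Daubechies, 8-tap,
   hard shrinkage at the universal threshold) and peaks are strict local
   maxima above ``snr`` times a MAD-based noise scale;
3. adaptive m/z bins are built around the reference peaks — peaks closer
   than the instrument tolerance are merged, wide gaps are tiled with
   fixed-width filler bins so weak ions in sparse regions are not lost;
4. per-pixel peak picking assigns each pixel's peaks to the bins, giving
   the pixels x bins feature matrix;
5. per-ion cleaning: low-coverage and single-model bins dropped, 3x3
   mask-aware median filtering with tissue-edge correction, median
   normalisation, generalised-log variance stabilisation, least-squares
   batch-effect removal, and removal of features correlated with the drug
   ion before clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage

from .core import BinScheme, FeatureTable, MSIDataset

__all__ = [
    "ReferenceSpectrum",
    "PeakList",
    "build_reference_spectrum",
    "denoise_spectrum",
    "pick_peaks",
    "build_adaptive_bins",
    "binned_feature_table",
    "filter_low_coverage",
    "spatial_clean",
    "normalize_glog",
    "glog",
    "remove_batch_effect",
    "drop_drug_correlated",
]

_WAVELET = "sym4"  # Daubechies least-asymmetric, filter length 8


@dataclass
class ReferenceSpectrum:
    """Pointwise-maximum spectrum over all pixels on a common m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class PeakList:
    """Detected peaks (m/z, apex intensity) with the threshold used."""

    mz: np.ndarray
    intensity: np.ndarray
    snr: float
    noise_scale: float

    def __len__(self) -> int:
        return len(self.mz)


def build_reference_spectrum(ds: MSIDataset) -> ReferenceSpectrum:
    """Pointwise maximum over all spectra, interpolating to a common axis.

    If spectra share an identical axis the maximum is taken directly;
    otherwise each spectrum is linearly interpolated onto the axis of the
    longest spectrum (zero outside its own range).
    """
    if ds.n_pixels == 0:
        raise ValueError("cannot build a reference spectrum from an empty dataset")
    axes = [s[0] for s in ds.spectra]
    ref_axis = max(axes, key=len)
    same = all(len(a) == len(ref_axis) and np.array_equal(a, ref_axis) for a in axes)
    if same:
        stack = np.stack([s[1] for s in ds.spectra])
        return ReferenceSpectrum(mz=ref_axis.copy(), intensity=stack.max(axis=0))
    best = np.full(len(ref_axis), -np.inf)
    for mz, inten in ds.spectra:
        best = np.maximum(best, np.interp(ref_axis, mz, inten, left=0.0, right=0.0))
    return ReferenceSpectrum(mz=ref_axis.copy(), intensity=best)


def _noise_scale(intensity: np.ndarray) -> float:
    """Robust noise sigma from the finest-detail wavelet coefficients."""
    detail = pywt.dwt(intensity, _WAVELET)[1]
    mad = np.median(np.abs(detail - np.median(detail)))
    return float(mad / 0.6745)


def denoise_spectrum(intensity: np.ndarray) -> tuple[np.ndarray, float]:
    """Hard wavelet shrinkage at the universal threshold.

    Returns the denoised signal (same length) and the noise scale sigma.
    """
    intensity = np.asarray(intensity, dtype=float)
    n = len(intensity)
    sigma = _noise_scale(intensity)
    coeffs = pywt.wavedec(intensity, _WAVELET)
    if sigma > 0:
        thr = sigma * np.sqrt(2.0 * np.log(n))
        coeffs = [coeffs[0]] + [np.where(np.abs(c) > thr, c, 0.0) for c in coeffs[1:]]
    smooth = pywt.waverec(coeffs, _WAVELET)[:n]
    return smooth, sigma


def pick_peaks(spectrum: ReferenceSpectrum, snr: float = 3.0) -> PeakList:
    """Strict local maxima of the denoised spectrum above snr x noise scale.

    A flat (constant) spectrum yields an empty peak list.
    """
    intensity = np.asarray(spectrum.intensity, dtype=float)
    if len(intensity) < 8:
        raise ValueError("spectrum too short for wavelet peak picking (need >= 8 samples)")
    from scipy.signal import find_peaks

    smooth, sigma = denoise_spectrum(intensity)
    # prominence floor guards against float-level ripple in flat regions;
    # find_peaks treats plateaus as a single local maximum
    tol = 1e-8 * max(1.0, float(np.abs(smooth).max()))
    floor = snr * sigma if sigma > tol else tol
    apex, _ = find_peaks(smooth, height=floor, prominence=tol)
    return PeakList(
        mz=spectrum.mz[apex], intensity=smooth[apex], snr=snr, noise_scale=sigma
    )


def build_adaptive_bins(
    peaks: PeakList,
    merge_tol: float = 0.05,
    gap_bin_width: float = 0.5,
    gap_threshold: float = 1.0,
    half_width: float = 0.25,
) -> BinScheme:
    """Derive non-overlapping m/z bins from a reference peak list.

    Chains of peaks with consecutive spacing below ``merge_tol`` collapse
    into one merged bin spanning the chain.  Boundaries between adjacent
    bins sit at the midpoint between their edge peaks, clipped to at most
    ``half_width`` Daltons from the apex.  Inter-bin gaps wider than
    ``gap_threshold`` are tiled with contiguous filler bins of width
    ``gap_bin_width`` (last tile truncated to fit).
    """
    if len(peaks) == 0:
        raise ValueError("cannot build bins from an empty peak list")
    mz = np.asarray(peaks.mz, dtype=float)

    # group peaks into merge chains
    groups: list[list[int]] = [[0]]
    for i in range(1, len(mz)):
        if mz[i] - mz[i - 1] < merge_tol:
            groups[-1].append(i)
        else:
            groups.append([i])

    lows = np.array([mz[g[0]] for g in groups])
    highs = np.array([mz[g[-1]] for g in groups])

    rows = []
    for k, g in enumerate(groups):
        lo = lows[k] - half_width
        hi = highs[k] + half_width
        if k > 0:
            lo = max(lo, (lows[k] + highs[k - 1]) / 2.0)
        if k < len(groups) - 1:
            hi = min(hi, (highs[k] + lows[k + 1]) / 2.0)
        origin = "merged" if len(g) > 1 else "peak"
        rows.append((lo, hi, (lows[k] + highs[k]) / 2.0, origin))

    # tile wide gaps with filler bins
    tiled = []
    for k, row in enumerate(rows):
        tiled.append(row)
        if k == len(rows) - 1:
            break
        gap_lo, gap_hi = row[1], rows[k + 1][0]
        if gap_hi - gap_lo > gap_threshold:
            edge = gap_lo
            while gap_hi - edge > 1e-9:
                upper = min(edge + gap_bin_width, gap_hi)
                tiled.append((edge, upper, (edge + upper) / 2.0, "gap"))
                edge = upper

    tiled.sort(key=lambda r: r[2])
    df = pd.DataFrame(tiled, columns=["lower", "upper", "center", "origin"])
    return BinScheme(bins=df, merge_tol=merge_tol, gap_bin_width=gap_bin_width)


def binned_feature_table(ds: MSIDataset, bins: BinScheme, snr: float = 3.0) -> FeatureTable:
    """Per-pixel peak picking plus bin assignment.

    Each pixel's spectrum is denoised and peak-picked with the same rule as
    the reference spectrum; cell (pixel, bin) holds the maximum apex
    intensity of the pixel's peaks falling inside the bin, 0 if none.
    """
    matrix = np.zeros((ds.n_pixels, len(bins)))
    for k, (mz, inten) in enumerate(ds.spectra):
        pl = pick_peaks(ReferenceSpectrum(mz=mz, intensity=inten), snr=snr)
        if len(pl) == 0:
            continue
        idx = bins.assign(pl.mz)
        for b, apex in zip(idx, pl.intensity):
            if b >= 0:
                matrix[k, b] = max(matrix[k, b], apex)
    return FeatureTable(
        matrix=matrix, centers=bins.centers, pixels=ds.pixel_frame(), bins=bins
    )


def filter_low_coverage(
    ft: FeatureTable, min_frac: float = 0.20
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop rare bins and bins confined to a single tumour model.

    A bin is dropped when it is nonzero in fewer than ``min_frac`` of all
    tissue pixels, or when its nonzero pixels all belong to one model.
    Returns the filtered table and a report of dropped bins with reasons.
    """
    nonzero = ft.matrix != 0
    coverage = nonzero.mean(axis=0)
    models = ft.pixels["model_id"].to_numpy()
    n_models = np.array(
        [len(np.unique(models[nonzero[:, j]])) if nonzero[:, j].any() else 0
         for j in range(ft.n_bins)]
    )
    low = coverage < min_frac
    single = n_models <= 1
    drop = low | single
    if drop.all():
        raise ValueError("coverage filter would drop every bin")
    report = pd.DataFrame(
        {
            "center": ft.centers[drop],
            "coverage": coverage[drop],
            "n_models": n_models[drop],
            "reason": np.where(low[drop], "low_coverage", "single_model"),
        }
    )
    kept = ft.replace_matrix(ft.matrix[:, ~drop], centers=ft.centers[~drop])
    return kept, report


def _neighbor_stack(grid: np.ndarray, window: int) -> np.ndarray:
    """Stack of shifted copies of a NaN-padded grid covering the window."""
    r = window // 2
    padded = np.pad(grid, r, constant_values=np.nan)
    shifts = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            shifts.append(padded[r + dr: r + dr + grid.shape[0],
                                 r + dc: r + dc + grid.shape[1]])
    return np.stack(shifts)


def spatial_clean(ft: FeatureTable, window: int = 3) -> FeatureTable:
    """Mask-aware median filter plus tissue-edge correction, per ion image.

    The median at each pixel is taken over the in-mask pixels of the
    ``window`` x ``window`` neighbourhood.  Edge correction then replaces
    every rim pixel (fewer than 8 in-mask 8-neighbours) by the median of
    its in-mask neighbours, suppressing the inflated intensities at the
    tissue/glass boundary.  Isolated pixels are left unchanged.
    """
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    rc = ft.coords
    shape = ft.grid_shape
    out = np.empty_like(ft.matrix)

    for j in range(ft.n_bins):
        grid = np.full(shape, np.nan)
        grid[rc[:, 0], rc[:, 1]] = ft.matrix[:, j]

        stack = _neighbor_stack(grid, window)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows off mask
            filtered = np.nanmedian(stack, axis=0)

        # edge correction on the filtered image
        nb = _neighbor_stack(filtered, 3)
        center_pos = 4  # (0,0) shift in the 3x3 stack
        neighbors = np.delete(nb, center_pos, axis=0)
        n_in_mask = np.sum(~np.isnan(neighbors), axis=0)
        rim = (~np.isnan(grid)) & (n_in_mask < 8)
        inner = (~np.isnan(grid)) & ~rim
        corrected = filtered.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            nb_median = np.nanmedian(neighbors, axis=0)
        has_nb = rim & (n_in_mask > 0)
        corrected[has_nb] = nb_median[has_nb]
        isolated = rim & (n_in_mask == 0)
        if isolated.any() and j == 0:
            warnings.warn(f"{int(isolated.sum())} isolated pixel(s) left unchanged")
        corrected[isolated] = grid[isolated]
        corrected[inner] = filtered[inner]
        out[:, j] = corrected[rc[:, 0], rc[:, 1]]

    return ft.replace_matrix(out)


def glog(x: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """Generalised log g(x) = ln((x + sqrt(x^2 + lam)) / 2); ln(x) at lam=0."""
    if lam < 0:
        raise ValueError("glog parameter must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.log((x + np.sqrt(x * x + lam)) / 2.0)


def normalize_glog(ft: FeatureTable, lam: float = 1.0) -> FeatureTable:
    """Median normalisation followed by generalised-log stabilisation.

    Each pixel's spectrum is rescaled so that its median over nonzero bins
    equals the grand median of those per-pixel medians; pixels with no
    nonzero feature are dropped with a warning.  The glog transform then
    stabilises the variance of the rescaled intensities.
    """
    nonzero = ft.matrix != 0
    any_nonzero = nonzero.any(axis=1)
    if not any_nonzero.all():
        warnings.warn(
            f"dropping {int((~any_nonzero).sum())} pixel(s) with all-zero features"
        )
    m = ft.matrix[any_nonzero]
    pix = ft.pixels.loc[any_nonzero].reset_index(drop=True)
    drug = ft.drug_values[any_nonzero] if ft.drug_values is not None else None

    medians = np.array([np.median(row[row != 0]) for row in m])
    target = np.median(medians)
    scale = target / medians
    scaled = m * scale[:, None]
    out = FeatureTable(
        matrix=glog(scaled, lam=lam),
        centers=ft.centers,
        pixels=pix,
        bins=ft.bins,
        drug_values=glog(drug * scale, lam=lam) if drug is not None else None,
        drug_center=ft.drug_center,
    )
    return out


def remove_batch_effect(
    ft: FeatureTable, batch: np.ndarray, protect: np.ndarray | None = None
) -> FeatureTable:
    """Least-squares removal of batch-indicator effects per ion.

    Batch levels enter as sum-to-zero contrasts so the grand mean is
    preserved; an optional ``protect`` factor (e.g. treatment) is included
    in the model and its effects are retained in the output.  A batch
    factor perfectly confounded with the protected design raises.
    """
    batch = np.asarray(batch)
    if batch.shape[0] != ft.n_pixels:
        raise ValueError("batch labels must align with pixels")
    levels = np.unique(batch)
    if levels.size <= 1:
        return ft.replace_matrix(ft.matrix.copy())

    # sum-to-zero contrast columns for batch
    bcols = np.zeros((ft.n_pixels, levels.size - 1))
    for k, lev in enumerate(levels[:-1]):
        bcols[batch == lev, k] = 1.0
        bcols[batch == levels[-1], k] = -1.0

    design = [np.ones((ft.n_pixels, 1))]
    if protect is not None:
        protect = np.asarray(protect)
        plevels = np.unique(protect)
        pcols = np.zeros((ft.n_pixels, plevels.size - 1))
        for k, lev in enumerate(plevels[1:]):
            pcols[protect == lev, k] = 1.0
        design.append(pcols)
    design.append(bcols)
    x = np.hstack(design)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("batch factor is confounded with the protected design")

    coef, *_ = np.linalg.lstsq(x, ft.matrix, rcond=None)
    nb = bcols.shape[1]
    batch_part = bcols @ coef[-nb:]
    # centring the batch contribution restores the grand mean exactly
    corrected = ft.matrix - batch_part + batch_part.mean(axis=0)
    return ft.replace_matrix(corrected)


def drop_drug_correlated(
    ft: FeatureTable, drug_bin, r_max: float = 0.9
) -> tuple[FeatureTable, pd.DataFrame]:
    """Move the drug bin aside and drop features tracking the drug image.

    The drug bin itself is moved to ``drug_values`` (never a clustering
    feature); remaining features with Pearson correlation above ``r_max``
    against the drug image are removed.  Zero-variance features, whose
    correlation is undefined, are retained with a warning.
    """
    col = ft._col_index(drug_bin)
    drug = ft.matrix[:, col].copy()
    keep_cols = np.arange(ft.n_bins) != col
    matrix = ft.matrix[:, keep_cols]
    centers = ft.centers[keep_cols]

    if drug.std() == 0:
        raise ValueError("drug image has zero variance; correlation filter undefined")
    zd = (drug - drug.mean()) / drug.std()
    r = np.full(matrix.shape[1], np.nan)
    sds = matrix.std(axis=0)
    ok = sds > 0
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance feature(s) retained (correlation undefined)"
        )
    zm = (matrix[:, ok] - matrix[:, ok].mean(axis=0)) / sds[ok]
    r[ok] = zm.T @ zd / len(drug)

    drop = np.zeros(matrix.shape[1], dtype=bool)
    drop[ok] = r[ok] > r_max
    report = pd.DataFrame({"center": centers[drop], "r_with_drug": r[drop]})
    out = FeatureTable(
        matrix=matrix[:, ~drop],
        centers=centers[~drop],
        pixels=ft.pixels,
        bins=ft.bins,
        drug_values=drug,
        drug_center=float(ft.centers[col]),
    )
    return out, report
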