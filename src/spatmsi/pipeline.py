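"""Configuration-driven orchestration of the full workflow.

``run_pipeline`` executes preprocess -> segment -> homogeneity -> lisa ->
associate -> select on a feature-table input, writing every intermediate
artifact (cluster map, LISA map, homogeneity report, association table,
selected-ion lists) plus a manifest recording seeds, artifact hashes and
any stage failure.  All parameters live in a single YAML document; unknown
keys are rejected so that typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import homogeneity as homog
from . import preprocessing as prep
from . import regression as reg
from . import segmentation as seg
from . import spatial as sp
from .core import FeatureTable

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("spatmsi")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, YAML-serialisable."""

    input_table: str = ""
    output_dir: str = "spatmsi_out"
    seed: int = 0
    # preprocessing
    drug_bin: float | None = None
    r_max: float = 0.9
    min_frac: float = 0.20
    median_window: int = 3
    glog_lam: float = 1.0
    batch_column: str | None = None
    protect_column: str | None = None
    skip_preprocess: bool = False
    # segmentation
    max_share: float = 0.40
    k_max: int = 10
    n_init: int = 10
    # homogeneity
    nu: int = 5
    connectivity: int = 8
    # spatial / LISA
    lisa_lag_distance: float = 5.0
    # selection
    selection_method: str = "SL"
    selection_lag_distance: float = 5.0
    alpha: float = 0.05
    selection_clusters: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | os.PathLike) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("pipeline config must be a single YAML mapping")
    return PipelineConfig.from_dict(doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also written).

    Any stage failure is recorded in the manifest with the stage name and
    error; partial outputs are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": [], "artifacts": {}, "failures": []}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

    def artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "preprocess"
    try:
        log.info("[%s] loading %s", stage, cfg.input_table)
        ft = FeatureTable.from_csv(cfg.input_table)
        if not cfg.skip_preprocess:
            if cfg.drug_bin is not None and ft.drug_values is None:
                ft, corr_report = prep.drop_drug_correlated(ft, cfg.drug_bin, r_max=cfg.r_max)
                _write_csv(corr_report, out / "drug_correlated_bins.csv")
                artifact("drug_correlated_bins", out / "drug_correlated_bins.csv")
            ft, dropped = prep.filter_low_coverage(ft, min_frac=cfg.min_frac)
            _write_csv(dropped, out / "dropped_bins.csv")
            artifact("dropped_bins", out / "dropped_bins.csv")
            ft = prep.spatial_clean(ft, window=cfg.median_window)
            ft = prep.normalize_glog(ft, lam=cfg.glog_lam)
            if cfg.batch_column:
                protect = (
                    ft.pixels[cfg.protect_column].to_numpy()
                    if cfg.protect_column else None
                )
                ft = prep.remove_batch_effect(
                    ft, ft.pixels[cfg.batch_column].to_numpy(), protect=protect
                )
        ft.to_csv(out / "feature_table.csv")
        artifact("feature_table", out / "feature_table.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failures"].append({"stage": stage, "error": str(exc)})
        _finish(manifest, out)
        return manifest

    stage = "segment"
    try:
        log.info("[%s] bisecting k-means on %d pixels", stage, ft.n_pixels)
        ci = seg.bisecting_segmentation(
            ft.matrix, max_share=cfg.max_share, k_max=cfg.k_max,
            seed=cfg.seed, n_init=cfg.n_init,
        )
        labels = ci.labels
        cmap = ft.pixels[["x", "y"]].copy()
        cmap["label"] = labels
        _write_csv(cmap, out / "cluster_map.csv")
        artifact("cluster_map", out / "cluster_map.csv")
        comp = seg.cluster_composition(
            labels, ft.pixels["model_id"].astype(str) + "/" + ft.pixels["treatment"].astype(str)
        )
        comp.reset_index().to_csv(out / "cluster_composition.csv", index=False)
        artifact("cluster_composition", out / "cluster_composition.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failures"].append({"stage": stage, "error": str(exc)})
        _finish(manifest, out)
        return manifest

    stage = "homogeneity"
    try:
        rows = []
        for (model, sl), grp in ft.pixels.groupby(["model_id", "slice_id"], sort=True):
            idx = grp.index.to_numpy()
            rc = ft.coords[idx]
            grid = np.full((rc[:, 0].max() + 1, rc[:, 1].max() + 1), np.nan)
            grid[rc[:, 0], rc[:, 1]] = labels[idx]
            rep = homog.homogeneity_report(grid, nu=cfg.nu, connectivity=cfg.connectivity)
            rep.insert(0, "model_id", model)
            rep.insert(1, "slice_id", sl)
            rows.append(rep)
        _write_csv(pd.concat(rows, ignore_index=True), out / "homogeneity.csv")
        artifact("homogeneity", out / "homogeneity.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failures"].append({"stage": stage, "error": str(exc)})
        _finish(manifest, out)
        return manifest

    stage = "lisa"
    lisa_by_slice: dict = {}
    try:
        if ft.drug_values is None:
            raise ValueError("no drug column in the feature table; set drug_bin")
        rows = []
        for sl, grp in ft.pixels.groupby("slice_id", sort=True):
            idx = grp.index.to_numpy()
            coords = ft.coords[idx]
            w = sp.build_weights(coords, threshold=cfg.lisa_lag_distance,
                                 style="row_standardized")
            lm = sp.lisa_map(ft.drug_values[idx], w)
            lisa_by_slice[sl] = (idx, lm)
            df = pd.DataFrame({
                "slice_id": sl, "x": coords[:, 1], "y": coords[:, 0], "zone": lm.zones,
            })
            rows.append(df)
        _write_csv(pd.concat(rows, ignore_index=True), out / "lisa_map.csv")
        artifact("lisa_map", out / "lisa_map.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failures"].append({"stage": stage, "error": str(exc)})
        _finish(manifest, out)
        return manifest

    stage = "associate"
    try:
        rows = []
        for sl, (idx, lm) in sorted(lisa_by_slice.items()):
            tab = assoc.zone_cluster_table(lm.zones, labels[idx], normalize="fractions")
            v = assoc.cramers_v(tab)
            t = (tab.table * 100).reset_index()
            t.insert(0, "slice_id", sl)
            t["cramers_v"] = v
            rows.append(t)
        _write_csv(pd.concat(rows, ignore_index=True), out / "association.csv")
        artifact("association", out / "association.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failures"].append({"stage": stage, "error": str(exc)})
        _finish(manifest, out)
        return manifest

    stage = "select"
    try:
        clusters = cfg.selection_clusters or sorted(np.unique(labels).tolist())
        rows = []
        for cl in clusters:
            slices = [
                sl for sl in pd.unique(ft.pixels["slice_id"])
                if 0 < (labels[ft.pixels["slice_id"] == sl] == cl).sum()
                < (ft.pixels["slice_id"] == sl).sum()
            ]
            if not slices:
                continue
            sel = reg.select_cluster_ions(
                ft, labels, cluster=int(cl), slices=slices,
                method=cfg.selection_method, alpha=cfg.alpha,
                lag_distance=cfg.selection_lag_distance,
            )
            for c in sel.final:
                rows.append({
                    "cluster": cl, "center": c, "sign": sel.signs[c],
                    "max_adjusted_p": max(sel.per_slice[sl][c][0] for sl in slices),
                })
        df = pd.DataFrame(rows, columns=["cluster", "center", "sign", "max_adjusted_p"])
        _write_csv(df, out / "selected_ions.csv")
        artifact("selected_ions", out / "selected_ions.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failures"].append({"stage": stage, "error": str(exc)})

    _finish(manifest, out)
    return manifest


def _finish(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
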