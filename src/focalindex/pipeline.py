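"""End-to-end per-scan and cohort orchestration.

``run_scan`` chains ingest -> (segment) -> clip -> regions -> profiles ->
focal index -> quantitation into a single self-describing :class:`ScanReport`
that serialises deterministically (re-running on identical inputs and
configuration reproduces it byte for byte). ``run_cohort`` maps a manifest of
scans and clinical covariates to per-scan reports plus the cohort statistics
battery (correlations of the focal index with regional aeration, gas volume,
weight and fluid balance, and the ventilatory-settings sensitivity
regression).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import FocalIndexError, ManifestError, UndefinedCorrelationError
from .focal import FocalIndexResult, focal_index
from .io import CTVolume, LungMask, clip_hu, load_mask, load_volume
from .profiles import AerationSummary, HUProfile, aeration_summary, compute_profile
from .quantitation import QuantitationResult, quantify
from .regions import DORSAL_DIAPHRAGMATIC, ROI_IDS, VENTRAL_APICAL, RegionMap, build_region_map
from .segmentation import SegmentationParams, segment_lungs
from .stats import (
    SENSITIVITY_PREDICTORS,
    CorrelationResult,
    pearson_with_ci,
    sensitivity_regression,
)

#: Cohort correlations computed for the focal index, (label, column) pairs.
CORRELATION_BATTERY = (
    ("fi_vs_dd_nonaer", "dorsal_diaphragmatic_nonaer_percent"),
    ("fi_vs_va_hyper", "ventral_apical_hyper_percent"),
    ("fi_vs_total_gas", "total_gas_ml"),
    ("fi_vs_lung_weight", "lung_weight_g"),
    ("fi_vs_fluid_balance", "fluid_balance_ml"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric choice of the pipeline, hashed into each report."""

    n_slices: int = 18
    grav_extent: str = "per-slice"  # or "global"
    bin_width_hu: float = 5.0
    hu_min: float = -1000.0
    hu_max: float = 100.0
    gas_reference_hu: float = -1000.0
    correlation_method: str = "pearson"

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ScanReport:
    """All per-scan outputs, JSON-serialisable and deterministic."""

    source_id: str
    focal_index: FocalIndexResult
    profiles: dict[str, HUProfile]
    aeration: dict[str, AerationSummary]
    roi_voxel_counts: dict[str, int]
    slice_indices: tuple[int, ...]
    quantitation: QuantitationResult
    warnings: tuple[str, ...]
    config_digest: str
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "version": self.version,
            "config_digest": self.config_digest,
            "focal_index": round(self.focal_index.value, 10),
            "overlap_percent": round(self.focal_index.overlap_percent, 10),
            "slice_indices": list(self.slice_indices),
            "roi_voxel_counts": dict(self.roi_voxel_counts),
            "aeration": {
                roi: {
                    "hyper_percent": _jsonify(s.hyper_percent),
                    "nonaer_percent": _jsonify(s.nonaer_percent),
                }
                for roi, s in self.aeration.items()
            },
            "quantitation": {
                "gas_volume_ml": round(self.quantitation.gas_volume_ml, 8),
                "lung_weight_g": round(self.quantitation.lung_weight_g, 8),
                "method": self.quantitation.method,
            },
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _jsonify(x: float) -> float | None:
    return None if np.isnan(x) else round(float(x), 10)


def run_scan_arrays(
    volume: CTVolume,
    mask: LungMask | None = None,
    config: PipelineConfig | None = None,
    segmentation: SegmentationParams | None = None,
) -> ScanReport:
    """Run the full analysis on an in-memory volume.

    An external mask takes precedence; without one the fallback segmentation
    runs with ``segmentation`` parameters.
    """
    config = config or PipelineConfig()
    warnings: list[str] = []
    if mask is None:
        mask = segment_lungs(volume, segmentation)
        warnings.append("mask produced by fallback segmentation, not an external mask")

    clipped = clip_hu(volume, mask)
    n_clipped = int(np.sum(volume.voxels[mask.labels] != clipped.voxels[mask.labels]))
    if n_clipped:
        warnings.append(f"{n_clipped} in-mask voxels clipped to [{config.hu_min:g}, {config.hu_max:g}] HU")

    region_map = build_region_map(
        clipped, mask, n_slices=config.n_slices, extent_mode=config.grav_extent
    )
    warnings.extend(region_map.warnings)

    profiles = {
        roi: compute_profile(region_map.voxels_of(roi, clipped), roi_id=roi) for roi in ROI_IDS
    }
    aeration = {roi: aeration_summary(p) for roi, p in profiles.items()}
    fi = focal_index(profiles[VENTRAL_APICAL], profiles[DORSAL_DIAPHRAGMATIC])
    quant = quantify(clipped, mask, region_map.selection)

    return ScanReport(
        source_id=volume.source_id,
        focal_index=fi,
        profiles=profiles,
        aeration=aeration,
        roi_voxel_counts=region_map.roi_voxel_counts,
        slice_indices=region_map.selection.indices,
        quantitation=quant,
        warnings=tuple(warnings),
        config_digest=config.digest(),
    )


def run_scan(
    ct_path: str | os.PathLike,
    mask_path: str | os.PathLike | None = None,
    config: PipelineConfig | None = None,
    segmentation: SegmentationParams | None = None,
) -> ScanReport:
    """File-based variant of :func:`run_scan_arrays`."""
    try:
        volume = load_volume(ct_path)
        mask = load_mask(mask_path, reference=volume) if mask_path else None
    except FocalIndexError as exc:
        raise type(exc)(f"ingest stage failed for {ct_path}: {exc}") from exc
    return run_scan_arrays(volume, mask, config=config, segmentation=segmentation)


def cohort_table(reports: list[ScanReport], covariates: pd.DataFrame) -> pd.DataFrame:
    """Join per-scan measurements with clinical covariates into one table.

    ``covariates`` must carry a ``source_id`` column plus fluid balance and
    the ventilatory settings; missing scans raise :class:`ManifestError`.
    """
    rows = []
    for rep in reports:
        rows.append(
            {
                "source_id": rep.source_id,
                "focal_index": rep.focal_index.value,
                "dorsal_diaphragmatic_nonaer_percent": rep.aeration[
                    DORSAL_DIAPHRAGMATIC
                ].nonaer_percent,
                "ventral_apical_hyper_percent": rep.aeration[VENTRAL_APICAL].hyper_percent,
                "total_gas_ml": rep.quantitation.gas_volume_ml,
                "lung_weight_g": rep.quantitation.lung_weight_g,
            }
        )
    measured = pd.DataFrame(rows)
    if "source_id" not in covariates.columns:
        raise ManifestError("covariate table lacks a source_id column")
    missing = set(measured.source_id) - set(covariates.source_id)
    if missing:
        raise ManifestError(f"covariates missing for scans: {sorted(missing)}")
    table = measured.merge(covariates, on="source_id", how="left")
    return table.sort_values("source_id", kind="stable").reset_index(drop=True)


def cohort_statistics(table: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """The study's correlation/regression battery on a cohort table."""
    config = config or PipelineConfig()
    if len(table) < 3:
        raise ManifestError(f"need >= 3 scans for cohort statistics, got {len(table)}")
    fi = table["focal_index"].to_numpy(dtype=float)
    if np.ptp(fi) == 0:
        raise UndefinedCorrelationError(
            "focal index has zero variance across the cohort; correlations undefined"
        )
    out: dict = {"n_scans": int(len(table)), "correlations": {}}
    for label, column in CORRELATION_BATTERY:
        if column not in table.columns:
            continue
        try:
            res = pearson_with_ci(fi, table[column], method=config.correlation_method)
        except UndefinedCorrelationError as exc:
            # a constant covariate leaves one entry undefined, not the battery
            out["correlations"][label] = {"undefined": str(exc)}
            continue
        out["correlations"][label] = {
            "r": round(res.r, 10),
            "ci_low": round(res.ci_low, 10),
            "ci_high": round(res.ci_high, 10),
            "p": round(res.p, 10),
            "n": res.n,
        }
    if all(c in table.columns for c in SENSITIVITY_PREDICTORS):
        reg = sensitivity_regression(table)
        out["sensitivity_regression"] = {
            "params": {k: round(v, 10) for k, v in reg.params.items()},
            "pvalues": {k: round(v, 10) for k, v in reg.pvalues.items()},
            "r_squared": round(reg.r_squared, 10),
            "adj_r_squared": round(reg.adj_r_squared, 10),
            "f_pvalue": round(reg.f_pvalue, 10),
        }
    return out


def run_cohort(
    manifest: pd.DataFrame | str | os.PathLike,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict, list[ScanReport]]:
    """Process every scan of a manifest and compute the cohort statistics.

    The manifest needs columns ``source_id, ct_path`` and optionally
    ``mask_path`` plus the covariate columns. Returns the cohort table, the
    statistics dict, and the per-scan reports (manifest row order does not
    affect the statistics: the table is sorted by source_id).
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"source_id", "ct_path"}
    if not required.issubset(manifest.columns):
        raise ManifestError(f"manifest must have columns {sorted(required)}")
    reports = []
    for _, row in manifest.iterrows():
        mask_path = row.get("mask_path")
        if isinstance(mask_path, float) and np.isnan(mask_path):
            mask_path = None
        rep = run_scan(row["ct_path"], mask_path, config=config)
        rep = dataclasses.replace(rep, source_id=str(row["source_id"]))
        reports.append(rep)
    covar_cols = ["source_id"] + [
        c for c in manifest.columns if c not in ("ct_path", "mask_path")
    ]
    covar_cols = list(dict.fromkeys(covar_cols))
    table = cohort_table(reports, manifest[covar_cols])
    stats = cohort_statistics(table, config=config)
    return table, stats, reports
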