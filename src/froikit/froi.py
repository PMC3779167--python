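"""Subject-specific functional ROI definition and parameter extraction.

Within a region's hypothesis space, a subject's candidate voxels are
those individually significant at ``candidate_p`` (uncorrected, via the
map's df) that sit in a connected suprathreshold cluster of at least
``min_other_voxels`` + 1 voxels.  The fROI is then grown from the peak
candidate: the peak plus every candidate voxel within ``radius_mm``
(Euclidean, world mm, inclusive) of the peak that is connected to the
peak through other selected candidates.

Five parameters are extracted per subject x region — voxel count, mean
statistic, and the statistic-weighted center of mass (x, y, z in mm) —
plus a binary found-flag.  Parameters of absent ROIs are reported as
missing values, never zeros.

"Contiguous with at least 10 other voxels" is interpreted transitively
(cluster-extent of 11+), the standard cluster-thresholding reading: a
literal 10-neighbour rule would forbid chain-shaped clusters outright.
Cluster contiguity is evaluated within the masked map by default
(masking precedes candidate identification); set
``cluster_within_mask=False`` to cluster on the whole map and clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hypothesis_space import HypothesisSpace
from .volumes import (ScalarVolume, connectivity_structure, label_components)

__all__ = ["FroiConfig", "FroiResult", "find_candidates", "select_froi",
           "extract_parameters", "define_froi", "froi_table"]

PARAM_NAMES = ("size", "mean_t", "com_x", "com_y", "com_z")


@dataclass(frozen=True)
class FroiConfig:
    candidate_p: float = 0.001
    min_other_voxels: int = 10
    radius_mm: float = 9.0
    connectivity: int = 26
    cluster_within_mask: bool = True

    def __post_init__(self):
        if not 0 < self.candidate_p < 1:
            raise ValueError("candidate_p must be in (0, 1)")
        if self.min_other_voxels < 0:
            raise ValueError("min_other_voxels must be >= 0")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")


@dataclass
class FroiResult:
    region: str
    found: bool
    voxels: np.ndarray  # (n, 3) int indices; empty when not found
    size: int
    mean_t: float  # nan when not found
    com_mm: tuple[float, float, float]  # nans when not found

    def as_row(self) -> dict:
        return {
            "region": self.region,
            "found": int(self.found),
            "size": self.size if self.found else np.nan,
            "mean_t": self.mean_t,
            "com_x": self.com_mm[0],
            "com_y": self.com_mm[1],
            "com_z": self.com_mm[2],
        }


def _t_cutoff(tmap: ScalarVolume, config: FroiConfig) -> float:
    if tmap.df is None:
        raise ValueError("tmap must carry df to convert candidate_p "
                         "to a t cutoff")
    return float(stats.t.isf(config.candidate_p, tmap.df))


def find_candidates(tmap: ScalarVolume, space: HypothesisSpace,
                    config: FroiConfig = FroiConfig()) -> np.ndarray:
    """Candidate voxel indices (n, 3) inside the hypothesis space."""
    if not tmap.grid.matches(space.mask.grid):
        raise ValueError("tmap and hypothesis space must share a grid")
    cutoff = _t_cutoff(tmap, config)
    supra = tmap.values > cutoff
    if config.cluster_within_mask:
        field_ = supra & space.mask.data
        labels, n = label_components(field_, config.connectivity)
        keep = np.zeros(n + 1, dtype=bool)
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep[1:] = sizes[1:] >= config.min_other_voxels + 1
        return np.argwhere(keep[labels])
    labels, n = label_components(supra, config.connectivity)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= config.min_other_voxels + 1
    return np.argwhere(keep[labels] & space.mask.data)


def select_froi(candidates: np.ndarray, tmap: ScalarVolume,
                config: FroiConfig = FroiConfig(),
                region: str = "") -> FroiResult:
    """Grow the ROI from the peak candidate voxel.

    The peak is the candidate with the highest statistic (ties broken by
    lowest linear voxel index, deterministically).  Selected voxels are
    candidates within ``radius_mm`` of the peak that are connected to the
    peak through the radius-restricted candidate set.
    """
    candidates = np.asarray(candidates, dtype=int).reshape(-1, 3)
    if candidates.shape[0] == 0:
        return _not_found(region)
    grid = tmap.grid
    tvals = tmap.values[tuple(candidates.T)]
    linear = np.ravel_multi_index(tuple(candidates.T), grid.dims)
    order = np.lexsort((linear, -tvals))
    peak = candidates[order[0]]

    world = grid.voxel_to_world(candidates)
    peak_mm = grid.voxel_to_world(peak)
    within = np.linalg.norm(world - peak_mm, axis=1) <= config.radius_mm

    allowed = np.zeros(grid.dims, dtype=bool)
    allowed[tuple(candidates[within].T)] = True
    labels, _ = label_components(allowed, config.connectivity)
    roi_mask = labels == labels[tuple(peak)]
    voxels = np.argwhere(roi_mask)
    return extract_parameters_from_voxels(voxels, tmap, region)


def extract_parameters_from_voxels(voxels: np.ndarray, tmap: ScalarVolume,
                                   region: str = "") -> FroiResult:
    """Size, mean statistic and T-weighted center of mass of a voxel set."""
    voxels = np.asarray(voxels, dtype=int).reshape(-1, 3)
    if voxels.shape[0] == 0:
        return _not_found(region)
    tvals = tmap.values[tuple(voxels.T)]
    world = tmap.grid.voxel_to_world(voxels)
    weights = tvals / tvals.sum()
    com = tuple(float(c) for c in weights @ world)
    return FroiResult(region=region, found=True, voxels=voxels,
                      size=int(voxels.shape[0]),
                      mean_t=float(tvals.mean()), com_mm=com)


def extract_parameters(result: FroiResult, tmap: ScalarVolume):
    """(size, mean_t, com_mm, found) of an existing result, recomputed."""
    if not result.found:
        return (np.nan, np.nan, (np.nan, np.nan, np.nan), False)
    fresh = extract_parameters_from_voxels(result.voxels, tmap, result.region)
    return (fresh.size, fresh.mean_t, fresh.com_mm, True)


def define_froi(tmap: ScalarVolume, space: HypothesisSpace,
                config: FroiConfig = FroiConfig()) -> FroiResult:
    """Full per-subject pipeline: candidates then peak-growth."""
    candidates = find_candidates(tmap, space, config)
    return select_froi(candidates, tmap, config, region=space.name)


def froi_table(results: dict[str, dict[str, FroiResult]]) -> pd.DataFrame:
    """Tabulate {subject_id: {region: FroiResult}} into long format."""
    rows = []
    for sid, per_region in results.items():
        for res in per_region.values():
            row = {"id": sid}
            row.update(res.as_row())
            rows.append(row)
    return pd.DataFrame(rows,
                        columns=["id", "region", "found", "size", "mean_t",
                                 "com_x", "com_y", "com_z"])


def _not_found(region: str) -> FroiResult:
    return FroiResult(region=region, found=False,
                      voxels=np.empty((0, 3), dtype=int), size=0,
                      mean_t=float("nan"),
                      com_mm=(float("nan"),) * 3)
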