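"""Group-level hypothesis spaces for subject-specific ROI definition.

A hypothesis space is the connected suprathreshold cluster, in a group
random-effects T-map, that contains a named region's representative seed
point.  To keep fROI definition independent of the group map it is grown
in, the cohort is split into two halves: spaces built from half 1 are
applied only to subjects in half 2 and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import REGION_CENTERS_MM
from .volumes import (BinaryMask, ScalarVolume, VolumeGrid,
                      connectivity_structure, label_components)

__all__ = [
    "HypothesisSpace",
    "RegionNotFoundError",
    "split_sample",
    "group_rfx_tmap",
    "extract_hypothesis_space",
    "DEFAULT_SEED_POINTS",
    "DEFAULT_Z_CLAMPS",
]

#: default seed points: the canonical printed region centers (MNI mm)
DEFAULT_SEED_POINTS = dict(REGION_CENTERS_MM)

#: per-region axis clamps (mm) separating the medial-prefrontal tiers
#: and keeping temporal regions off midline artifacts
DEFAULT_Z_CLAMPS = {
    "DMPFC": ("z>", 20.0),
    "MMPFC": ("z_between", (0.0, 20.0)),
    "VMPFC": ("z<", 0.0),
    "RTPJ": ("z>", 6.0),
    "LTPJ": ("z>", 6.0),
    "RSTS": ("z>", 6.0),
}


class RegionNotFoundError(RuntimeError):
    """No suprathreshold voxel near the requested seed point."""


@dataclass
class HypothesisSpace:
    name: str
    mask: BinaryMask
    source_half: int
    seed_point_mm: tuple[float, float, float]

    def __post_init__(self):
        if self.mask.size == 0:
            raise ValueError(f"hypothesis space {self.name!r} is empty")


def split_sample(records: pd.DataFrame, seed: int = 0):
    """Randomly split a cohort into two halves, balancing group labels.

    Each diagnostic group is split as evenly as possible, so overall
    half sizes differ by at most 1 and ASD counts differ by at most 1.
    Returns (half1, half2) as DataFrames.  Deterministic given seed.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    half1_idx, half2_idx = [], []
    # stratify by group; alternate leftover singletons between halves so
    # neither half systematically gets the larger share
    flip = rng.integers(0, 2)
    for k, (_, sub) in enumerate(records.groupby("group", sort=True)):
        order = sub.index.to_numpy().copy()
        rng.shuffle(order)
        cut = (len(order) + ((k + flip) % 2)) // 2
        half1_idx.extend(order[:cut])
        half2_idx.extend(order[cut:])
    return (records.loc[half1_idx].sort_index(),
            records.loc[half2_idx].sort_index())


def group_rfx_tmap(maps: list[ScalarVolume]) -> ScalarVolume:
    """Voxelwise one-sample t across subjects; df = n - 1.

    Zero-variance voxels: t is 0 when the mean is also 0, else signed
    infinity (both cases are flagged by being non-finite-variance and
    matter only on degenerate synthetic input).
    """
    if len(maps) < 2:
        raise ValueError("need >= 2 maps for a random-effects map")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.matches(grid):
            raise ValueError("all maps must share one grid")
    data = np.stack([m.values for m in maps])
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var & (mean == 0)] = 0.0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    return ScalarVolume(grid, t, df=n - 1)


def _apply_clamp(supra: np.ndarray, grid: VolumeGrid, clamp) -> np.ndarray:
    kind, value = clamp
    z = grid.all_world_coords()[..., 2]
    if kind == "z>":
        return supra & (z > value)
    if kind == "z<":
        return supra & (z < value)
    if kind == "z_between":
        lo, hi = value
        return supra & (z > lo) & (z < hi)
    raise ValueError(f"unknown clamp kind {kind!r}")


def extract_hypothesis_space(tmap: ScalarVolume, name: str,
                             seed_point_mm,
                             threshold_p: float = 0.001,
                             connectivity: int = 26,
                             search_radius_mm: float = 12.0,
                             source_half: int = 1,
                             clamp=None) -> HypothesisSpace:
    """The connected suprathreshold cluster containing the seed point.

    Threshold is the one-sided t cutoff for ``threshold_p`` at the map's
    df.  If the seed's own voxel is subthreshold, the nearest
    suprathreshold voxel within ``search_radius_mm`` is used instead.
    Optional ``clamp`` restricts the suprathreshold set along z before
    clustering (used to split the medial-prefrontal tiers).
    """
    grid = tmap.grid
    seed_vox = grid.world_to_voxel(seed_point_mm)
    if not grid.contains(seed_vox):
        raise ValueError(f"seed point {seed_point_mm} outside grid")
    if tmap.df is None:
        raise ValueError("tmap must carry df to convert p to a t cutoff")
    cutoff = stats.t.isf(threshold_p, tmap.df)
    supra = tmap.values > cutoff
    if clamp is not None:
        supra = _apply_clamp(supra, grid, clamp)
    labels, _ = label_components(supra, connectivity)

    lab = labels[tuple(seed_vox)]
    if lab == 0:
        lab = _nearest_suprathreshold_label(grid, labels, supra,
                                            seed_point_mm, search_radius_mm)
        if lab == 0:
            raise RegionNotFoundError(
                f"region {name!r}: no suprathreshold voxel within "
                f"{search_radius_mm} mm of seed {tuple(seed_point_mm)}")
    mask = BinaryMask(grid, labels == lab)
    member_vox = grid.world_to_voxel(seed_point_mm)
    if not mask.data[tuple(member_vox)]:
        # seed voxel itself subthreshold: keep the nearest member as the
        # space's recorded seed anchor
        members = mask.members
        d = np.linalg.norm(grid.voxel_to_world(members)
                           - np.asarray(seed_point_mm), axis=1)
        member_vox = members[int(np.argmin(d))]
    anchor_mm = tuple(float(x) for x in grid.voxel_to_world(member_vox))
    return HypothesisSpace(name=name, mask=mask, source_half=source_half,
                           seed_point_mm=anchor_mm)


def _nearest_suprathreshold_label(grid, labels, supra, seed_point_mm,
                                  search_radius_mm) -> int:
    members = np.argwhere(supra)
    if members.size == 0:
        return 0
    d = np.linalg.norm(grid.voxel_to_world(members)
                       - np.asarray(seed_point_mm), axis=1)
    i = int(np.argmin(d))
    if d[i] > search_radius_mm:
        return 0
    return int(labels[tuple(members[i])])


def build_spaces_for_half(maps: list[ScalarVolume], source_half: int,
                          seed_points: dict | None = None,
                          threshold_p: float = 0.001,
                          connectivity: int = 26,
                          clamps: dict | None = None,
                          search_radius_mm: float = 12.0,
                          strict: bool = False) -> dict[str, HypothesisSpace]:
    """Random-effects map over one half-sample, then one space per region.

    Regions whose seed has no nearby suprathreshold cluster are skipped
    (or raised, when ``strict``).
    """
    seed_points = seed_points or DEFAULT_SEED_POINTS
    clamps = DEFAULT_Z_CLAMPS if clamps is None else clamps
    tmap = group_rfx_tmap(maps)
    spaces = {}
    for name, seed_mm in seed_points.items():
        try:
            spaces[name] = extract_hypothesis_space(
                tmap, name, seed_mm, threshold_p=threshold_p,
                connectivity=connectivity, source_half=source_half,
                search_radius_mm=search_radius_mm,
                clamp=clamps.get(name))
        except RegionNotFoundError:
            if strict:
                raise
    return spaces
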