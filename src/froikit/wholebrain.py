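"""Whole-brain group analyses: voxelwise group-difference maps, cluster
extraction at fixed thresholds, and the split-half discover-then-validate
procedure.

Discovery runs at a lenient voxelwise threshold (p < 0.001 uncorrected)
in one half of each subject's data; each discovered cluster is then
validated by extracting its mean contrast value per subject in the
*other* half and testing the group difference there (significant when
the same-direction difference reaches p < 0.05).  Independence of the
two halves is enforced structurally: maps carry a half tag and the
validator refuses the discovery half.

A max-statistic label-permutation option provides a familywise-corrected
whole-brain alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volumes import ScalarVolume, label_components

__all__ = ["ClusterRecord", "voxelwise_group_diff_tmap",
           "clusters_at_threshold", "validate_in_heldout",
           "max_stat_threshold"]


@dataclass
class ClusterRecord:
    peak_mm: tuple[float, float, float]
    peak_t: float
    size: int
    voxels: np.ndarray  # (n, 3)
    discovery_half: str = ""
    direction: int = 1  # +1: A>B, -1: B>A
    top_peaks: list = field(default_factory=list)  # [(xyz_mm, t), ...]
    validation_p: float | None = None
    validated: bool | None = None


def _stack(maps: list[ScalarVolume]) -> np.ndarray:
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.matches(grid):
            raise ValueError("maps must share one grid")
    return np.stack([m.values for m in maps])


def voxelwise_group_diff_tmap(maps_a: list[ScalarVolume],
                              maps_b: list[ScalarVolume],
                              nuisance: np.ndarray | None = None
                              ) -> ScalarVolume:
    """Per-voxel two-sample t-map, signed A - B.

    With ``nuisance`` (an (nA+nB, q) matrix of covariates, A rows first),
    each voxel is fit by OLS on [intercept, group, nuisance] and the
    group coefficient's t is returned; otherwise a pooled-variance
    two-sample t.  df = nA + nB - 2 (or n - p with nuisance).
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need >= 2 maps per group")
    a = _stack(maps_a)
    b = _stack(maps_b)
    if not maps_a[0].grid.matches(maps_b[0].grid):
        raise ValueError("groups must share one grid")
    grid = maps_a[0].grid
    na, nb = a.shape[0], b.shape[0]
    if nuisance is None:
        mean_d = a.mean(axis=0) - b.mean(axis=0)
        sp2 = ((na - 1) * a.var(axis=0, ddof=1)
               + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_d / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t[~np.isfinite(t)] = 0.0
        return ScalarVolume(grid, t, df=na + nb - 2)
    # per-voxel GLM with nuisance regressors, solved once via pinv
    nuisance = np.asarray(nuisance, dtype=float)
    n = na + nb
    if nuisance.shape[0] != n:
        raise ValueError("nuisance rows must match total subjects")
    group = np.concatenate([np.ones(na), np.zeros(nb)])
    X = np.column_stack([np.ones(n), group - group.mean(),
                         nuisance - nuisance.mean(axis=0)])
    p = X.shape[1]
    Y = np.concatenate([a, b]).reshape(n, -1)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid ** 2).sum(axis=0) / (n - p)
    xtx_inv_g = np.linalg.inv(X.T @ X)[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / np.sqrt(sigma2 * xtx_inv_g)
    t[~np.isfinite(t)] = 0.0
    return ScalarVolume(grid, t.reshape(grid.dims), df=n - p)


def clusters_at_threshold(tmap: ScalarVolume, p_threshold: float = 0.001,
                          min_size: int = 0, connectivity: int = 26,
                          n_top_peaks: int = 3,
                          discovery_half: str = "",
                          direction: int = 1) -> list[ClusterRecord]:
    """Suprathreshold connected components of size >= min_size.

    Thresholds the positive tail of ``direction * tmap`` at the
    one-sided t cutoff for ``p_threshold`` at the map's df.  Clusters
    are sorted by peak t then first linear index; up to ``n_top_peaks``
    local peaks are reported per cluster.
    """
    if tmap.df is None:
        raise ValueError("tmap must carry df")
    cutoff = stats.t.isf(p_threshold, tmap.df)
    values = direction * tmap.values
    supra = values > cutoff
    labels, n = label_components(supra, connectivity)
    records = []
    for lab in range(1, n + 1):
        voxels = np.argwhere(labels == lab)
        if voxels.shape[0] < max(min_size, 1):
            continue
        tvals = values[tuple(voxels.T)]
        order = np.argsort(-tvals, kind="stable")
        peak_vox = voxels[order[0]]
        top = [(tuple(float(c) for c in tmap.grid.voxel_to_world(voxels[i])),
                float(tvals[i]))
               for i in order[:n_top_peaks]]
        records.append(ClusterRecord(
            peak_mm=tuple(float(c)
                          for c in tmap.grid.voxel_to_world(peak_vox)),
            peak_t=float(tvals[order[0]]), size=int(voxels.shape[0]),
            voxels=voxels, discovery_half=discovery_half,
            direction=direction, top_peaks=top))
    records.sort(key=lambda r: (-r.peak_t, np.ravel_multi_index(
        tuple(r.voxels[0]), tmap.grid.dims)))
    return records


def validate_in_heldout(clusters: list[ClusterRecord],
                        heldout_a: list[ScalarVolume],
                        heldout_b: list[ScalarVolume],
                        heldout_half: str,
                        alpha: float = 0.05) -> list[ClusterRecord]:
    """Test each discovered cluster's group difference in held-out maps.

    Per cluster: the mean contrast over member voxels is extracted per
    held-out subject; a two-sample t-test compares groups; the cluster
    validates when the difference has the discovery direction and
    two-sided p < alpha.  Refuses validation against the discovery half.
    """
    a = _stack(heldout_a)
    b = _stack(heldout_b)
    out = []
    for cluster in clusters:
        if cluster.discovery_half and cluster.discovery_half == heldout_half:
            raise ValueError(
                f"cluster discovered in half {cluster.discovery_half!r} "
                f"cannot be validated on the same half")
        if cluster.voxels.shape[0] == 0:
            raise ValueError("empty cluster after grid alignment")
        idx = tuple(cluster.voxels.T)
        resp_a = a[:, idx[0], idx[1], idx[2]].mean(axis=1)
        resp_b = b[:, idx[0], idx[1], idx[2]].mean(axis=1)
        t, p = stats.ttest_ind(resp_a, resp_b)
        same_dir = np.sign(t) == np.sign(cluster.direction)
        cluster.validation_p = float(p)
        cluster.validated = bool(same_dir and p < alpha)
        out.append(cluster)
    return out


def max_stat_threshold(maps_a: list[ScalarVolume],
                       maps_b: list[ScalarVolume],
                       n_perm: int = 1000, seed: int = 0,
                       alpha: float = 0.05) -> float:
    """Familywise-corrected voxelwise |t| threshold by label permutation.

    The null distribution of the maximum absolute voxelwise t over
    random group relabelings; the (1 - alpha) quantile is the corrected
    threshold.
    """
    data = np.concatenate([_stack(maps_a), _stack(maps_b)])
    na = len(maps_a)
    n = data.shape[0]
    flat = data.reshape(n, -1)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for j in range(n_perm):
        idx = rng.permutation(n)
        a, b = flat[idx[:na]], flat[idx[na:]]
        mean_d = a.mean(axis=0) - b.mean(axis=0)
        sp2 = ((na - 1) * a.var(axis=0, ddof=1)
               + (n - na - 1) * b.var(axis=0, ddof=1)) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_d / np.sqrt(sp2 * (1.0 / na + 1.0 / (n - na)))
        maxima[j] = np.nanmax(np.abs(t))
    return float(np.quantile(maxima, 1.0 - alpha))
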