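"""Voxel-wise group statistics and cluster-extent thresholding.

All maps are Student-t volumes: two-sample pooled-variance contrasts
(60-mmHg CRD vs 0-mmHg control within a treatment), the 2×2 WAS × CRD
interaction contrast against pooled within-cell variance, and seed
correlation maps (per-voxel Pearson r across animals against the seed
region's mean OD, converted to t with n−2 degrees of freedom).

Thresholding follows the uncorrected-voxel-p + cluster-extent convention:
one-sided p < .05 per direction, connected components (face adjacency by
default) grouped separately for activations and deactivations, and
components below the extent threshold discarded.  No random-field or
permutation correction is applied — by design.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats

from .errors import EmptyIntersectionError, SpecificationError
from .volume import BrainVolume

log = logging.getLogger(__name__)

#: nominal full-scale reconstruction grid (40-µm in-plane pixels over a
#: 16 × 12 mm coronal field, 57 sections) used to scale the 100-voxel
#: extent threshold down to desk-size grids
REFERENCE_FULLSCALE_GRID = (400, 57, 300)
REFERENCE_FULLSCALE_VOXELS = int(np.prod(REFERENCE_FULLSCALE_GRID))

#: the full-scale analysis smooths 3×3 voxels in-plane only, so its
#: 100-voxel extent criterion spans 100/9 smoothness resels
FULLSCALE_EXTENT_RESELS = 100.0 / 9.0

Subgroup = tuple[str, int]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StatMap:
    """A statistic volume (t values; NaN where undefined or outside mask)."""

    data: np.ndarray
    kind: str                  # "t" | "interaction_t" | "correlation_t"
    df: int
    contrast: str = ""
    mask: np.ndarray | None = None
    n_undefined: int = 0
    r_data: np.ndarray | None = None   # raw Pearson r for correlation maps

    def t_critical(self, voxel_p: float = 0.05, two_sided: bool = False
                   ) -> float:
        p = voxel_p / 2 if two_sided else voxel_p
        return float(stats.t.isf(p, self.df))


@dataclass(frozen=True)
class Cluster:
    """One suprathreshold connected component of consistent sign."""

    voxels: np.ndarray         # (k, 3) integer coordinates
    sign: int                  # +1 activation, −1 deactivation
    size: int
    peak_stat: float
    peak_ijk: tuple[int, int, int]

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class ClusterSet:
    """Signed suprathreshold clusters surviving the extent criterion."""

    clusters: list[Cluster]
    voxel_p: float
    extent: int
    df: int
    kind: str = "t"
    shape: tuple[int, ...] = ()

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def mask(self, sign: int | None = None) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for c in self.clusters:
            if sign is None or c.sign == sign:
                m |= c.mask(self.shape)
        return m


@dataclass
class SeedSeries:
    """Per-animal mean OD over the seed ROI."""

    values: np.ndarray
    animal_ids: list[str]
    subgroup: Subgroup | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.animal_ids):
            raise ValueError("one value per animal required")


def _stack(volumes: Sequence[BrainVolume | np.ndarray]) -> np.ndarray:
    arrays = [v.data if isinstance(v, BrainVolume) else np.asarray(v, float)
              for v in volumes]
    return np.stack(arrays, axis=0)


def _apply_mask(data: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is not None:
        data = np.where(mask, data, np.nan)
    return data


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def t_contrast(group_a: Sequence[BrainVolume | np.ndarray],
               group_b: Sequence[BrainVolume | np.ndarray],
               mask: np.ndarray | None = None,
               contrast: str = "A-B") -> StatMap:
    """Per-voxel pooled-variance two-sample t of group A minus group B.

    Positive t marks higher OD (activation) in A.  Voxels with zero pooled
    variance are undefined (NaN) and counted in ``n_undefined``.
    """
    a, b = _stack(group_a), _stack(group_b)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise SpecificationError("each group needs at least 2 volumes")
    if a.shape[1:] != b.shape[1:]:
        raise SpecificationError("groups must share a voxel grid")
    df = na + nb - 2
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.nan)
    t = _apply_mask(t, mask)
    n_undef = int(np.sum((se == 0) & (mask if mask is not None else True)))
    return StatMap(t, kind="t", df=df, contrast=contrast, mask=mask,
                   n_undefined=n_undef)


def factorial_interaction(cells: Mapping[Subgroup,
                                         Sequence[BrainVolume | np.ndarray]],
                          mask: np.ndarray | None = None) -> StatMap:
    """WAS × CRD interaction t-map of the between-subjects 2×2 design.

    The statistic is the cell-means contrast
    (WAS60 − WAS0) − (sham60 − sham0) over its standard error from pooled
    within-cell variance, with N − 4 degrees of freedom.  Positive t means
    the CRD response is larger under WAS than under sham.
    """
    keys = [("WAS", 60), ("WAS", 0), ("sham", 60), ("sham", 0)]
    try:
        groups = [_stack(cells[k]) for k in keys]
    except KeyError as exc:
        raise SpecificationError(f"empty/missing design cell {exc}") from exc
    if any(len(g) < 2 for g in groups):
        raise SpecificationError("every design cell needs ≥ 2 volumes")
    ns = [len(g) for g in groups]
    total_n = sum(ns)
    df = total_n - 4
    sse = sum((g.var(axis=0, ddof=1)) * (n - 1) for g, n in zip(groups, ns))
    mse = sse / df
    contrast = (groups[0].mean(axis=0) - groups[1].mean(axis=0)
                - groups[2].mean(axis=0) + groups[3].mean(axis=0))
    se = np.sqrt(mse * sum(1.0 / n for n in ns))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, contrast / se, np.nan)
    t = _apply_mask(t, mask)
    n_undef = int(np.sum((se == 0) & (mask if mask is not None else True)))
    return StatMap(t, kind="interaction_t", df=df,
                   contrast="(WAS60-WAS0)-(sham60-sham0)", mask=mask,
                   n_undefined=n_undef)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

_STRUCTURES = {6: ndi.generate_binary_structure(3, 1),
               18: ndi.generate_binary_structure(3, 2),
               26: ndi.generate_binary_structure(3, 3)}


def threshold_clusters(statmap: StatMap, voxel_p: float = 0.05,
                       extent: int = 100, connectivity: int = 6,
                       two_sided: bool = False) -> ClusterSet:
    """Group suprathreshold voxels into signed clusters and apply the
    extent criterion.

    Positive and negative excursions are labelled separately (never merged
    across the sign boundary); clusters smaller than ``extent`` voxels are
    dropped.  ``connectivity`` is the 3D neighbourhood (6 face / 18 edge /
    26 corner adjacency).
    """
    if extent < 1:
        raise ValueError("extent must be ≥ 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    tcrit = statmap.t_critical(voxel_p, two_sided)
    data = statmap.data
    clusters: list[Cluster] = []
    for sign in (+1, -1):
        supra = np.nan_to_num(sign * data, nan=-np.inf) >= tcrit
        labels, n = ndi.label(supra, structure=_STRUCTURES[connectivity])
        for lab in range(1, n + 1):
            voxels = np.argwhere(labels == lab)
            if len(voxels) < extent:
                continue
            vals = data[tuple(voxels.T)]
            peak = int(np.argmax(sign * vals))
            clusters.append(Cluster(
                voxels=voxels, sign=sign, size=len(voxels),
                peak_stat=float(vals[peak]),
                peak_ijk=tuple(int(x) for x in voxels[peak])))
    return ClusterSet(clusters, voxel_p=voxel_p, extent=extent,
                      df=statmap.df, kind=statmap.kind, shape=data.shape)


def scale_extent(grid_voxels: int,
                 smoothing_fwhm_vox: Sequence[float] | None = None,
                 extent_fullscale: int = 100,
                 reference_voxels: int = REFERENCE_FULLSCALE_VOXELS,
                 floor_unsmoothed: int = 5) -> int:
    """Scale the full-scale 100-voxel extent threshold to a small grid.

    The primary rule is proportional to grid volume; because that rounds to
    ~1 voxel on desk-size grids (where a 1-voxel extent no longer guards
    against isolated noise voxels), the result is floored.  For unsmoothed
    maps the floor is ``floor_unsmoothed`` voxels; for smoothed maps it is
    the voxel count spanning the same number of smoothness resels the
    full-scale criterion spans (100 voxels ≈ 11.1 resels of in-plane 3×3
    smoothing), so the extent guard keeps its statistical role.
    """
    proportional = extent_fullscale * grid_voxels / reference_voxels
    if smoothing_fwhm_vox is None:
        floor = floor_unsmoothed
    else:
        resel_vox = float(np.prod([max(f, 1.0) for f in smoothing_fwhm_vox]))
        floor = math.ceil(FULLSCALE_EXTENT_RESELS * resel_vox)
    extent = max(int(round(proportional)), floor, 1)
    log.info("extent threshold scaled: %d full-scale -> %d "
             "(grid %d vox, factor %.2e, floor %d)",
             extent_fullscale, extent, grid_voxels,
             grid_voxels / reference_voxels, floor)
    return extent


# ---------------------------------------------------------------------------
# seed series and correlation maps
# ---------------------------------------------------------------------------

def extract_seed_series(volumes: Sequence[BrainVolume],
                        roi: np.ndarray,
                        mask: np.ndarray | None = None) -> SeedSeries:
    """Arithmetic mean OD over the seed ROI, one value per animal."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise EmptyIntersectionError("seed ROI is empty")
    if mask is not None:
        outside = roi & ~np.asarray(mask, dtype=bool)
        if outside.any():
            where = np.argwhere(outside)[:5].tolist()
            raise SpecificationError(
                f"{int(outside.sum())} ROI voxels fall outside the mask, "
                f"e.g. {where}")
    subgroups = {v.subgroup for v in volumes}
    return SeedSeries(
        values=np.array([float(v.data[roi].mean()) for v in volumes]),
        animal_ids=[v.animal_id for v in volumes],
        subgroup=subgroups.pop() if len(subgroups) == 1 else None)


def define_seed_roi(region_mask: np.ndarray, activation: ClusterSet,
                    fallback_to_region: bool = False) -> np.ndarray:
    """Seed ROI = one hemisphere's atlas region ∩ its positive activation
    clusters.  An empty intersection raises unless the explicit fallback to
    the full region is enabled."""
    region_mask = np.asarray(region_mask, dtype=bool)
    roi = region_mask & activation.mask(sign=+1)
    if not roi.any():
        if fallback_to_region:
            warnings.warn("seed region shows no positive activation overlap; "
                          "falling back to the full atlas region",
                          stacklevel=2)
            return region_mask.copy()
        raise EmptyIntersectionError(
            "no overlap between the seed region and positive activation "
            "clusters; enable fallback_to_region to use the full region")
    return roi


def seed_correlation_map(volumes: Sequence[BrainVolume],
                         seed: SeedSeries,
                         mask: np.ndarray | None = None) -> StatMap:
    """Across-animal Pearson correlation of voxel OD with the seed values.

    The r volume is converted to t with n − 2 degrees of freedom for
    thresholding; the sign of r is retained.  Voxels with zero variance are
    undefined; a zero-variance seed is an error.
    """
    if len(volumes) < 3:
        raise SpecificationError("correlation needs at least 3 animals")
    if len(volumes) != len(seed.values):
        raise SpecificationError("one seed value per volume required")
    s = seed.values - seed.values.mean()
    ss = float((s ** 2).sum())
    if ss == 0:
        raise SpecificationError("seed series has zero variance")
    x = _stack(volumes)
    n = len(volumes)
    xc = x - x.mean(axis=0)
    num = np.tensordot(s, xc, axes=(0, 0))
    den = np.sqrt((xc ** 2).sum(axis=0) * ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, np.nan)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    t = _apply_mask(t, mask)
    r = _apply_mask(r, mask)
    n_undef = int(np.sum((den == 0) & (mask if mask is not None else True)))
    return StatMap(t, kind="correlation_t", df=df, contrast="seed r->t",
                   mask=mask, n_undefined=n_undef, r_data=r)


# ---------------------------------------------------------------------------
# atlas attribution
# ---------------------------------------------------------------------------

def clusters_to_regions(clusters: ClusterSet, atlas,
                        min_overlap_frac: float = 0.10) -> pd.DataFrame:
    """Attribute clusters to atlas regions by voxel overlap.

    One row per (cluster, region) pair whose overlap reaches
    ``min_overlap_frac`` of the smaller of the two voxel counts.  Cluster
    voxels on background labels are tallied and warned about, never
    silently dropped.
    """
    rows = []
    n_background = 0
    region_sizes = {name: atlas.region_size(name)
                    for name in atlas.region_names}
    labels_by_value = dict(zip(atlas.names["label"], atlas.names["name"]))
    for cid, cluster in enumerate(clusters):
        labs = atlas.labels[tuple(cluster.voxels.T)]
        counts = np.bincount(labs, minlength=int(atlas.names["label"].max())
                             + 1 if len(atlas.names) else 1)
        n_background += int(counts[0])
        for lab, count in enumerate(counts):
            if lab == 0 or count == 0:
                continue
            name = labels_by_value[lab]
            needed = max(1, int(math.ceil(
                min_overlap_frac * min(cluster.size, region_sizes[name]))))
            if count >= needed:
                rows.append({"cluster_id": cid, "region": name,
                             "sign": cluster.sign,
                             "overlap_voxels": int(count),
                             "cluster_size": cluster.size,
                             "region_size": region_sizes[name],
                             "peak_stat": cluster.peak_stat})
    if n_background:
        warnings.warn(f"{n_background} cluster voxels fall on background "
                      "labels", stacklevel=2)
    return pd.DataFrame(rows, columns=[
        "cluster_id", "region", "sign", "overlap_voxels", "cluster_size",
        "region_size", "peak_stat"])
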