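"""Iodine-removal efficacy and image noise measurement.

Two questions are answered here for every series of a paired study:

1. How much signal survives above the calcium detection threshold inside the
   whole-heart mask?  On a contrast CTA most blood-pool voxels exceed 130 HU;
   after effective iodine removal almost none should.  Quantified as the raw
   voxel fraction *strictly above* the threshold ("exceeding 130 HU"),
   independent of how the accompanying histogram is binned.  Note the scorer
   (:mod:`vncstudy.cascore`) uses the inclusive ``>= 130`` Agatston
   convention; the two differ only on exactly-130 voxels.

2. How noisy is the series?  Measured as the standard deviation of HU inside
   circular ROIs placed in the homogeneous left-ventricular cavity, copied
   unchanged to every registered series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume import CTVolume


@dataclass
class HistogramSummary:
    bin_edges: np.ndarray  # HU
    counts: np.ndarray     # voxels per bin; sums to n_total
    n_total: int
    proportion_above: float
    threshold: float
    series_id: str = ""

    def validate(self) -> None:
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("histogram counts must sum to the masked voxel count")
        if not (0.0 <= self.proportion_above <= 1.0):
            raise ValueError("proportion_above must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dict(series_id=self.series_id, n_total=self.n_total,
                    proportion_above=self.proportion_above, threshold=self.threshold,
                    bin_edges=self.bin_edges.tolist(), counts=self.counts.tolist())


@dataclass
class ROISpec:
    """A circular in-plane ROI: center in mm, diameter in mm, slice index."""

    center: tuple[float, float]
    diameter: float
    slice_index: int

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be > 0")


@dataclass
class NoiseResult:
    per_roi_sd: list[float]
    per_roi_mean: list[float]
    pooled_sd: float  # arithmetic mean of the per-ROI SDs
    series_id: str = ""


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _resample_grid(shape, spacing, target: float):
    """Output shape and query coordinates (index units) for isotropic resampling.

    The output spans the same physical extent (first to last voxel center).
    """
    n_out, coords = [], []
    for n, s in zip(shape, spacing):
        extent = (n - 1) * s
        m = int(np.floor(extent / target + 1e-9)) + 1
        n_out.append(m)
        coords.append(np.arange(m) * (target / s))
    return tuple(n_out), coords


def resample_isotropic(volume: CTVolume, target_mm: float = 1.0) -> CTVolume:
    """Resample a series to isotropic voxels by trilinear interpolation.

    Masks must go through :func:`resample_mask_isotropic` (nearest-neighbor)
    instead.  The already-isotropic identity case returns the grid unchanged.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    if volume.data.size == 0:
        raise ValueError("cannot resample an empty volume")
    shape, coords = _resample_grid(volume.shape, volume.spacing, target_mm)
    grid = np.meshgrid(*coords, indexing="ij")
    out = ndi.map_coordinates(volume.data, np.array(grid), order=1, mode="nearest")
    return volume.copy_with(
        data=out.astype(np.float32),
        spacing=(target_mm, target_mm, target_mm),
        slice_thickness=target_mm,
    )


def resample_mask_isotropic(mask: np.ndarray, spacing, target_mm: float = 1.0) -> np.ndarray:
    """Nearest-neighbor companion of :func:`resample_isotropic` for label maps."""
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    mask = np.asarray(mask)
    shape, coords = _resample_grid(mask.shape, spacing, target_mm)
    grid = np.meshgrid(*coords, indexing="ij")
    return ndi.map_coordinates(mask.astype(np.uint8), np.array(grid), order=0,
                               mode="nearest").astype(mask.dtype)


def resample_mask_to_grid(mask: np.ndarray, spacing, target_spacing,
                          target_shape) -> np.ndarray:
    """Nearest-neighbor resampling of a mask onto an arbitrary aligned grid
    (shared origin at the first voxel center)."""
    mask = np.asarray(mask)
    coords = [np.arange(m) * (t / s)
              for m, t, s in zip(target_shape, target_spacing, spacing)]
    grid = np.meshgrid(*coords, indexing="ij")
    return ndi.map_coordinates(mask.astype(np.uint8), np.array(grid), order=0,
                               mode="nearest").astype(mask.dtype)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def heart_histogram(volume: CTVolume, mask: np.ndarray, threshold: float = 130.0,
                    bin_width: float = 1.0,
                    hu_range: tuple[float, float] = (-200.0, 1500.0)) -> HistogramSummary:
    """Whole-heart HU histogram and the raw fraction of voxels above threshold.

    ``proportion_above`` uses strict ``>`` on the unbinned masked voxels, so
    it is invariant under any choice of ``bin_width``.  Values outside
    ``hu_range`` are clipped into the edge bins so counts cover every masked
    voxel.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError("mask is not aligned to the volume grid")
    if not mask.any():
        raise ValueError("empty mask")
    vals = volume.data[mask]
    proportion = float((vals > threshold).mean())
    edges = np.arange(hu_range[0], hu_range[1] + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(np.clip(vals, edges[0], edges[-1]), bins=edges)
    summary = HistogramSummary(
        bin_edges=edges, counts=counts, n_total=int(vals.size),
        proportion_above=proportion, threshold=float(threshold),
        series_id=volume.series_id)
    summary.validate()
    return summary


# ---------------------------------------------------------------------------
# noise ROIs
# ---------------------------------------------------------------------------

def place_lv_rois(lv_mask: np.ndarray, spacing, diameter_mm: float = 15.0,
                  n_rois: int = 3, seed: int = 0) -> list[ROISpec]:
    """Place circular ROIs fully inside the LV cavity on distinct slices.

    Slices nearest the LV centroid are preferred; within each slice the
    center is drawn (seeded) from the deepest pocket of the cavity, i.e.
    among positions whose in-plane distance-to-background is within half a
    voxel of the maximum.  Raises if the eroded cavity cannot host the
    requested diameter, reporting the largest feasible one.
    """
    lv_mask = np.asarray(lv_mask).astype(bool)
    if diameter_mm <= 0:
        raise ValueError("diameter must be > 0")
    if not lv_mask.any():
        raise ValueError("empty LV mask")
    sx, sy = float(spacing[0]), float(spacing[1])
    radius = diameter_mm / 2.0
    margin = 0.5 * max(sx, sy)
    rng = np.random.default_rng(seed)

    # per-slice in-plane distance to background, in mm
    dist = np.stack(
        [ndi.distance_transform_edt(lv_mask[:, :, k], sampling=(sx, sy))
         for k in range(lv_mask.shape[2])], axis=2)
    feasible = dist >= radius + margin
    feasible_slices = np.flatnonzero(feasible.any(axis=(0, 1)))
    if feasible_slices.size < n_rois:
        best = float(dist.max())
        raise ValueError(
            f"LV mask cannot host {n_rois} ROIs of diameter {diameter_mm} mm; "
            f"largest feasible diameter is {max(0.0, 2 * (best - margin)):.1f} mm"
        )
    centroid_z = ndi.center_of_mass(lv_mask)[2]
    order = feasible_slices[np.argsort(np.abs(feasible_slices - centroid_z),
                                       kind="stable")]
    rois = []
    for k in order[:n_rois]:
        d2 = dist[:, :, k]
        deepest = d2.max()
        ii, jj = np.nonzero(d2 >= deepest - 0.5 * max(sx, sy))
        pick = int(rng.integers(ii.size))
        rois.append(ROISpec(center=(ii[pick] * sx, jj[pick] * sy),
                            diameter=diameter_mm, slice_index=int(k)))
    return rois


def _roi_values(volume: CTVolume, roi: ROISpec) -> np.ndarray:
    nx, ny, nz = volume.shape
    if not (0 <= roi.slice_index < nz):
        raise ValueError(f"ROI slice {roi.slice_index} outside volume (nz={nz})")
    sx, sy = volume.spacing[0], volume.spacing[1]
    cx, cy = roi.center
    r = roi.diameter / 2.0
    if cx - r < -sx / 2 or cy - r < -sy / 2 or \
       cx + r > (nx - 0.5) * sx or cy + r > (ny - 0.5) * sy:
        raise ValueError("ROI circle extends outside the volume bounds")
    i0, i1 = int(np.floor((cx - r) / sx)), int(np.ceil((cx + r) / sx)) + 1
    j0, j1 = int(np.floor((cy - r) / sy)), int(np.ceil((cy + r) / sy)) + 1
    i0, j0 = max(i0, 0), max(j0, 0)
    ii = np.arange(i0, min(i1, nx))[:, None] * sx - cx
    jj = np.arange(j0, min(j1, ny))[None, :] * sy - cy
    inside = ii ** 2 + jj ** 2 <= r ** 2  # voxel-center membership
    patch = volume.data[i0:i0 + inside.shape[0], j0:j0 + inside.shape[1], roi.slice_index]
    return patch[inside]


def measure_noise(volume: CTVolume, rois: list[ROISpec]) -> NoiseResult:
    """SD of HU within each ROI; pooled noise = mean of the per-ROI SDs.

    The ROI list is defined once (on the contrast series) and reused verbatim
    across registered series, so every series samples the identical voxel
    index set.
    """
    sds, means = [], []
    for roi in rois:
        vals = _roi_values(volume, roi)
        if vals.size < 2:
            raise ValueError("ROI contains fewer than 2 voxels")
        sds.append(float(np.std(vals, ddof=1)))
        means.append(float(vals.mean()))
    return NoiseResult(per_roi_sd=sds, per_roi_mean=means,
                       pooled_sd=float(np.mean(sds)), series_id=volume.series_id)


def rois_to_json(rois: list[ROISpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([dict(center=list(r.center), diameter=r.diameter,
                        slice_index=r.slice_index) for r in rois], fh, indent=2)


def rois_from_json(path) -> list[ROISpec]:
    with open(path) as fh:
        return [ROISpec(center=tuple(d["center"]), diameter=d["diameter"],
                        slice_index=d["slice_index"]) for d in json.load(fh)]
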