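"""Agatston and volume calcium scoring with per-vessel assignment.

Classical Agatston scoring operates slice-wise: voxels at or above the
detection threshold (130 HU) are grouped into in-plane 8-connected lesions,
each lesion contributes its area (mm^2) times a density weight keyed to its
peak HU (1: 130-199, 2: 200-299, 3: 300-399, 4: >=400), and lesion scores
are summed over slices.  The definition assumes contiguous 3.0 mm slices;
for other reconstructions every slice is scored and the per-volume total is
multiplied by ``z_increment / 3.0`` so that overlapping or thin slices are
neither double- nor under-counted.  The calcium volume score is the number
of qualifying voxels times the voxel footprint times the increment (mm^3).

Lesions smaller than a minimum area (default 1 mm^2, the classical
minimum-lesion rule) are discarded.  The detection threshold is inclusive
(``>= 130``), the Agatston convention, in contrast to the strict ``>``
used for the iodine-removal histogram proportion in :mod:`vncstudy.imgchar`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume import CTVolume

#: Agatston density weight from lesion peak HU.
def agatston_weight(peak_hu: float) -> int:
    if peak_hu < 130:
        raise ValueError("peak below the detection threshold has no weight")
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


# in-plane 8-connectivity, no connections across slices
_SLICEWISE_STRUCT = np.zeros((3, 3, 3), dtype=bool)
_SLICEWISE_STRUCT[:, :, 1] = True


@dataclass
class Lesion:
    """One per-slice connected component of supra-threshold voxels."""

    slice_index: int
    voxel_coords: np.ndarray  # (n, 2) in-plane indices
    area: float               # mm^2 = voxel count x in-plane voxel area
    peak_hu: float
    peak_voxel: tuple[int, int]
    vessel: str | None = None

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]


@dataclass
class CalciumResult:
    """Agatston and volume scores, total and per vessel, for one series."""

    patient_id: str
    series_id: str
    agatston_total: float
    volume_total: float
    per_vessel: dict[str | None, tuple[float, float]]  # vessel -> (agatston, volume)
    n_lesions: int

    def validate(self) -> None:
        ag = sum(v[0] for v in self.per_vessel.values())
        vo = sum(v[1] for v in self.per_vessel.values())
        if not (np.isclose(ag, self.agatston_total) and np.isclose(vo, self.volume_total)):
            raise ValueError("totals must equal the sum over vessels plus unassigned")
        if self.agatston_total < 0 or self.volume_total < 0:
            raise ValueError("scores must be nonnegative")


def find_lesions(volume: CTVolume, threshold: float = 130.0,
                 min_area_mm2: float = 1.0,
                 exclusion_mask: np.ndarray | None = None) -> list[Lesion]:
    """Per-slice 8-connected components of voxels with HU >= threshold.

    Voxels under ``exclusion_mask`` never participate; components with area
    below ``min_area_mm2`` are discarded.  An empty result is valid.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    supra = volume.data >= threshold
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask).astype(bool)
        if exclusion_mask.shape != volume.shape:
            raise ValueError("exclusion mask is not aligned to the volume grid")
        supra &= ~exclusion_mask
    labels, n_lab = ndi.label(supra, structure=_SLICEWISE_STRUCT)
    if n_lab == 0:
        return []
    voxel_area = volume.spacing[0] * volume.spacing[1]
    # group the (sparse) supra-threshold voxels by label in one sort
    flat_idx = np.flatnonzero(supra)
    labs = labels.ravel()[flat_idx]
    vals = volume.data.ravel()[flat_idx]
    order = np.argsort(labs, kind="stable")
    bounds = np.searchsorted(labs[order], np.arange(1, n_lab + 2))
    ny, nz = volume.shape[1], volume.shape[2]
    lesions = []
    for lab in range(1, n_lab + 1):
        members = order[bounds[lab - 1]:bounds[lab]]
        if members.size * voxel_area < min_area_mm2:
            continue
        idxs = flat_idx[members]
        vv = vals[members]
        ii = (idxs // (ny * nz)).astype(np.intp)
        jj = ((idxs // nz) % ny).astype(np.intp)
        pk = int(np.argmax(vv))  # first maximum: deterministic tie-break
        lesions.append(Lesion(
            slice_index=int(idxs[0] % nz),
            voxel_coords=np.column_stack([ii, jj]),
            area=float(members.size * voxel_area),
            peak_hu=float(vv[pk]),
            peak_voxel=(int(ii[pk]), int(jj[pk])),
        ))
    return lesions


def _increment_factor(volume_meta: CTVolume) -> float:
    dz = volume_meta.spacing[2]
    if dz <= 0:
        raise ValueError("slice increment must be positive")
    return dz / 3.0


def agatston_score(lesions: list[Lesion], volume_meta: CTVolume) -> float:
    """Total Agatston score with thin-slice increment normalization.

    For a classical 3.0 mm / 3.0 mm series the factor is 1 and the score
    reduces to the textbook definition.
    """
    factor = _increment_factor(volume_meta)
    return float(sum(l.area * agatston_weight(l.peak_hu) for l in lesions) * factor)


def volume_score(volume: CTVolume, threshold: float = 130.0,
                 exclusion_mask: np.ndarray | None = None,
                 min_area_mm2: float = 1.0) -> float:
    """Calcium volume (mm^3): qualifying voxels x in-plane area x increment."""
    lesions = find_lesions(volume, threshold=threshold, min_area_mm2=min_area_mm2,
                           exclusion_mask=exclusion_mask)
    voxel_area = volume.spacing[0] * volume.spacing[1]
    dz = volume.spacing[2]
    if dz <= 0:
        raise ValueError("slice increment must be positive")
    return float(sum(l.n_voxels for l in lesions) * voxel_area * dz)


def assign_vessels(lesions: list[Lesion], vessel_mask: np.ndarray,
                   vessel_names: tuple[str, ...] = ("LM", "LAD", "CX", "RCA")) -> list[Lesion]:
    """Assign each lesion the territory label of the majority of its voxels.

    Ties are broken by the label under the lesion's peak-HU voxel.  Lesions
    whose majority voxels carry no label stay unassigned (``vessel=None``)
    but are retained in totals.
    """
    vessel_mask = np.asarray(vessel_mask)
    for lesion in lesions:
        labs = vessel_mask[lesion.voxel_coords[:, 0], lesion.voxel_coords[:, 1],
                           lesion.slice_index]
        counts = np.bincount(labs.astype(np.intp))
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            code = int(winners[0])
        else:  # tie: label under the peak voxel
            code = int(vessel_mask[lesion.peak_voxel[0], lesion.peak_voxel[1],
                                   lesion.slice_index])
        lesion.vessel = vessel_names[code - 1] if 1 <= code <= len(vessel_names) else None
    return lesions


def score_series(volume: CTVolume, vessel_mask: np.ndarray | None = None,
                 exclusion_mask: np.ndarray | None = None,
                 threshold: float = 130.0, min_area_mm2: float = 1.0,
                 patient_id: str = "P00") -> CalciumResult:
    """Full scoring of one series: lesions, vessel assignment, both scores."""
    lesions = find_lesions(volume, threshold=threshold, min_area_mm2=min_area_mm2,
                           exclusion_mask=exclusion_mask)
    if vessel_mask is not None:
        assign_vessels(lesions, vessel_mask)
    factor = _increment_factor(volume)
    voxel_vol = volume.spacing[0] * volume.spacing[1] * volume.spacing[2]
    per_vessel: dict[str | None, list[float]] = {}
    for l in lesions:
        acc = per_vessel.setdefault(l.vessel, [0.0, 0.0])
        acc[0] += l.area * agatston_weight(l.peak_hu) * factor
        acc[1] += l.n_voxels * voxel_vol
    result = CalciumResult(
        patient_id=patient_id, series_id=volume.series_id,
        agatston_total=float(sum(v[0] for v in per_vessel.values())),
        volume_total=float(sum(v[1] for v in per_vessel.values())),
        per_vessel={k: (v[0], v[1]) for k, v in per_vessel.items()},
        n_lesions=len(lesions),
    )
    result.validate()
    return result


def classify_agreement(tnc: CalciumResult, vnc: CalciumResult) -> str:
    """Score-zero agreement class between reference and derived series.

    ``false_pos``: reference score 0 but derived score > 0;
    ``false_neg``: reference score > 0 but derived score 0.
    """
    if tnc.patient_id != vnc.patient_id:
        raise ValueError(
            f"patient mismatch: {tnc.patient_id!r} vs {vnc.patient_id!r}")
    t, v = tnc.agatston_total > 0, vnc.agatston_total > 0
    if t and v:
        return "true_pos"
    if not t and not v:
        return "true_neg"
    if not t and v:
        return "false_pos"
    return "false_neg"
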