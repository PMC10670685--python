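"""Core CT volume container and NIfTI round-trip.

A :class:`CTVolume` is the universal currency of the pipeline: a 3D grid of
Hounsfield units indexed ``(x, y, z)`` with anisotropic voxel spacing.  The
z spacing is the *slice increment*; reconstructed slices may be thicker than
the increment (overlapping slices, e.g. the 3.0 mm / 1.5 mm non-contrast
reference series), which is why ``slice_thickness`` is carried separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

_SERIES_RE = re.compile(r"^(CTA|TNC|VNC_(Conv|PC)_[1-4])$")


def vnc_series_id(algorithm: str, setting: int) -> str:
    """Canonical series id, e.g. ``vnc_series_id("conv", 1) == "VNC_Conv_1"``."""
    alg = {"conv": "Conv", "pc": "PC"}.get(algorithm.lower())
    if alg is None:
        raise ValueError(f"unknown VNC algorithm {algorithm!r} (expected 'conv' or 'pc')")
    if setting not in (1, 2, 3, 4):
        raise ValueError(f"unknown reconstruction setting {setting!r} (expected 1..4)")
    return f"VNC_{alg}_{setting}"


@dataclass
class CTVolume:
    """A reconstructed CT series.

    Parameters
    ----------
    data
        3D array of CT numbers (HU), axis order ``(x, y, z)``; cast to float32.
    spacing
        Voxel size in mm: in-plane x/y and the slice increment along z.
    slice_thickness
        Reconstructed slice thickness in mm (>= z increment).
    series_id
        One of ``CTA``, ``TNC``, ``VNC_Conv_k``, ``VNC_PC_k`` (k = 1..4).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    slice_thickness: float
    series_id: str = "CTA"
    kernel_label: str = "Qr36"
    qir_level: str = "off"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.slice_thickness = float(self.slice_thickness)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume data must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if not (self.slice_thickness >= self.spacing[2] > 0):
            raise ValueError(
                f"slice_thickness ({self.slice_thickness}) must be >= z increment "
                f"({self.spacing[2]}) > 0"
            )
        if not _SERIES_RE.match(self.series_id):
            raise ValueError(f"invalid series_id {self.series_id!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU values outside [{HU_MIN}, {HU_MAX}]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical span between first and last voxel centers, per axis."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))

    def copy_with(self, data: np.ndarray, **kwargs) -> "CTVolume":
        params = dict(
            spacing=self.spacing,
            slice_thickness=self.slice_thickness,
            series_id=self.series_id,
            kernel_label=self.kernel_label,
            qir_level=self.qir_level,
        )
        params.update(kwargs)
        return CTVolume(data=data, **params)


def save_nifti(volume: CTVolume, path) -> None:
    """Write a volume as NIfTI-1 with spacing in the header.

    Slice thickness, series id, kernel and QIR level go into the free-text
    ``descrip`` field (NIfTI has no dedicated slot for overlapping slices).
    """
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms(volume.spacing)
    descrip = f"thk={volume.slice_thickness};sid={volume.series_id};" \
              f"k={volume.kernel_label};q={volume.qir_level}"
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path) -> CTVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = {}
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    for part in descrip.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            meta[k] = v
    return CTVolume(
        data=np.asanyarray(img.dataobj),
        spacing=spacing,
        slice_thickness=float(meta.get("thk", spacing[2])),
        series_id=meta.get("sid", "CTA"),
        kernel_label=meta.get("k", "Qr36"),
        qir_level=meta.get("q", "off"),
    )


def save_mask(mask: np.ndarray, spacing, path) -> None:
    """Write a binary or labeled mask as a NIfTI label map (uint8)."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(np.uint8)
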