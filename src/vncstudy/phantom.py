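"""Synthetic cardiac CT phantom with paired contrast / non-contrast series.

The generator emulates the statistical structure a paired-series calcium
quantification study relies on, without any projection physics:

* a contrast-enhanced CTA whose heart histogram is trimodal (LV blood pool >
  RV blood pool > myocardium),
* a true non-contrast (TNC) reference reconstructed at 3.0 mm slices with a
  1.5 mm increment,
* eight virtual non-contrast (VNC) series — conventional and
  calcium-preserving flavors at four reconstruction settings — derived from
  the same underlying material maps.

Everything is built from three additive basis maps (water-equivalent tissue,
iodine, calcium) on a fine base grid; each series is a slab-averaged,
re-incremented, noise-corrupted view of a sum of those maps.  The
conventional VNC algorithm removes iodine but also a configurable fraction
of the calcium signal; the calcium-preserving algorithm keeps calcium intact
but may introduce spurious supra-threshold specks.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .volume import HU_MAX, HU_MIN, CTVolume, save_mask, save_nifti, vnc_series_id

VESSELS = ("LM", "LAD", "CX", "RCA")


@dataclass(frozen=True)
class ReconSetting:
    kernel_label: str
    qir_level: str
    slice_thickness: float  # mm
    slice_increment: float  # mm


#: The four VNC reconstruction settings (kernel, QIR strength, thickness/increment).
RECON_SETTINGS: dict[int, ReconSetting] = {
    1: ReconSetting("Qr36", "Q4", 0.4, 0.2),
    2: ReconSetting("Br36", "Q4", 0.4, 0.2),
    3: ReconSetting("Qr36", "Q4", 1.0, 0.4),
    4: ReconSetting("Qr36", "Q3", 1.0, 0.4),
}
TNC_RECON = ReconSetting("Qr36", "off", 3.0, 1.5)
CTA_RECON = ReconSetting("Bv40", "Q4", 0.4, 0.2)

# RNG stream codes: series id -> stable integer used with the phantom seed.
_STREAM_CODES = {"CTA": 100, "TNC": 101}
_STREAM_CODES.update({vnc_series_id(a, s): 200 + 10 * i + s
                      for i, a in enumerate(("conv", "pc")) for s in (1, 2, 3, 4)})


@dataclass
class HULevels:
    """Compartment CT numbers (HU): unenhanced and contrast-enhanced values."""

    background: float = 40.0
    myocardium_tnc: float = 45.0
    myocardium_cta: float = 90.0
    rv_pool_tnc: float = 45.0
    rv_pool_cta: float = 250.0
    lv_pool_tnc: float = 45.0
    lv_pool_cta: float = 450.0

    def validate(self) -> None:
        if not (self.lv_pool_cta > self.rv_pool_cta > self.myocardium_cta):
            raise ValueError(
                "enhanced pool HU must be strictly ordered LV > RV > myocardium, got "
                f"LV={self.lv_pool_cta}, RV={self.rv_pool_cta}, myo={self.myocardium_cta}"
            )


def default_noise_sd() -> dict[str, float]:
    """Per-series Gaussian noise SD (HU).

    The 3.0 mm non-contrast reference sits at 26 HU; the thin-slice (0.4 mm)
    VNC settings 1-2 are slightly noisier and the 1.0 mm settings 3-4 slightly
    quieter, with the calcium-preserving flavor a few HU above the
    conventional one — reproducing the measured single-digit HU deltas.
    """
    sd = {"CTA": 15.0, "TNC": 26.0}
    for s in (1, 2):
        sd[vnc_series_id("conv", s)] = 29.0
        sd[vnc_series_id("pc", s)] = 32.0
    for s in (3, 4):
        sd[vnc_series_id("conv", s)] = 20.0
        sd[vnc_series_id("pc", s)] = 22.0
    return sd


@dataclass
class CalcificationSpec:
    """A spherical coronary calcification with known ground truth.

    ``center`` is in mm in the volume frame (voxel centers start at 0).
    ``peak_hu`` is the HU at the lesion core; the profile falls off linearly
    over a thin edge ramp to create partial-volume voxels.
    """

    center: tuple[float, float, float]
    radius: float
    peak_hu: float
    vessel: str

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        self.radius = float(self.radius)
        self.peak_hu = float(self.peak_hu)
        if self.radius <= 0:
            raise ValueError("calcification radius must be > 0")
        if self.peak_hu < 130:
            raise ValueError("calcification peak_hu must be >= 130 HU")
        if self.vessel not in VESSELS:
            raise ValueError(f"invalid vessel {self.vessel!r}, expected one of {VESSELS}")

    @property
    def true_volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient.

    ``grid_shape``/``base_spacing`` define the fine rasterization grid; the
    z step of the base grid doubles as the finest slice increment (0.2 mm).
    ``calcium_retention_conv`` is the fraction of the calcium HU excess the
    conventional VNC algorithm retains; ``pc_false_positive_rate`` is the
    expected Poisson count of spurious supra-threshold specks per
    calcium-preserving series.
    """

    grid_shape: tuple[int, int, int] = (192, 192, 240)
    base_spacing: tuple[float, float, float] = (0.5, 0.5, 0.2)
    hu_levels: HULevels = field(default_factory=HULevels)
    noise_sd: dict[str, float] = field(default_factory=default_noise_sd)
    calcium_retention_conv: float = 0.7
    pc_false_positive_rate: float = 1.0
    calcifications: list[CalcificationSpec] = field(default_factory=list)
    stent_vessel: str | None = None
    edge_mm: float | None = None  # lesion edge-ramp width; None -> min(base_spacing)
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 1 for n in self.grid_shape):
            raise ValueError("grid_shape must have three entries > 1")
        if any(s <= 0 for s in self.base_spacing):
            raise ValueError("base_spacing components must be > 0")
        self.hu_levels.validate()
        if not (0.0 <= self.calcium_retention_conv <= 1.0):
            raise ValueError("calcium_retention_conv must lie in [0, 1]")
        if self.pc_false_positive_rate < 0:
            raise ValueError("pc_false_positive_rate must be >= 0")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")
        if self.stent_vessel is not None and self.stent_vessel not in VESSELS:
            raise ValueError(f"invalid stent_vessel {self.stent_vessel!r}")

    @property
    def edge_width(self) -> float:
        return float(self.edge_mm) if self.edge_mm is not None else min(self.base_spacing)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["base_spacing"] = list(self.base_spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["grid_shape"] = tuple(d.get("grid_shape", (192, 192, 240)))
        d["base_spacing"] = tuple(d.get("base_spacing", (0.5, 0.5, 0.2)))
        if isinstance(d.get("hu_levels"), dict):
            d["hu_levels"] = HULevels(**d["hu_levels"])
        cals = d.get("calcifications") or []
        d["calcifications"] = [
            c if isinstance(c, CalcificationSpec) else CalcificationSpec(**c) for c in cals
        ]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PhantomGeometry:
    """Derived mm-frame geometry: cavities, myocardial shell, vessel boxes."""

    lv_center: np.ndarray
    lv_radius: float
    shell_thickness: float
    rv_center: np.ndarray
    rv_radius: float
    territories: dict[str, tuple[np.ndarray, np.ndarray]]  # vessel -> (lo, hi) mm

    @classmethod
    def from_spec(cls, spec: PhantomSpec) -> "PhantomGeometry":
        ext = np.array([(n - 1) * s for n, s in zip(spec.grid_shape, spec.base_spacing)])
        X, Y, Z = ext
        lv_r = float(min(0.17 * X, 0.17 * Y, 0.38 * Z))
        # thin myocardial shell, proportional to the cavity so the blood
        # pools dominate the heart mask at any phantom scale
        shell = 0.125 * lv_r
        rv_r = 0.8 * lv_r
        lv_c = np.array([0.40 * X, 0.50 * Y, 0.50 * Z])
        rv_c = np.array([lv_c[0] + lv_r + shell + rv_r + 1.0, 0.50 * Y, 0.50 * Z])
        # Four disjoint corner boxes, clear of the heart, one per coronary.
        m, w = 0.065 * min(X, Y), 0.145 * min(X, Y)
        zlo, zhi = 0.10 * Z, 0.90 * Z
        corners = {
            "LM": (m, m),
            "LAD": (m, Y - m - w),
            "CX": (X - m - w, m),
            "RCA": (X - m - w, Y - m - w),
        }
        territories = {
            v: (np.array([x0, y0, zlo]), np.array([x0 + w, y0 + w, zhi]))
            for v, (x0, y0) in corners.items()
        }
        return cls(lv_c, lv_r, shell, rv_c, rv_r, territories)

    def territory_of(self, point) -> str | None:
        p = np.asarray(point, dtype=float)
        hits = [v for v, (lo, hi) in self.territories.items()
                if np.all(p >= lo) and np.all(p <= hi)]
        if len(hits) > 1:  # boxes are disjoint by construction
            raise ValueError("territories overlap; geometry invalid")
        return hits[0] if hits else None


@dataclass
class BasisMaps:
    """Additive HU contributions: CTA = water + iodine + calcium."""

    water_equivalent: np.ndarray
    iodine: np.ndarray
    calcium: np.ndarray

    def validate(self) -> None:
        if not (self.water_equivalent.shape == self.iodine.shape == self.calcium.shape):
            raise ValueError("basis maps must share one shape")


@dataclass
class SeriesBundle:
    """All registered series, masks and ground truth for one synthetic patient."""

    patient_id: str
    spec: PhantomSpec
    geometry: PhantomGeometry
    basis: BasisMaps
    volumes: dict[str, CTVolume]
    heart_mask: np.ndarray
    lv_mask: np.ndarray
    vessel_mask: np.ndarray  # uint8 labels: 0 bg, 1..4 = LM/LAD/CX/RCA
    excluded_mask: np.ndarray
    ground_truth: pd.DataFrame
    # slab-resampled basis maps, keyed (map, thickness, increment); series that
    # share a reconstruction geometry share these
    slab_cache: dict = field(default_factory=dict, repr=False)

    @property
    def base_spacing(self) -> tuple[float, float, float]:
        return self.spec.base_spacing

    def resampled_basis(self, name: str, recon: "ReconSetting") -> np.ndarray:
        key = (name, recon.slice_thickness, recon.slice_increment)
        if key not in self.slab_cache:
            self.slab_cache[key] = resample_slab(
                getattr(self.basis, name), self.spec.base_spacing,
                recon.slice_thickness, recon.slice_increment)
        return self.slab_cache[key]


# ---------------------------------------------------------------------------
# rasterization helpers
# ---------------------------------------------------------------------------

def _axis_coords(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.base_spacing
    xs = (np.arange(nx, dtype=np.float32) * sx)[:, None, None]
    ys = (np.arange(ny, dtype=np.float32) * sy)[None, :, None]
    zs = (np.arange(nz, dtype=np.float32) * sz)[None, None, :]
    return xs, ys, zs


def _sphere_dist2(xs, ys, zs, center):
    cx, cy, cz = (np.float32(c) for c in center)
    d2_xy = (xs - cx) ** 2 + (ys - cy) ** 2  # (nx, ny, 1): one full-grid pass
    return d2_xy + (zs - cz) ** 2


def _add_sphere(data: np.ndarray, spacing, center, radius, excess, edge) -> None:
    """Add a hard sphere with a linear edge ramp of width ``edge`` (centered
    on the nominal radius) to ``data``, in-place, within a local window."""
    lo_idx = [max(0, int(np.floor((c - radius - edge) / s)))
              for c, s in zip(center, spacing)]
    hi_idx = [min(n, int(np.ceil((c + radius + edge) / s)) + 2)
              for c, s, n in zip(center, spacing, data.shape)]
    sub = tuple(slice(lo, hi) for lo, hi in zip(lo_idx, hi_idx))
    axes = []
    for ax, (lo, hi) in enumerate(zip(lo_idx, hi_idx)):
        coords = np.arange(lo, hi, dtype=np.float32) * spacing[ax] - center[ax]
        shape = [1, 1, 1]
        shape[ax] = hi - lo
        axes.append(coords.reshape(shape))
    d = np.sqrt(axes[0] ** 2 + axes[1] ** 2 + axes[2] ** 2)
    frac = np.clip((radius + edge / 2.0 - d) / edge, 0.0, 1.0)
    data[sub] += (excess * frac).astype(np.float32)


def rasterize_phantom(spec: PhantomSpec):
    """Build basis maps and masks on the base grid.

    Returns ``(basis, heart_mask, lv_mask, vessel_mask, excluded_mask)``.
    """
    geom = PhantomGeometry.from_spec(spec)
    hu = spec.hu_levels
    xs, ys, zs = _axis_coords(spec)

    d2_lv = _sphere_dist2(xs, ys, zs, geom.lv_center)
    d2_rv = _sphere_dist2(xs, ys, zs, geom.rv_center)
    lv = d2_lv <= geom.lv_radius ** 2
    shell = (d2_lv <= (geom.lv_radius + geom.shell_thickness) ** 2) & ~lv
    rv = (d2_rv <= geom.rv_radius ** 2) & ~lv & ~shell
    heart = lv | shell | rv

    water = np.full(spec.grid_shape, hu.background, dtype=np.float32)
    water[shell] = hu.myocardium_tnc
    water[rv] = hu.rv_pool_tnc
    water[lv] = hu.lv_pool_tnc

    iodine = np.zeros(spec.grid_shape, dtype=np.float32)
    iodine[shell] = hu.myocardium_cta - hu.myocardium_tnc
    iodine[rv] = hu.rv_pool_cta - hu.rv_pool_tnc
    iodine[lv] = hu.lv_pool_cta - hu.lv_pool_tnc

    vessel_mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    for code, v in enumerate(VESSELS, start=1):
        lo, hi = geom.territories[v]
        box = ((xs >= lo[0]) & (xs <= hi[0]) & (ys >= lo[1]) & (ys <= hi[1])
               & (zs >= lo[2]) & (zs <= hi[2]))
        vessel_mask[box] = code

    excluded = np.zeros(spec.grid_shape, dtype=bool)
    if spec.stent_vessel is not None:
        lo, hi = geom.territories[spec.stent_vessel]
        zmid = 0.5 * (lo[2] + hi[2])
        box = ((xs >= lo[0]) & (xs <= hi[0]) & (ys >= lo[1]) & (ys <= hi[1])
               & (zs >= zmid) & (zs <= hi[2]))
        excluded |= box

    calcium = np.zeros(spec.grid_shape, dtype=np.float32)
    edge = spec.edge_width
    for cal in spec.calcifications:
        _add_sphere(calcium, spec.base_spacing, cal.center, cal.radius,
                    cal.peak_hu - hu.background, edge)

    basis = BasisMaps(water_equivalent=water, iodine=iodine, calcium=calcium)
    return basis, heart, lv, vessel_mask, excluded


def _validate_calcifications(spec: PhantomSpec, geom: PhantomGeometry) -> None:
    ext = np.array([(n - 1) * s for n, s in zip(spec.grid_shape, spec.base_spacing)])
    edge = spec.edge_width
    cals = spec.calcifications
    for cal in cals:
        c = np.asarray(cal.center)
        r = cal.radius + edge
        if np.any(c - r < 0) or np.any(c + r > ext):
            raise ValueError(
                f"calcification at {cal.center} (radius {cal.radius} mm) extends "
                f"outside the grid extent {tuple(ext)}"
            )
        t = geom.territory_of(cal.center)
        if t is None:
            raise ValueError(
                f"calcification center {cal.center} lies in no vessel territory"
            )
        if t != cal.vessel:
            raise ValueError(
                f"calcification labeled {cal.vessel} but its center lies in the "
                f"{t} territory"
            )
    for i in range(len(cals)):
        for j in range(i + 1, len(cals)):
            d = math.dist(cals[i].center, cals[j].center)
            if d < cals[i].radius + cals[j].radius + edge:
                raise ValueError(
                    f"calcifications {i} and {j} overlap (centers {d:.2f} mm apart)"
                )


# ---------------------------------------------------------------------------
# series synthesis
# ---------------------------------------------------------------------------

def resample_slab(data: np.ndarray, base_spacing, thickness: float,
                  increment: float) -> np.ndarray:
    """Re-reconstruct a base-grid map at the given slice thickness/increment.

    Each output slice is the mean of the map over a slab of the requested
    thickness (sampled at the base z step, linearly interpolated), with slab
    centers spaced by the increment.  Linear, so it commutes with sums of
    basis maps.
    """
    from scipy import ndimage as ndi

    dz = base_spacing[2]
    nz = data.shape[2]
    zmax = (nz - 1) * dz
    n_out = int(np.floor(zmax / increment + 1e-6)) + 1
    z_out = np.arange(n_out) * increment
    n_sub = max(1, int(round(thickness / dz)))
    offsets = (np.arange(n_sub) + 0.5) / n_sub * thickness - thickness / 2.0

    stride = increment / dz
    m = int(round(stride))
    if abs(stride - m) < 1e-6 and m >= 1:
        # grid-aligned increments: the slab average is a fixed z kernel
        # (interpolated midpoint comb) followed by a stride — much cheaper
        # than per-slice gathers
        taps = int(np.ceil(offsets.max() / dz + 1e-9))
        kernel = np.zeros(2 * taps + 1, dtype=np.float32)
        for off in offsets:
            q = off / dz
            i0 = int(np.floor(q))
            w = q - i0
            kernel[i0 + taps] += 1.0 - w
            if w > 0:
                kernel[i0 + 1 + taps] += w
        kernel /= np.float32(n_sub)
        smoothed = ndi.correlate1d(data.astype(np.float32, copy=False), kernel,
                                   axis=2, mode="nearest")
        return np.ascontiguousarray(smoothed[:, :, :: m][:, :, :n_out])

    acc = np.zeros(data.shape[:2] + (n_out,), dtype=np.float32)
    for off in offsets:
        zq = np.clip((z_out + off) / dz, 0.0, nz - 1.0)
        i0 = np.floor(zq).astype(np.intp)
        i1 = np.minimum(i0 + 1, nz - 1)
        w = (zq - i0).astype(np.float32)
        acc += data[:, :, i0] * (1.0 - w) + data[:, :, i1] * w
    acc /= np.float32(n_sub)
    return acc


def _series_rng(spec: PhantomSpec, series_id: str, sub: int = 0) -> np.random.Generator:
    code = _STREAM_CODES[series_id]
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), code, sub]))


def _finalize(data: np.ndarray, spec: PhantomSpec, series_id: str,
              recon: ReconSetting) -> CTVolume:
    # `data` is always a freshly combined buffer; mutate in place
    sd = float(spec.noise_sd.get(series_id, 0.0))
    if sd > 0:
        rng = _series_rng(spec, series_id, sub=0)
        noise = rng.standard_normal(size=data.shape, dtype=np.float32)
        noise *= np.float32(sd)
        data += noise
    np.clip(data, HU_MIN, HU_MAX, out=data)
    return CTVolume(
        data=data,
        spacing=(spec.base_spacing[0], spec.base_spacing[1], recon.slice_increment),
        slice_thickness=recon.slice_thickness,
        series_id=series_id,
        kernel_label=recon.kernel_label,
        qir_level=recon.qir_level,
    )


def _insert_specks(data: np.ndarray, spacing, geom: PhantomGeometry,
                   rng: np.random.Generator, rate: float, background: float) -> int:
    """Add Poisson-count spurious supra-threshold specks in vessel territories."""
    count = int(rng.poisson(rate))
    for _ in range(count):
        vessel = VESSELS[int(rng.integers(len(VESSELS)))]
        lo, hi = geom.territories[vessel]
        r = float(rng.uniform(0.7, 1.2))
        peak = float(rng.uniform(160.0, 300.0))
        margin = r + 1.0
        center = tuple(float(rng.uniform(lo[k] + margin, hi[k] - margin)) for k in range(3))
        _add_sphere(data, spacing, center, r, peak - background, min(spacing))
    return count


def simulate_vnc(bundle: SeriesBundle, algorithm: str, setting: int,
                 spec: PhantomSpec | None = None) -> CTVolume:
    """Emulate iodine removal for one VNC flavor and reconstruction setting.

    ``conv``: iodine removed, calcium excess scaled by
    ``calcium_retention_conv``.  ``pc``: iodine removed, calcium preserved,
    plus Poisson-count spurious specks.  Iodine contribution is exactly zero
    before noise in both modes.
    """
    spec = spec if spec is not None else bundle.spec
    series_id = vnc_series_id(algorithm, setting)  # validates algorithm/setting
    recon = RECON_SETTINGS[setting]
    water = bundle.resampled_basis("water_equivalent", recon)
    calcium = bundle.resampled_basis("calcium", recon)
    if algorithm.lower() == "conv":
        data = water + np.float32(spec.calcium_retention_conv) * calcium
    else:
        data = water + calcium
    if algorithm.lower() == "pc" and spec.pc_false_positive_rate > 0:
        speck_rng = _series_rng(spec, series_id, sub=1)
        spacing = (spec.base_spacing[0], spec.base_spacing[1], recon.slice_increment)
        _insert_specks(data, spacing, bundle.geometry, speck_rng,
                       spec.pc_false_positive_rate, spec.hu_levels.background)
    return _finalize(data, spec, series_id, recon)


def generate_phantom(spec: PhantomSpec, patient_id: str = "P00") -> SeriesBundle:
    """Generate one synthetic patient: all series, masks and ground truth.

    Deterministic given ``spec.seed``.  Raises on invalid specs, lesions
    outside the grid or the labeled territory, and overlapping lesions.
    """
    spec.validate()
    geom = PhantomGeometry.from_spec(spec)
    _validate_calcifications(spec, geom)
    basis, heart, lv, vessel_mask, excluded = rasterize_phantom(spec)

    gt_rows = []
    for cal in spec.calcifications:
        in_excluded = False
        if spec.stent_vessel is not None and cal.vessel == spec.stent_vessel:
            lo, hi = geom.territories[spec.stent_vessel]
            in_excluded = cal.center[2] >= 0.5 * (lo[2] + hi[2])
        gt_rows.append(dict(
            patient_id=patient_id, vessel=cal.vessel,
            center_x_mm=cal.center[0], center_y_mm=cal.center[1],
            center_z_mm=cal.center[2], radius_mm=cal.radius,
            peak_hu=cal.peak_hu, true_volume_mm3=cal.true_volume_mm3,
            excluded=in_excluded,
        ))
    ground_truth = pd.DataFrame(
        gt_rows, columns=["patient_id", "vessel", "center_x_mm", "center_y_mm",
                          "center_z_mm", "radius_mm", "peak_hu",
                          "true_volume_mm3", "excluded"])

    volumes: dict[str, CTVolume] = {}
    bundle = SeriesBundle(
        patient_id=patient_id, spec=spec, geometry=geom, basis=basis,
        volumes=volumes, heart_mask=heart, lv_mask=lv,
        vessel_mask=vessel_mask, excluded_mask=excluded,
        ground_truth=ground_truth,
    )
    cta = (bundle.resampled_basis("water_equivalent", CTA_RECON)
           + bundle.resampled_basis("iodine", CTA_RECON)
           + bundle.resampled_basis("calcium", CTA_RECON))
    volumes["CTA"] = _finalize(cta, spec, "CTA", CTA_RECON)
    tnc = (bundle.resampled_basis("water_equivalent", TNC_RECON)
           + bundle.resampled_basis("calcium", TNC_RECON))
    volumes["TNC"] = _finalize(tnc, spec, "TNC", TNC_RECON)
    for algorithm in ("conv", "pc"):
        for setting in RECON_SETTINGS:
            sid = vnc_series_id(algorithm, setting)
            volumes[sid] = simulate_vnc(bundle, algorithm, setting, spec)
    return bundle


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def sample_cohort_specs(
    n_patients: int,
    template: PhantomSpec | None = None,
    seed: int = 0,
    zero_fraction: float = 0.15,
    stent_fraction: float = 0.25,
    lesion_count_range: tuple[int, int] = (2, 14),
    radius_log_median: float = 1.5,
    radius_log_sd: float = 0.45,
    radius_clip: tuple[float, float] = (0.8, 3.3),
    peak_range: tuple[float, float] = (160.0, 800.0),
    retention_sd: float = 0.15,
    retention_clip: tuple[float, float] = (0.35, 0.95),
) -> list[PhantomSpec]:
    """Sample per-patient phantom specs with randomized calcification burden.

    Burdens span zero to heavy: a ``zero_fraction`` of patients carry no
    calcium (mirroring score-zero patients), the rest draw a log-normal mix
    of lesion radii and uniform peak densities across the four vessels.

    The conventional algorithm's calcium retention varies from patient to
    patient (it depends on lesion composition and contrast timing in real
    reconstructions), so each patient's retention is drawn from a clipped
    normal around the template value with SD ``retention_sd``; this is what
    limits the predictive accuracy of the conventional flavor even after
    regression calibration.  Reproducible given ``seed``; cheap (no volumes
    are rasterized here).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    template = template if template is not None else PhantomSpec()
    template.validate()
    geom = PhantomGeometry.from_spec(template)
    edge = template.edge_width
    # largest lesion the territory boxes can host with placement margins
    lo0, hi0 = next(iter(geom.territories.values()))
    r_feasible = min(min(hi0[0] - lo0[0], hi0[1] - lo0[1]) / 2 - edge - 0.7,
                     (hi0[2] - lo0[2]) / 2 - 2.3)
    if r_feasible < radius_clip[0]:
        raise ValueError(
            f"vessel territories too small for lesions >= {radius_clip[0]} mm "
            f"(feasible maximum {r_feasible:.2f} mm); enlarge the grid")
    radius_clip = (radius_clip[0], min(radius_clip[1], r_feasible))
    specs = []
    children = np.random.SeedSequence(seed).spawn(n_patients)
    for child in children:
        rng = np.random.default_rng(child)
        pseed = int(rng.integers(0, 2 ** 31))
        retention = float(np.clip(
            rng.normal(template.calcium_retention_conv, retention_sd),
            *retention_clip))
        stent = (rng.random() < stent_fraction)
        stent_vessel = VESSELS[int(rng.integers(len(VESSELS)))] if stent else None
        cals: list[CalcificationSpec] = []
        if rng.random() >= zero_fraction:
            n_les = int(rng.integers(lesion_count_range[0], lesion_count_range[1] + 1))
            for _ in range(n_les):
                vessel = VESSELS[int(rng.integers(len(VESSELS)))]
                radius = float(np.clip(rng.lognormal(math.log(radius_log_median),
                                                     radius_log_sd), *radius_clip))
                peak = float(rng.uniform(*peak_range))
                lo, hi = geom.territories[vessel]
                margin_xy = radius + edge + 0.6
                margin_z = radius + 2.2  # room for 3 mm slab spread of the reference
                placed = None
                for _try in range(200):
                    c = (float(rng.uniform(lo[0] + margin_xy, hi[0] - margin_xy)),
                         float(rng.uniform(lo[1] + margin_xy, hi[1] - margin_xy)),
                         float(rng.uniform(lo[2] + margin_z, hi[2] - margin_z)))
                    ok = all(math.dist(c, o.center) >= radius + o.radius + edge
                             for o in cals if o.vessel == vessel)
                    if ok:
                        placed = c
                        break
                if placed is not None:
                    cals.append(CalcificationSpec(center=placed, radius=radius,
                                                  peak_hu=peak, vessel=vessel))
        specs.append(replace(template, calcifications=cals, seed=pseed,
                             stent_vessel=stent_vessel,
                             calcium_retention_conv=retention))
    return specs


def generate_cohort(n_patients: int, template: PhantomSpec | None = None,
                    seed: int = 0, **sampling_kwargs) -> list[SeriesBundle]:
    """Generate a cohort of synthetic patients (see :func:`sample_cohort_specs`).

    Note: bundles are memory-heavy at the default grid size; for large runs
    prefer iterating over :func:`sample_cohort_specs` and generating one
    patient at a time.
    """
    specs = sample_cohort_specs(n_patients, template, seed, **sampling_kwargs)
    return [generate_phantom(s, patient_id=f"P{i + 1:02d}")
            for i, s in enumerate(specs)]


def write_bundle(bundle: SeriesBundle, out_dir) -> None:
    """Write all series (NIfTI), masks (NIfTI label maps), ground truth (CSV)
    and the phantom spec (YAML) for one patient."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, vol in bundle.volumes.items():
        save_nifti(vol, out / f"{sid}.nii.gz")
    sp = bundle.base_spacing
    save_mask(bundle.heart_mask, sp, out / "heart_mask.nii.gz")
    save_mask(bundle.lv_mask, sp, out / "lv_mask.nii.gz")
    save_mask(bundle.vessel_mask, sp, out / "vessel_mask.nii.gz")
    save_mask(bundle.excluded_mask, sp, out / "excluded_mask.nii.gz")
    bundle.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    bundle.spec.to_yaml(out / "phantom_spec.yaml")
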