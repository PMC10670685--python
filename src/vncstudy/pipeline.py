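"""End-to-end study orchestration.

``run_study`` drives the whole paired-series evaluation: sample a synthetic
cohort, generate each patient's registered series, characterize the images
(whole-heart supra-threshold proportion, LV-ROI noise), quantify coronary
calcium on the non-contrast reference and on every virtual non-contrast
series, and compare the derived scores against the reference with paired
tests, correlations, sqrt-scale regression and the bootstrap
predictive-accuracy procedure.  Patients are processed one at a time so the
memory footprint stays at a single bundle.

Scoring emulates reader-guided lesion selection: only lesions inside the
coronary-territory mask (dilated by a small margin to cover slab spread)
participate, and stented territory segments plus everything distal are
excluded on every series alike.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import cascore, imgchar, stats
from .phantom import (RECON_SETTINGS, PhantomSpec, SeriesBundle, generate_phantom,
                      sample_cohort_specs, write_bundle, VESSELS)
from .volume import CTVolume, vnc_series_id

log = logging.getLogger("vncstudy")

#: Standard adult conversion coefficients, mSv per mGy*cm.
CHEST_COEFF = 0.017
ABDOMEN_COEFF = 0.015
PELVIS_COEFF = 0.019

VNC_SERIES = tuple(vnc_series_id(a, s) for a in ("conv", "pc") for s in (1, 2, 3, 4))
SCORED_SERIES = ("TNC",) + VNC_SERIES
ALL_SERIES = ("CTA",) + SCORED_SERIES


def cta_conversion_coefficient() -> float:
    """Angiography coefficient: mean of the chest, abdomen and pelvis values."""
    return float(np.mean([CHEST_COEFF, ABDOMEN_COEFF, PELVIS_COEFF]))


def effective_dose(dlp: float, coefficient: float) -> float:
    """Effective dose (mSv) = dose length product (mGy*cm) x coefficient."""
    if dlp < 0:
        raise ValueError("DLP must be >= 0")
    if coefficient <= 0:
        raise ValueError("conversion coefficient must be > 0")
    return float(dlp * coefficient)


@dataclass
class DoseRecord:
    scan_id: str
    dlp: float                     # mGy*cm
    ctdi_vol: float                # mGy (metadata only)
    conversion_coefficient: float  # mSv / (mGy*cm)

    @property
    def effective_dose(self) -> float:
        return effective_dose(self.dlp, self.conversion_coefficient)


@dataclass
class RunConfig:
    """Everything needed to reproduce a study run.

    The reconstruction-setting table itself lives in
    :data:`vncstudy.phantom.RECON_SETTINGS` (series -> kernel, QIR,
    thickness, increment); the phantom template carries the per-series noise
    levels.  Seeds for every stochastic stage derive from ``seed``.
    """

    n_patients: int = 20
    template: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0
    zero_fraction: float = 0.15
    stent_fraction: float = 0.25
    threshold_hu: float = 130.0
    min_area_mm2: float = 1.0
    iso_mm: float = 1.0
    roi_diameter_mm: float = 15.0
    n_rois: int = 3
    scoring_margin_mm: float = 2.0
    n_boot: int = 10_000
    alpha: float = 0.05
    nect_dlp_mgycm: float = 31.8
    cta_dlp_mgycm: float = 330.0
    nect_ctdi_mgy: float = 1.5
    cta_ctdi_mgy: float = 4.4
    save_volumes: bool = False

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        self.template.validate()
        for name in ("threshold_hu", "min_area_mm2", "iso_mm", "roi_diameter_mm",
                     "scoring_margin_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["template"] = self.template.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("template"), dict):
            d["template"] = PhantomSpec.from_dict(d["template"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StudyReport:
    config: RunConfig
    histograms: pd.DataFrame
    noise: pd.DataFrame
    scores: pd.DataFrame
    stats: pd.DataFrame
    mae_comparison: pd.DataFrame
    classification: pd.DataFrame
    classification_summary: pd.DataFrame
    dose: pd.DataFrame
    baseline: pd.DataFrame

    _TABLES = ("histograms", "noise", "scores", "stats", "mae_comparison",
               "classification", "classification_summary", "dose", "baseline")

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        for sub in ("scores", "stats", "report"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        locations = {
            "histograms": "report", "noise": "report", "scores": "scores",
            "stats": "stats", "mae_comparison": "stats",
            "classification": "stats", "classification_summary": "stats",
            "dose": "report", "baseline": "report",
        }
        for name in self._TABLES:
            getattr(self, name).to_csv(out / locations[name] / f"{name}.csv",
                                       index=False)
        cfg = self.config.to_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
            "seed": self.config.seed,
            "series": list(ALL_SERIES),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# per-patient helpers
# ---------------------------------------------------------------------------

def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def _boxes_on_grid(boxes, shape, spacing, margin: float = 0.0) -> np.ndarray:
    xs = (np.arange(shape[0]) * spacing[0])[:, None, None]
    ys = (np.arange(shape[1]) * spacing[1])[None, :, None]
    zs = (np.arange(shape[2]) * spacing[2])[None, None, :]
    out = np.zeros(shape, dtype=bool)
    for lo, hi in boxes:
        out |= ((xs >= lo[0] - margin) & (xs <= hi[0] + margin)
                & (ys >= lo[1] - margin) & (ys <= hi[1] + margin)
                & (zs >= lo[2] - margin) & (zs <= hi[2] + margin))
    return out


def _scoring_exclusion(bundle: SeriesBundle, volume: CTVolume,
                       margin: float) -> np.ndarray:
    """Everything outside the (dilated) coronary territories, plus the
    stented segment and all distal territory, on the series grid."""
    geom = bundle.geometry
    region = _boxes_on_grid(geom.territories.values(), volume.shape,
                            volume.spacing, margin=margin)
    exclusion = ~region
    if bundle.spec.stent_vessel is not None:
        lo, hi = geom.territories[bundle.spec.stent_vessel]
        zmid = 0.5 * (lo[2] + hi[2])
        stent_lo = np.array([lo[0], lo[1], zmid])
        exclusion |= _boxes_on_grid([(stent_lo, hi)], volume.shape,
                                    volume.spacing, margin=margin)
    return exclusion


def _mask_on_series_grid(mask: np.ndarray, base_spacing, volume: CTVolume) -> np.ndarray:
    """Nearest-neighbor transfer of a base-grid mask onto a series grid.

    Phantom series share the in-plane grid, so the common case reduces to
    nearest-slice indexing along z."""
    if (mask.shape[:2] == volume.shape[:2]
            and np.allclose(base_spacing[:2], volume.spacing[:2])):
        zi = np.clip(np.round(np.arange(volume.shape[2]) * volume.spacing[2]
                              / base_spacing[2]).astype(np.intp), 0, mask.shape[2] - 1)
        return mask[:, :, zi]
    return imgchar.resample_mask_to_grid(mask, base_spacing, volume.spacing,
                                         volume.shape)


def _characterize_patient(bundle: SeriesBundle, config: RunConfig,
                          roi_seed: int):
    """Iodine-removal histograms and ROI noise on the isotropic common frame."""
    sp = bundle.base_spacing
    heart_iso = imgchar.resample_mask_isotropic(bundle.heart_mask, sp, config.iso_mm)
    lv_iso = imgchar.resample_mask_isotropic(bundle.lv_mask, sp, config.iso_mm)
    # series extents differ by a fraction of a slice; register on the common
    # overlap of the isotropic grids
    def iso_shape(vol):
        return tuple(int(np.floor((n - 1) * s / config.iso_mm + 1e-9)) + 1
                     for n, s in zip(vol.shape, vol.spacing))

    common = tuple(min(iso_shape(bundle.volumes[sid])[ax] for sid in ALL_SERIES)
                   for ax in range(3))
    crop = tuple(slice(0, c) for c in common)
    heart_iso = heart_iso[crop]
    lv_iso = lv_iso[crop]
    rois = None
    hist_rows, noise_rows = [], []
    for sid in ALL_SERIES:
        iso = imgchar.resample_isotropic(bundle.volumes[sid], config.iso_mm)
        iso = iso.copy_with(data=iso.data[crop])
        if rois is None:  # placed on the contrast series, copied to the rest
            rois = imgchar.place_lv_rois(lv_iso, (config.iso_mm,) * 3,
                                         config.roi_diameter_mm, config.n_rois,
                                         seed=roi_seed)
        hist = imgchar.heart_histogram(iso, heart_iso, threshold=config.threshold_hu)
        hist_rows.append(dict(patient_id=bundle.patient_id, series_id=sid,
                              proportion_above=hist.proportion_above,
                              proportion_above_pct=100.0 * hist.proportion_above,
                              n_voxels=hist.n_total))
        noise = imgchar.measure_noise(iso, rois)
        noise_rows.append(dict(patient_id=bundle.patient_id, series_id=sid,
                               pooled_sd_hu=noise.pooled_sd,
                               roi1_sd=noise.per_roi_sd[0],
                               roi2_sd=noise.per_roi_sd[1],
                               roi3_sd=noise.per_roi_sd[2]))
    return hist_rows, noise_rows


def _score_patient(bundle: SeriesBundle, config: RunConfig):
    """Score the reference and every VNC series; tidy per-vessel rows."""
    rows, results = [], {}
    for sid in SCORED_SERIES:
        vol = bundle.volumes[sid]
        exclusion = _scoring_exclusion(bundle, vol, config.scoring_margin_mm)
        vessels = _mask_on_series_grid(bundle.vessel_mask, bundle.base_spacing, vol)
        res = cascore.score_series(
            vol, vessel_mask=vessels, exclusion_mask=exclusion,
            threshold=config.threshold_hu, min_area_mm2=config.min_area_mm2,
            patient_id=bundle.patient_id)
        results[sid] = res
        rows.append(dict(patient_id=bundle.patient_id, series_id=sid,
                         vessel="TOTAL", agatston=res.agatston_total,
                         volume_mm3=res.volume_total, n_lesions=res.n_lesions))
        for vessel in VESSELS + (None,):
            ag, vo = res.per_vessel.get(vessel, (0.0, 0.0))
            rows.append(dict(patient_id=bundle.patient_id, series_id=sid,
                             vessel=vessel or "unassigned", agatston=ag,
                             volume_mm3=vo, n_lesions=np.nan))
    return rows, results


# ---------------------------------------------------------------------------
# cohort-level statistics
# ---------------------------------------------------------------------------

def _pivot(scores: pd.DataFrame, metric: str, vessel_level: bool) -> pd.DataFrame:
    if vessel_level:
        sub = scores[scores.vessel.isin(VESSELS)]
        sub = sub.assign(key=sub.patient_id + ":" + sub.vessel)
    else:
        sub = scores[scores.vessel == "TOTAL"].assign(key=lambda d: d.patient_id)
    return sub.pivot_table(index="key", columns="series_id", values=metric,
                           fill_value=0.0)


def agreement_statistics(scores: pd.DataFrame, config: RunConfig):
    """Per-series agreement of derived vs reference calcium quantities.

    Returns ``(stats_df, mae_comparison_df)``.  Per-patient rows carry the
    paired test, correlations, sqrt-scale regression and bootstrap MAE;
    per-vessel rows (patient x vessel pairs pooled) carry correlations and
    regression.  The conventional-vs-calcium-preserving MAE comparison pairs
    bootstrap replicates by index (identical resample seeds per setting).
    """
    stat_rows, cmp_rows = [], []
    boot: dict[tuple[str, str], stats.BootstrapSummary] = {}
    for metric_code, metric in enumerate(("agatston", "volume_mm3")):
        wide_p = _pivot(scores, metric, vessel_level=False)
        wide_v = _pivot(scores, metric, vessel_level=True)
        for sid in VNC_SERIES:
            setting = int(sid[-1])
            y = wide_p["TNC"].to_numpy()
            x = wide_p[sid].to_numpy()
            row = dict(series_id=sid, metric=metric, level="per_patient",
                       n=len(x))
            try:
                test = stats.paired_difference_test(x, y, config.alpha)
                row.update(test_used=test.test_used, statistic=test.statistic,
                           p_value=test.p_value, normality_p=test.normality_p,
                           degenerate=test.degenerate)
            except ValueError:
                pass
            for meth in ("pearson", "spearman"):
                try:
                    row[meth] = stats.correlate(x, y, meth)
                except ValueError:
                    row[meth] = np.nan
            try:
                fit = stats.sqrt_regression(x, y)
                row.update(slope=fit.slope, intercept=fit.intercept,
                           r_squared=fit.r_squared)
                bseed = _derive_seed(config.seed, 500, setting, metric_code)
                bs = stats.bootstrap_mae(x, y, n_boot=config.n_boot, seed=bseed)
                boot[(sid, metric)] = bs
                row.update(mae_median=bs.mae_median, mae_q25=bs.mae_q25,
                           mae_q75=bs.mae_q75, n_boot=bs.n_boot,
                           bootstrap_seed=bs.seed)
            except ValueError:
                pass
            stat_rows.append(row)

            xv, yv = wide_v[sid].to_numpy(), wide_v["TNC"].to_numpy()
            vrow = dict(series_id=sid, metric=metric, level="per_vessel",
                        n=len(xv))
            for meth in ("pearson", "spearman"):
                try:
                    vrow[meth] = stats.correlate(xv, yv, meth)
                except ValueError:
                    vrow[meth] = np.nan
            try:
                fit = stats.sqrt_regression(xv, yv)
                vrow.update(slope=fit.slope, intercept=fit.intercept,
                            r_squared=fit.r_squared)
            except ValueError:
                pass
            stat_rows.append(vrow)

        for setting in RECON_SETTINGS:
            conv = boot.get((vnc_series_id("conv", setting), metric))
            pc = boot.get((vnc_series_id("pc", setting), metric))
            if conv is None or pc is None:
                continue
            # replicate-paired comparison: identical resample indices by seed
            w = sps.wilcoxon(conv.maes, pc.maes, zero_method="wilcox")
            cmp_rows.append(dict(
                setting=setting, metric=metric,
                mae_median_conv=conv.mae_median, mae_median_pc=pc.mae_median,
                mae_iqr_conv=f"{conv.mae_q25:.1f}-{conv.mae_q75:.1f}",
                mae_iqr_pc=f"{pc.mae_q25:.1f}-{pc.mae_q75:.1f}",
                wilcoxon_p=float(w.pvalue),
                pc_smaller=bool(pc.mae_median < conv.mae_median)))
    return pd.DataFrame(stat_rows), pd.DataFrame(cmp_rows)


def dose_table(config: RunConfig) -> pd.DataFrame:
    records = [
        DoseRecord("NECT", config.nect_dlp_mgycm, config.nect_ctdi_mgy, CHEST_COEFF),
        DoseRecord("CTA", config.cta_dlp_mgycm, config.cta_ctdi_mgy,
                   cta_conversion_coefficient()),
    ]
    return pd.DataFrame([dict(scan_id=r.scan_id, dlp_mgycm=r.dlp,
                              ctdi_vol_mgy=r.ctdi_vol,
                              conversion_coefficient=r.conversion_coefficient,
                              effective_dose_msv=r.effective_dose)
                         for r in records])


# ---------------------------------------------------------------------------
# baseline-style summaries
# ---------------------------------------------------------------------------

def format_count(k: int, n: int) -> str:
    """Proportion formatting, e.g. ``format_count(22, 38) == '22/38 (57.9%)'``."""
    if n <= 0 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n with n > 0")
    return f"{k}/{n} ({100.0 * k / n:.1f}%)"


def summarize_cohort(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Baseline-style variable summaries.

    Binary variables are shown as ``k/n (percent)``.  Continuous variables go
    through a Shapiro-Wilk gate: normal-looking ones as ``mean +/- SD``,
    otherwise as ``median (IQR)``.  Constant variables take the mean path
    with SD 0.
    """
    if df.empty:
        raise ValueError("nonempty results required")
    rows = []
    for col in df.columns:
        s = df[col]
        vals = s.dropna()
        uniq = set(np.unique(vals.to_numpy()).tolist())
        if s.dtype == bool or uniq <= {0, 1, True, False}:
            k = int(np.asarray(vals, dtype=float).sum())
            rows.append(dict(variable=col, summary=format_count(k, len(vals)),
                             rule="count"))
            continue
        if not np.issubdtype(np.asarray(vals).dtype, np.number):
            continue
        x = vals.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            normal = True
        else:
            normal = float(sps.shapiro(x).pvalue) > alpha
        if normal:
            summary = f"{x.mean():.1f} ± {x.std(ddof=1) if x.size > 1 else 0.0:.1f}"
            rule = "mean_sd"
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            summary = f"{med:.1f} ({q1:.1f}–{q3:.1f})"
            rule = "median_iqr"
        rows.append(dict(variable=col, summary=summary, rule=rule))
    return pd.DataFrame(rows)


def _cohort_baseline(gt_frames: list[pd.DataFrame],
                     specs: list[PhantomSpec]) -> pd.DataFrame:
    per_patient = []
    for gt, spec in zip(gt_frames, specs):
        per_patient.append(dict(
            n_lesions=len(gt),
            true_volume_mm3=float(gt.true_volume_mm3.sum()) if len(gt) else 0.0,
            zero_calcium=len(gt) == 0,
            stented=spec.stent_vessel is not None,
        ))
    return summarize_cohort(pd.DataFrame(per_patient))


# ---------------------------------------------------------------------------
# stage drivers (single-stage runs for the analysis scripts)
# ---------------------------------------------------------------------------

def _iterate_patients(config: RunConfig):
    specs = sample_cohort_specs(
        config.n_patients, config.template, seed=_derive_seed(config.seed, 1),
        zero_fraction=config.zero_fraction, stent_fraction=config.stent_fraction)
    for i, spec in enumerate(specs):
        yield i, spec, generate_phantom(spec, patient_id=f"P{i + 1:02d}")


def characterize_study(config: RunConfig):
    """Run only the image-characterization stage over a fresh cohort.

    Returns ``(histograms, noise)`` with rows identical to what
    :func:`run_study` would report for the same config.
    """
    config.validate()
    hist_rows, noise_rows = [], []
    for i, spec, bundle in _iterate_patients(config):
        h, nz = _characterize_patient(bundle, config,
                                      roi_seed=_derive_seed(config.seed, 2, i))
        hist_rows += h
        noise_rows += nz
        log.info("characterized %s", bundle.patient_id)
    return pd.DataFrame(hist_rows), pd.DataFrame(noise_rows)


def score_study(config: RunConfig):
    """Run only the calcium-scoring stage over a fresh cohort.

    Returns ``(scores, classification)`` with rows identical to what
    :func:`run_study` would report for the same config.
    """
    config.validate()
    score_rows, class_rows = [], []
    for i, spec, bundle in _iterate_patients(config):
        rows, results = _score_patient(bundle, config)
        score_rows += rows
        for sid in VNC_SERIES:
            class_rows.append(dict(
                patient_id=bundle.patient_id, series_id=sid,
                agreement=cascore.classify_agreement(results["TNC"], results[sid]),
                tnc_agatston=results["TNC"].agatston_total,
                vnc_agatston=results[sid].agatston_total))
        log.info("scored %s", bundle.patient_id)
    return pd.DataFrame(score_rows), pd.DataFrame(class_rows)


# ---------------------------------------------------------------------------
# the study driver
# ---------------------------------------------------------------------------

def run_study(config: RunConfig, out_dir=None) -> StudyReport:
    """Run the full study; optionally write all tables under ``out_dir``.

    Fully reproducible from ``config`` (every stochastic stage derives its
    seed from ``config.seed``); identical configs give byte-identical CSVs.
    """
    config.validate()
    specs = sample_cohort_specs(
        config.n_patients, config.template, seed=_derive_seed(config.seed, 1),
        zero_fraction=config.zero_fraction, stent_fraction=config.stent_fraction)
    hist_rows, noise_rows, score_rows, class_rows = [], [], [], []
    gt_frames = []
    for i, spec in enumerate(specs):
        pid = f"P{i + 1:02d}"
        stage = "phantom"
        try:
            t0 = time.perf_counter()
            bundle = generate_phantom(spec, patient_id=pid)
            gt_frames.append(bundle.ground_truth)
            if config.save_volumes and out_dir is not None:
                write_bundle(bundle, Path(out_dir) / "volumes" / pid)
            stage = "imgchar"
            h, nz = _characterize_patient(bundle, config,
                                          roi_seed=_derive_seed(config.seed, 2, i))
            hist_rows += h
            noise_rows += nz
            stage = "cascore"
            rows, results = _score_patient(bundle, config)
            score_rows += rows
            for sid in VNC_SERIES:
                class_rows.append(dict(
                    patient_id=pid, series_id=sid,
                    agreement=cascore.classify_agreement(results["TNC"],
                                                         results[sid]),
                    tnc_agatston=results["TNC"].agatston_total,
                    vnc_agatston=results[sid].agatston_total))
            log.info("patient %s done in %.1f s", pid, time.perf_counter() - t0)
            del bundle
        except Exception as err:
            raise RuntimeError(
                f"stage {stage!r} failed for patient {pid}: {err}") from err

    scores = pd.DataFrame(score_rows)
    stage = "stats"
    try:
        stats_df, mae_cmp = agreement_statistics(scores, config)
    except Exception as err:
        raise RuntimeError(f"stage 'stats' failed: {err}") from err
    classification = pd.DataFrame(class_rows)
    class_summary = (classification.groupby(["series_id", "agreement"])
                     .size().rename("count").reset_index())
    report = StudyReport(
        config=config,
        histograms=pd.DataFrame(hist_rows),
        noise=pd.DataFrame(noise_rows),
        scores=scores,
        stats=stats_df,
        mae_comparison=mae_cmp,
        classification=classification,
        classification_summary=class_summary,
        dose=dose_table(config),
        baseline=_cohort_baseline(gt_frames, specs),
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
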