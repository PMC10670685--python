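#!/usr/bin/env python
"""Define the synthetic cohort: per-patient calcification ground truth.

Samples the study cohort (default: 20 patients) from the default phantom
template — randomized lesion burden across the four coronary territories,
a fraction of calcium-free patients, a fraction with a stented (excluded)
segment, and per-patient calcium retention of the conventional VNC
algorithm — and writes the ground-truth lesion table plus a baseline-style
cohort summary.  No volumes are rasterized here; this is the cheap,
reproducible definition every later stage regenerates from the same seed.
"""

import pandas as pd

import vncstudy as v
from vncstudy.pipeline import _cohort_baseline, _derive_seed

from _common import default_config, study_args


def main() -> int:
    args = study_args(__doc__)
    config = default_config(args)
    specs = v.sample_cohort_specs(
        config.n_patients, config.template, seed=_derive_seed(config.seed, 1),
        zero_fraction=config.zero_fraction, stent_fraction=config.stent_fraction)

    gt_frames = []
    for i, spec in enumerate(specs):
        pid = f"P{i + 1:02d}"
        rows = [dict(patient_id=pid, vessel=c.vessel,
                     center_x_mm=c.center[0], center_y_mm=c.center[1],
                     center_z_mm=c.center[2], radius_mm=c.radius,
                     peak_hu=c.peak_hu, true_volume_mm3=c.true_volume_mm3,
                     retention_conv=spec.calcium_retention_conv,
                     stent_vessel=spec.stent_vessel or "")
                for c in spec.calcifications]
        gt_frames.append(pd.DataFrame(rows, columns=[
            "patient_id", "vessel", "center_x_mm", "center_y_mm", "center_z_mm",
            "radius_mm", "peak_hu", "true_volume_mm3", "retention_conv",
            "stent_vessel"]))
    ground_truth = pd.concat([f for f in gt_frames if len(f)] or gt_frames,
                             ignore_index=True)
    ground_truth.to_csv(args.out / "ground_truth.csv", index=False)

    baseline = _cohort_baseline(gt_frames, specs)
    baseline.to_csv(args.out / "baseline.csv", index=False)

    n_zero = sum(len(f) == 0 for f in gt_frames)
    totals = [f.true_volume_mm3.sum() for f in gt_frames]
    print(f"cohort of {len(specs)} patients, seed {args.seed}")
    print(f"  calcium-free patients: {v.format_count(n_zero, len(specs))}")
    print(f"  true calcium volume per patient: median "
          f"{pd.Series(totals).median():.0f} mm^3, max {max(totals):.0f} mm^3")
    print(f"  tables: {args.out/'ground_truth.csv'}, {args.out/'baseline.csv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
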