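#!/usr/bin/env python
"""Effective-dose arithmetic for the paired acquisition protocol.

Converts the dose-length products of the dedicated non-contrast scan and
the CT angiography into effective doses with the standard adult conversion
coefficients (chest 0.017; angiography: mean of chest/abdomen/pelvis =
0.017 mSv per mGy*cm).  Pure metadata arithmetic — no simulation.
"""

import vncstudy as v
from vncstudy.pipeline import dose_table

from _common import default_config, study_args


def main() -> int:
    args = study_args(__doc__)
    df = dose_table(default_config(args))
    df.to_csv(args.out / "dose.csv", index=False)
    for _, row in df.iterrows():
        print(f"{row.scan_id:5s} DLP {row.dlp_mgycm:6.1f} mGy*cm x "
              f"{row.conversion_coefficient:.3f} = "
              f"{row.effective_dose_msv:5.2f} mSv")
    print(f"table: {args.out/'dose.csv'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
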