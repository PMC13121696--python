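#!/usr/bin/env python
"""Fit every iohexol concentration–time series and tabulate measured GFR.

Each injection is fitted independently to the two-compartment model with
one-compartment fallback; GFR = dose / AUC.  Writes results/gfr_fits.csv
and prints per-group mean GFR at each injection time (the 1, 19 and 43 h
injections measure GFR at roughly 6, 24 and 48 h of the protocol).
"""

from pathlib import Path

from crushkit.config import EffectConfig, StudyConfig
from crushkit.pipeline import gfr_table, write_frame
from crushkit.synthetic_cohort import generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cohort = generate_cohort(StudyConfig(seed=SEED), EffectConfig())
    df = gfr_table(cohort)
    write_frame(df, OUT / "gfr_fits.csv")
    print(f"fitted {len(df)} series; fallback used in {int(df.fallback_used.sum())}")
    summary = (
        df.groupby(["group", "injection_time_h"]).gfr_ml_min.agg(["mean", "std"]).round(1)
    )
    print(summary)
    print(f"wrote {OUT / 'gfr_fits.csv'}")


if __name__ == "__main__":
    main()
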