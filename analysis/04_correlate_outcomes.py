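#!/usr/bin/env python
"""Correlate fitted growth constants with outcomes across the cohort.

Reads the per-subject fits of analysis/02_tune_validate.py, assembles
the correlation variables (lifespan, fitted T_theta and T_s, the driving
ratio T_theta / sigma_theta_bar), computes the Bonferroni-corrected
Pearson map and Tobit censored regressions of lifespan, and also reports
the correlation map of the packaged 10-animal reference table.  Writes
results/correlation/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from vesselgrow.outcome_statistics import (
    load_cohort_table,
    mz_pseudo_r2,
    pearson_map,
    records_to_frame,
    tobit_fit,
)
from vesselgrow.pipeline import run_correlation

parser = argparse.ArgumentParser()
parser.add_argument("--fits", type=Path,
                    default=Path("results/tuning_validation.csv"))
parser.add_argument("--out", type=Path, default=Path("results/correlation"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)

# --- synthetic cohort with per-subject fitted constants -------------------
fits = pd.read_csv(args.fits)
frame = pd.DataFrame({
    "lifespan": fits.lifespan_months,
    "T_theta": fits.T_theta_fit,
    "T_s": fits.T_s_fit,
    "T_theta_over_sigma": fits.T_theta_fit / (fits.sigma_theta_bar_Pa / 1e3),
})
cmap, tobit = run_correlation(frame, variables=list(frame.columns))
cmap.to_frame().to_csv(args.out / "synthetic_correlation_map.csv")
pd.DataFrame(cmap.p, index=cmap.variables, columns=cmap.variables).to_csv(
    args.out / "synthetic_correlation_p.csv")

print("synthetic cohort (fitted constants vs lifespan):")
for name, (fit, r2) in tobit.items():
    i = cmap.variables.index("lifespan")
    j = cmap.variables.index(name)
    print(f"  {name}: Pearson r = {cmap.r[i, j]:+.2f}, "
          f"Tobit slope = {fit.beta[1]:+.3f} "
          f"(pseudo-R^2 = {r2:.2f}, {fit.n_censored} censored)")
summary = {name: {"beta": fit.beta.tolist(), "sigma": fit.sigma,
                  "pseudo_r2": r2, "n_censored": fit.n_censored}
           for name, (fit, r2) in tobit.items()}
(args.out / "synthetic_tobit.json").write_text(json.dumps(summary, indent=2))

# --- packaged reference table --------------------------------------------
ref = records_to_frame(load_cohort_table())
ref_vars = ["lifespan", "ATI", "E_asc", "E_desc"]
ref_map = pearson_map(ref, ref_vars)
ref_map.to_frame().to_csv(args.out / "reference_correlation_map.csv")
fit = tobit_fit(ref[["E_asc"]].to_numpy(), ref["lifespan"].to_numpy())
r2 = mz_pseudo_r2(fit, ref[["E_asc"]].to_numpy())
print(f"\nreference table ({len(ref)} animals, "
      f"{int(ref.censored.sum())} censored):")
i = ref_map.variables.index("lifespan")
for v in ref_vars[1:]:
    j = ref_map.variables.index(v)
    star = "*" if ref_map.significant[i, j] else ""
    print(f"  lifespan vs {v}: r = {ref_map.r[i, j]:+.2f}"
          f" (raw p = {ref_map.p[i, j]:.2f}){star}")
print(f"  Tobit lifespan ~ E_asc: slope {fit.beta[1]:+.4f}, "
      f"pseudo-R^2 = {r2:.2f}")
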