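#!/usr/bin/env python
"""Behavioral bias analysis: ve/vae, mixed bias models, temporal dynamics.

Reads the simulated cohort trial tables from results/ (run
01_simulate_cohort.py first), computes the trial-wise ventriloquism effect
and aftereffect, fits the three mixed bias models, compares the aftereffect
models by BIC, tests each discrepancy level against zero, and writes the
binned bias time courses that show the LT buildup and the flat ST course.
"""

import json
import pathlib

import pandas as pd

from ventrilab.behavior import (bin_bias_timecourse, compare_models,
                                compute_ve, compute_vae, fit_bias_glmm,
                                per_dva_tests)

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
trials = pd.concat([pd.read_csv(RESULTS / f"trials_{p}.tsv", sep="\t")
                    for p in ("LT", "ST")], ignore_index=True)

ve = compute_ve(trials)
vae = compute_vae(trials)
ve.to_csv(RESULTS / "bias_ve.tsv", sep="\t", index=False)
vae.to_csv(RESULTS / "bias_vae.tsv", sep="\t", index=False)

fits = {}
for bias, model in ((ve, "eq1-ve"), (vae, "eq1-vae"), (vae, "eq2-vae")):
    fit = fit_bias_glmm(bias, model)
    fits[model] = fit
    print(f"{model}: BIC={fit.bic:,.0f}  "
          + "  ".join(f"{t}={r.estimate:+.3f}" for t, r in fit.coef.iterrows()))
dbic = compare_models(fits["eq1-vae"], fits["eq2-vae"])
print(f"ΔBIC (aftereffect model without vs with previous response) = {dbic:.1f} "
      f"-> the carryover term {'improves' if dbic > 0 else 'does not improve'} the fit")

(RESULTS / "bias_model_fits.json").write_text(json.dumps(
    {m: f.to_dict() for m, f in fits.items()} | {"delta_bic_eq1_eq2": dbic},
    indent=2, default=float))

for label, bias in (("ve", ve), ("vae", vae)):
    tests = per_dva_tests(bias, value=label)
    sig = int(tests.significant.sum())
    print(f"{label}: {sig}/6 discrepancy levels differ from zero "
          f"(signed-rank, Holm-corrected)")
    tests.to_csv(RESULTS / f"per_dva_tests_{label}.tsv", sep="\t", index=False)

rows = []
for paradigm in ("LT", "ST"):
    tc = bin_bias_timecourse(vae, paradigm, seed=1)
    tc["paradigm"] = paradigm
    rows.append(tc)
    drift = tc["mean"].iloc[-6:].mean() - tc["mean"].iloc[:6].mean()
    print(f"{paradigm}: binned vae drift (last-first 6 bins) = {drift:+.2f} deg")
pd.concat(rows).to_csv(RESULTS / "vae_timecourse.tsv", sep="\t", index=False)
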