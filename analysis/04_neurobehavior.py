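#!/usr/bin/env python
"""Neurobehavioral models: which decoded representations predict the bias.

Simulates a cohort with an active neural→behavior coupling on the
discrepancy representation, then asks (1) whether the decoded ΔVA (and, as
control, the decoded response) in the AV trial predicts the next trial's
aftereffect within each paradigm, (2) whether this transfers across
paradigms (conjunction of both cross-directions), and (3) whether the
A-trial sound representation is shifted by the preceding discrepancy.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from ventrilab.cluster_stats import cluster_test, conjunction_cluster_test
from ventrilab.decoding import WindowGrid
from ventrilab.neurobehavior import (conjunction, link_cross,
                                     link_sound_encoding, link_within)
from ventrilab.simulate import SimulationParams, simulate_subject

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

N_SUBJECTS = 10
params = SimulationParams(seed=1, n_channels=32, snr=1.5, coupling=0.3,
                          sound_bias=0.3)
cohort = {p: [simulate_subject(p, params, s) for s in range(N_SUBJECTS)]
          for p in ("LT", "ST")}
grid = WindowGrid.from_times(cohort["LT"][0].epochs.times, params.fs)


def report(name, result, cr):
    sig = cr.significant(0.01)
    ranges = ", ".join(f"{grid.centers[c.start]*1e3:.0f}-{grid.centers[c.stop]*1e3:.0f} ms"
                       f" (p={c.p:.4f})" for c in sig) or "none"
    print(f"{name}: significant clusters: {ranges}")
    return {"direction": result.direction, "equation": result.equation,
            "clusters": cr.to_dict()["clusters"]}


summary = {}
rows = []
for paradigm in ("LT", "ST"):
    for variable, eq in (("dva", "Eq3"), ("rav", "Eq4")):
        nb = link_within(cohort[paradigm], variable, grid=grid, repeats=10, seed=4)
        cr = cluster_test(nb.betas, mode="beta", n_rand=2000, seed=5)
        summary[f"within-{paradigm}-{variable}"] = report(
            f"within {paradigm}, LDA-{variable} -> vae", nb, cr)
        rows.append(pd.DataFrame({"analysis": f"within-{paradigm}-{variable}",
                                  "time_s": grid.centers, "t": nb.tmap,
                                  "cohens_d": nb.dmap}))

lt_st = link_cross(cohort["LT"], cohort["ST"], "dva", grid=grid, repeats=10, seed=4)
st_lt = link_cross(cohort["ST"], cohort["LT"], "dva", grid=grid, repeats=10, seed=4)
conj_map, opposite = conjunction(lt_st.tmap, st_lt.tmap)
cr = conjunction_cluster_test(lt_st.betas, st_lt.betas, n_rand=2000, seed=5)
summary["cross-conjunction-dva"] = report("cross-paradigm conjunction (ΔVA)", lt_st, cr)
summary["cross-conjunction-dva"]["opposite_sign_windows"] = int(opposite.sum())
rows.append(pd.DataFrame({"analysis": "cross-conjunction-dva",
                          "time_s": grid.centers, "t": conj_map,
                          "cohens_d": np.minimum(lt_st.dmap, st_lt.dmap)}))

for paradigm in ("LT", "ST"):
    nb = link_sound_encoding(cohort[paradigm], "dva", grid=grid, repeats=10, seed=4)
    cr = cluster_test(nb.betas, mode="beta", n_rand=2000, seed=5)
    summary[f"sound-encoding-{paradigm}"] = report(
        f"{paradigm}: previous ΔVA -> LDA-sound", nb, cr)
    rows.append(pd.DataFrame({"analysis": f"sound-encoding-{paradigm}",
                              "time_s": grid.centers, "t": nb.tmap,
                              "cohens_d": nb.dmap}))

pd.concat(rows).to_csv(RESULTS / "neurobehavior_tmaps.tsv", sep="\t", index=False)
(RESULTS / "neurobehavior_summary.json").write_text(
    json.dumps(summary, indent=2, default=float))
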