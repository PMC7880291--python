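"""End-to-end validation experiments on the synthetic generator.

Each function runs one self-contained study — simulate under known ground
truth, analyse with the package's own pipeline, summarize — and returns
plain dictionaries.  They back the acceptance checks and the numbered
analysis drivers.  Problem sizes (subjects, replicate counts, channel
counts) are chosen so a full validation pass runs on a laptop in minutes;
the scientific conditions (trial counts, design structure, coefficient
values, analysis settings) are the study conditions themselves.
"""

from __future__ import annotations

import numpy as np

from .behavior import compare_models, compute_vae, fit_bias_glmm
from .cluster_stats import cluster_test, conjunction_cluster_test
from .decoding import WindowGrid, crossval_auc
from .design import generate_design
from .neurobehavior import link_cross, link_within
from .simulate import (SimulationParams, cohort_trials, simulate_cohort,
                       simulate_subject, with_params)

__all__ = [
    "design_counts",
    "glmm_recovery",
    "decoding_null_auc",
    "decoding_signal_recovery",
    "link_recovery_signal",
    "link_null_calibration",
    "cross_paradigm_dissociation",
    "permutation_p_floor",
    "fwer_calibration",
]

#: fixed-effect ground truth used by the recovery studies
RECOVERY_TRUTH = {"Intercept": 0.0, "ss": 0.89, "dva": -0.06, "rav": 0.026,
                  "P": 0.0, "ss:P": 0.0, "dva:P": 0.0}


def _derive(seed: int, salt: int, rep: int = 0) -> int:
    """Stable sub-seed below 2**31."""
    return (seed * 1_000_003 + salt * 7919 + rep) % (2**31 - 1)


def design_counts(seed: int = 0) -> dict:
    """Trial counts and ΔVA repeats of freshly generated LT/ST designs."""
    out = {}
    for paradigm in ("LT", "ST"):
        df = generate_design(paradigm, seed)
        counts = df.trial_type.value_counts()
        reps = df[df.trial_type == "AV"].delta_va.value_counts()
        out[paradigm] = {
            "AV": int(counts.get("AV", 0)),
            "A": int(counts.get("A", 0)),
            "V": int(counts.get("V", 0)),
            "dva_repeats": {float(k): int(v) for k, v in reps.items()},
        }
    return out


def glmm_recovery(n_replicates: int = 100, seed: int = 0,
                  n_subjects: int = 19) -> dict:
    """Refit the aftereffect model on its own generator output.

    Simulates ``n_replicates`` cohorts with the default Eq-2-style
    coefficients (cumulative state off, so the fitted model is exactly the
    generating one), refits both bias models, and reports per-term 95% CI
    coverage of the generating values plus the BIC preference for the
    carryover model.
    """
    coverage = {t: 0 for t in RECOVERY_TRUTH}
    estimates = {t: [] for t in RECOVERY_TRUTH}
    dbics = []
    for rep in range(n_replicates):
        params = SimulationParams(seed=_derive(seed, 1, rep),
                                  n_subjects=n_subjects, cumulative_rate=0.0)
        vae = compute_vae(cohort_trials(simulate_cohort(params, with_epochs=False)))
        f1 = fit_bias_glmm(vae, "eq1-vae")
        f2 = fit_bias_glmm(vae, "eq2-vae")
        dbics.append(compare_models(f1, f2))
        for term, truth in RECOVERY_TRUTH.items():
            lo = f2.coef.loc[term, "ci_low"]
            hi = f2.coef.loc[term, "ci_high"]
            coverage[term] += int(lo <= truth <= hi)
            estimates[term].append(float(f2.coef.loc[term, "estimate"]))
    return {
        "n_replicates": n_replicates,
        "coverage": {t: c / n_replicates for t, c in coverage.items()},
        "mean_estimates": {t: float(np.mean(v)) for t, v in estimates.items()},
        "delta_bic": [float(d) for d in dbics],
        "delta_bic_positive_fraction": float(np.mean(np.array(dbics) > 0)),
    }


def _null_params(seed: int, n_channels: int = 8) -> SimulationParams:
    """No neural signal coupling and no behavioral ΔVA dependence."""
    return SimulationParams(seed=seed, n_channels=n_channels, snr=1.0,
                            coupling=0.0, sound_bias=0.0, b_vae_sqrt=0.0,
                            b_vae_lin=0.0, b_resp=0.0, cumulative_rate=0.0,
                            epoch_window=(-0.42, 0.52))


def decoding_null_auc(n_runs: int = 50, seed: int = 0) -> dict:
    """Mean per-window AUC when epochs carry no signal at all (snr = 0)."""
    aucs = []
    for r in range(n_runs):
        params = with_params(_null_params(_derive(seed, 2, r)), snr=0.0)
        sd = simulate_subject("ST", params, 0, trial_types=("AV",))
        av = sd.trials[sd.trials.trial_type == "AV"].set_index("trial_index")
        ep = sd.epochs.select(np.isin(sd.epochs.trial_index, av.index))
        dva = av.loc[ep.trial_index, "delta_va"].to_numpy()
        aucs.append(crossval_auc(ep, dva, seed=r).auc)
    mean_auc = np.mean(aucs, axis=0)
    return {"n_runs": n_runs, "mean_auc": mean_auc,
            "min": float(mean_auc.min()), "max": float(mean_auc.max())}


def decoding_signal_recovery(seed: int = 0, snr: float = 4.0) -> dict:
    """High-snr single subject: AUC in the envelope and pattern recovery."""
    params = SimulationParams(seed=seed, n_channels=16, snr=snr)
    sd = simulate_subject("LT", params, 0, trial_types=("AV",))
    av = sd.trials[sd.trials.trial_type == "AV"].set_index("trial_index")
    ep = sd.epochs.select(np.isin(sd.epochs.trial_index, av.index))
    dva = av.loc[ep.trial_index, "delta_va"].to_numpy()
    res = crossval_auc(ep, dva, seed=seed)
    center, width = params.pattern_latency["dva"]
    inside = np.abs(res.grid.centers - center) <= width
    j = int(np.argmin(np.abs(res.grid.centers - center)))
    r = float(np.corrcoef(res.fwd[j], sd.truth["patterns"]["dva"])[0, 1])
    return {
        "peak_auc": float(res.auc.max()),
        "peak_latency": float(res.grid.centers[res.auc.argmax()]),
        "min_auc_inside_envelope": float(res.auc[inside].min()),
        "pattern_correlation": abs(r),
    }


def link_recovery_signal(seed: int = 0, n_subjects: int = 12,
                         repeats: int = 5, n_rand: int = 2000) -> dict:
    """Eq-3 cluster recovery with active neural→behavior coupling."""
    params = SimulationParams(seed=seed, n_channels=16, snr=1.5, coupling=0.3)
    subs = [simulate_subject("ST", params, s, trial_types=("AV",))
            for s in range(n_subjects)]
    grid = WindowGrid.from_times(subs[0].epochs.times, subs[0].epochs.fs)
    nb = link_within(subs, "dva", grid=grid, repeats=repeats, seed=seed)
    cr = cluster_test(nb.betas, mode="beta", n_rand=n_rand, seed=seed)
    latency = params.pattern_latency["dva"][0]
    sig = cr.significant(0.01)
    covering = [c for c in sig
                if grid.centers[c.start] <= latency <= grid.centers[c.stop]]
    return {
        "latency": latency,
        "clusters": [(float(grid.centers[c.start]), float(grid.centers[c.stop]),
                      float(c.p)) for c in cr.clusters],
        "n_significant": len(sig),
        "significant_cluster_covers_latency": bool(covering),
        "all_significant_cover_latency": len(covering) == len(sig),
        "min_p": min((c.p for c in cr.clusters), default=1.0),
        "peak_t_latency": float(grid.centers[np.abs(nb.tmap).argmax()]),
    }


def link_null_calibration(n_runs: int = 100, seed: int = 0,
                          n_subjects: int = 8, n_rand: int = 500) -> dict:
    """Fraction of fully-null Eq-3 analyses producing a cluster at α=0.05."""
    hits = 0
    for r in range(n_runs):
        params = _null_params(_derive(seed, 3, r))
        subs = [simulate_subject("ST", params, s, trial_types=("AV",))
                for s in range(n_subjects)]
        grid = WindowGrid.from_times(subs[0].epochs.times, subs[0].epochs.fs)
        nb = link_within(subs, "dva", grid=grid, repeats=2, seed=r)
        cr = cluster_test(nb.betas, mode="beta", n_rand=n_rand, seed=r, alpha=0.05)
        hits += bool(cr.significant(0.05))
    return {"n_runs": n_runs, "fraction_with_cluster": hits / n_runs}


def cross_paradigm_dissociation(seed: int = 0, shared: bool = True,
                                n_subjects: int = 10, repeats: int = 5,
                                n_rand: int = 1000) -> dict:
    """Conjunction vs within-paradigm clusters with shared or session-specific
    spatial patterns."""
    params = SimulationParams(seed=seed, n_channels=16, snr=1.5, coupling=0.3)
    cohorts = {}
    for pcode, paradigm in enumerate(("LT", "ST")):
        subs = []
        for s in range(n_subjects):
            prng = (None if shared else
                    np.random.default_rng([seed, s, 991, pcode]))
            subs.append(simulate_subject(paradigm, params, s,
                                         trial_types=("AV",), pattern_rng=prng))
        cohorts[paradigm] = subs
    grid = WindowGrid.from_times(cohorts["LT"][0].epochs.times, params.fs)

    within = {}
    for paradigm in ("LT", "ST"):
        nb = link_within(cohorts[paradigm], "dva", grid=grid, repeats=repeats,
                         seed=seed)
        cr = cluster_test(nb.betas, mode="beta", n_rand=n_rand, seed=seed)
        within[paradigm] = bool(cr.significant(0.01))
    lt_st = link_cross(cohorts["LT"], cohorts["ST"], "dva", grid=grid,
                       repeats=repeats, seed=seed)
    st_lt = link_cross(cohorts["ST"], cohorts["LT"], "dva", grid=grid,
                       repeats=repeats, seed=seed)
    conj = conjunction_cluster_test(lt_st.betas, st_lt.betas, n_rand=n_rand,
                                    seed=seed)
    sig = conj.significant(0.01)
    return {
        "shared_patterns": shared,
        "within_significant": within,
        "conjunction_significant": bool(sig),
        "conjunction_min_p": min((c.p for c in conj.clusters), default=1.0),
    }


def permutation_p_floor(seed: int = 0, n_rand: int = 3000) -> float:
    """Smallest attainable cluster p: a constant strong effect in all subjects."""
    rng = np.random.default_rng(seed)
    data = 5.0 + 0.01 * rng.normal(size=(19, 40))
    res = cluster_test(data, mode="beta", n_rand=n_rand, seed=seed)
    return float(min(c.p for c in res.clusters))


def fwer_calibration(n_runs: int = 400, seed: int = 0, n_subjects: int = 12,
                     n_rand: int = 300) -> dict:
    """Family-wise error of the full null pipeline at α = 0.05."""
    hits = 0
    for r in range(n_runs):
        params = _null_params(_derive(seed, 4, r))
        subs = [simulate_subject("ST", params, s, trial_types=("AV",))
                for s in range(n_subjects)]
        grid = WindowGrid.from_times(subs[0].epochs.times, subs[0].epochs.fs)
        nb = link_within(subs, "dva", grid=grid, repeats=1, seed=r)
        cr = cluster_test(nb.betas, mode="beta", n_rand=n_rand, seed=r, alpha=0.05)
        hits += bool(cr.significant(0.05))
    frac = hits / n_runs
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_runs)
    return {"n_runs": n_runs, "fwer": frac,
            "binomial_band": (0.05 - half, 0.05 + half)}
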