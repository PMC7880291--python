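"""Synthetic behavior and EEG-like epochs with known ground truth.

The behavioral generator inverts the bias models used in the analysis:
AV-trial responses are drawn around the true sound position with a
ventriloquism shift depending linearly and via the signed square root on
the audiovisual discrepancy; A-trial responses carry the aftereffect
(same two ΔVA terms of the preceding AV trial), a carryover from the
previous response, and — in the LT paradigm only — a slowly accumulating
recalibration state.

The epoch generator embeds one fixed random spatial pattern per encoded
variable (ΔVA side, response side, sound side) under a smooth temporal
envelope into band-limited, spatially correlated noise.  The single-trial
amplitude of the ΔVA pattern in an AV trial can be injected into the paired
A trial's response (``coupling``), creating a ground-truth neurobehavioral
link for the downstream regression analyses to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import generate_design
from .epochs import EpochArray, bandpass, epoch_times

__all__ = [
    "SimulationParams",
    "SubjectData",
    "simulate_behavior",
    "simulate_epochs",
    "simulate_subject",
    "simulate_cohort",
    "signed_sqrt",
]


def signed_sqrt(x):
    """Signed square root sign(x)·√|x| (odd in x)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.sqrt(np.abs(x))


@dataclass
class SimulationParams:
    """Generator settings; defaults emulate the study conditions.

    The ventriloquism-effect and aftereffect coefficients are in degrees per
    unit of their regressor; ``sigma_resp`` is the single-trial localization
    noise SD in degrees; ``sigma_subj`` the between-subject intercept SD.
    ``cumulative_rate`` is the per-pair relaxation rate of the LT
    recalibration state toward ``±cumulative_target`` degrees (sign of the
    current block's ΔVA); it is held at zero in ST.  ``snr`` is the ratio of
    pattern amplitude to noise RMS, ``amp_jitter`` the SD of trial-to-trial
    amplitude fluctuation, and ``coupling`` (degrees per amplitude unit)
    feeds the AV trial's ΔVA-pattern amplitude into the paired A response.
    ``pattern_latency`` maps each encoded variable to (center, width) of its
    Gaussian envelope in seconds.  ``sound_bias`` shifts the A-trial
    sound-pattern amplitude by the sign of the preceding trial's ΔVA,
    emulating a recalibrated sound representation.
    """

    n_subjects: int = 19
    # behavior
    b_ve_sqrt: float = 2.06
    b_ve_lin: float = 0.02
    b_vae_sqrt: float = 0.89
    b_vae_lin: float = -0.06
    b_resp: float = 0.026
    cumulative_rate: float = 0.02
    cumulative_target: float = 2.0
    sigma_resp: float = 4.0
    sigma_subj: float = 1.0
    # epochs
    n_channels: int = 32
    fs: float = 150.0
    epoch_window: tuple[float, float] = (-0.8, 0.65)
    snr: float = 1.0
    amp_jitter: float = 0.5
    pattern_latency: dict = field(default_factory=lambda: {
        "dva": (0.25, 0.05), "rav": (0.30, 0.05), "aa": (0.135, 0.05)})
    coupling: float = 0.3
    sound_bias: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_resp <= 0:
            raise ValueError("sigma_resp must be > 0")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        t0, t1 = self.epoch_window
        if t0 > -0.4 or t1 < 0.5:
            raise ValueError("epoch window must contain [-0.4, 0.5] s")


def _check_pairing(design: pd.DataFrame) -> pd.DataFrame:
    df = design.reset_index(drop=True)
    a_rows = np.flatnonzero((df.trial_type == "A").to_numpy())
    if a_rows.size == 0 or np.any(df.loc[a_rows - 1, "trial_type"].to_numpy() != "AV"):
        raise ValueError("design lacks strict AV->A pairing")
    prev = df.loc[a_rows, "prev_av_index"].to_numpy()
    if np.any(prev != df.loc[a_rows - 1, "trial_index"].to_numpy()):
        raise ValueError("prev_av_index does not point at the preceding AV trial")
    return df


def simulate_behavior(design: pd.DataFrame, params: SimulationParams,
                      rng: np.random.Generator | None = None,
                      subject_offset: float = 0.0) -> pd.DataFrame:
    """Fill the ``response`` column of a trial table.

    AV:  R = A + b_ve_sqrt·ss(ΔVA) + b_ve_lin·ΔVA + ε
    A:   R = A + b_vae_sqrt·ss(ΔVA_prev) + b_vae_lin·ΔVA_prev
             + b_resp·R_AV_prev + c_t + ε
    V:   R = V + ε

    ``c_t`` relaxes toward ±cumulative_target at ``cumulative_rate`` per
    AV–A pair within each sign-constant LT half (reset at the
    leftward/rightward break); it is 0 throughout ST.  ``subject_offset``
    is a constant localization bias added to every response.
    """
    df = _check_pairing(design).copy()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    paradigm = df["paradigm"].iloc[0]

    av = df.trial_type == "AV"
    dva = df.loc[av, "delta_va"].to_numpy()
    r_av = (df.loc[av, "a_loc"].to_numpy()
            + params.b_ve_sqrt * signed_sqrt(dva)
            + params.b_ve_lin * dva
            + rng.normal(0.0, params.sigma_resp, av.sum()))
    df.loc[av, "response"] = r_av

    a_rows = np.flatnonzero((df.trial_type == "A").to_numpy())
    dva_prev = df.loc[a_rows - 1, "delta_va"].to_numpy()
    r_prev = df.loc[a_rows - 1, "response"].to_numpy()

    # cumulative recalibration state, closed form of
    # c_k = c_{k-1} + rate*(target - c_{k-1}) starting from 0 at each half
    c = np.zeros(a_rows.size)
    if paradigm == "LT" and params.cumulative_rate > 0:
        blocks = df.loc[a_rows, "block"].to_numpy()
        for half, sign in ((blocks <= 3, -1.0), (blocks > 3, 1.0)):
            k = np.arange(1, half.sum() + 1)
            c[half] = sign * params.cumulative_target * (
                1.0 - (1.0 - params.cumulative_rate) ** k)

    df.loc[a_rows, "response"] = (
        df.loc[a_rows, "a_loc"].to_numpy()
        + params.b_vae_sqrt * signed_sqrt(dva_prev)
        + params.b_vae_lin * dva_prev
        + params.b_resp * r_prev
        + c
        + rng.normal(0.0, params.sigma_resp, a_rows.size))

    v = df.trial_type == "V"
    df.loc[v, "response"] = (df.loc[v, "v_loc"].to_numpy()
                             + rng.normal(0.0, params.sigma_resp, v.sum()))
    df["response"] += subject_offset
    return df


def _envelope(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / width) ** 2)


def simulate_epochs(design: pd.DataFrame, params: SimulationParams,
                    rng: np.random.Generator | None = None,
                    pattern_rng: np.random.Generator | None = None,
                    trial_types: tuple[str, ...] = ("AV", "A")):
    """Simulate epochs for all AV and A trials of a session.

    Returns ``(epochs, trials, truth)``: the epoch array, a copy of the
    trial table with the neural-amplitude coupling added to the A-trial
    responses, and a ground-truth dict with the spatial patterns
    (``patterns``, unit norm per variable), per-trial amplitudes
    (``amplitudes`` indexed like the epochs), and the envelope parameters.

    ``pattern_rng`` fixes the spatial patterns and noise mixing separately
    from the trial-level randomness, so a cohort can share topographies.
    """
    df = _check_pairing(design).copy()
    if df["response"].isna().all():
        raise ValueError("simulate behavior before epochs")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if pattern_rng is None:
        pattern_rng = rng

    t0, t1 = params.epoch_window
    for var, (center, width) in params.pattern_latency.items():
        if not (t0 <= center <= t1):
            raise ValueError(f"pattern latency {center} s for {var!r} outside epoch window")

    times = epoch_times(t0, t1, params.fs)
    keep = df.trial_type.isin(list(trial_types)).to_numpy()
    sub = df.loc[keep]
    n_trials, n_ch, n_samp = keep.sum(), params.n_channels, times.size

    # fixed unit-norm spatial patterns and an SPD spatial noise mixing
    patterns = {}
    for var in params.pattern_latency:
        p = pattern_rng.normal(size=n_ch)
        patterns[var] = p / np.linalg.norm(p)
    mix = pattern_rng.normal(size=(n_ch, n_ch)) / np.sqrt(n_ch)
    mix += 0.5 * np.eye(n_ch)

    noise = rng.normal(size=(n_trials, n_ch, n_samp))
    noise = np.einsum("ij,tjs->tis", mix, noise)
    noise = bandpass(noise, params.fs)
    noise /= noise.std()

    data = noise
    is_av = (sub.trial_type == "AV").to_numpy()
    gvals = {
        "dva": np.where(is_av, np.sign(sub.delta_va.fillna(0.0)), 0.0),
        "rav": np.where(is_av, np.sign(sub.response), 0.0),
        "aa": np.where(~is_av, np.sign(sub.a_loc.fillna(0.0)), 0.0),
    }
    # previous-trial discrepancy sign per A trial (for the sound-bias leak)
    av_dva = df.loc[df.trial_type == "AV"].set_index("trial_index")["delta_va"]
    prev_sign = np.where(
        is_av, 0.0,
        np.sign(av_dva.reindex(sub.prev_av_index).fillna(0.0).to_numpy()))

    amps = {}
    for var, (center, width) in params.pattern_latency.items():
        g = gvals[var]
        active = g != 0
        amp = np.zeros(n_trials)
        amp[active] = g[active] + params.amp_jitter * rng.normal(size=active.sum())
        if var == "aa" and params.sound_bias:
            amp[active] += params.sound_bias * prev_sign[active]
        amps[var] = amp
        env = _envelope(times, center, width)
        data += params.snr * amp[:, None, None] * np.outer(patterns[var], env)[None]

    trial_index = sub.trial_index.to_numpy()
    epochs = EpochArray(data, times, params.fs, trial_index=trial_index)

    # neurobehavioral coupling: the AV trial's single-trial ΔVA-pattern
    # amplitude leaks into the paired A trial's reported location
    if params.coupling > 0 and params.snr > 0 and "AV" in trial_types:
        amp_by_index = pd.Series(amps["dva"], index=trial_index)
        a_mask = df.trial_type == "A"
        leak = amp_by_index.reindex(df.loc[a_mask, "prev_av_index"]).to_numpy()
        df.loc[a_mask, "response"] += params.coupling * leak

    truth = {
        "patterns": patterns,
        "amplitudes": pd.DataFrame(amps, index=trial_index),
        "pattern_latency": dict(params.pattern_latency),
        "mixing": mix,
    }
    return epochs, df, truth


@dataclass
class SubjectData:
    """One subject × paradigm session: trial table, epochs, ground truth."""
    subject: int
    paradigm: str
    trials: pd.DataFrame
    epochs: EpochArray | None = None
    truth: dict | None = None


def simulate_subject(paradigm: str, params: SimulationParams, subject: int = 0,
                     with_epochs: bool = True,
                     pattern_rng: np.random.Generator | None = None,
                     trial_types: tuple[str, ...] = ("AV", "A")) -> SubjectData:
    """Simulate one subject's session (design → behavior → epochs).

    All randomness derives from ``params.seed`` together with the subject
    number and paradigm, so cohorts are reproducible trial-for-trial.
    """
    pcode = {"LT": 0, "ST": 1}[paradigm]
    design = generate_design(paradigm, np.random.SeedSequence([params.seed, subject, pcode, 0]))
    rng_b = np.random.default_rng([params.seed, subject, pcode, 1])
    offset = float(np.random.default_rng([params.seed, subject, 17]).normal(0.0, params.sigma_subj))
    trials = simulate_behavior(design, params, rng=rng_b, subject_offset=offset)
    epochs = truth = None
    if with_epochs:
        rng_e = np.random.default_rng([params.seed, subject, pcode, 2])
        if pattern_rng is None:
            # patterns shared across paradigms within a subject
            pattern_rng = np.random.default_rng([params.seed, subject, 3])
        epochs, trials, truth = simulate_epochs(trials, params, rng=rng_e,
                                                pattern_rng=pattern_rng,
                                                trial_types=trial_types)
    trials = trials.copy()
    trials["subject"] = subject
    return SubjectData(subject, paradigm, trials, epochs, truth)


def simulate_cohort(params: SimulationParams, paradigms=("LT", "ST"),
                    with_epochs: bool = False):
    """Simulate all subjects; returns ``{paradigm: [SubjectData, ...]}``."""
    return {p: [simulate_subject(p, params, s, with_epochs=with_epochs)
                for s in range(params.n_subjects)]
            for p in paradigms}


def cohort_trials(cohort: dict) -> pd.DataFrame:
    """Stack all subjects' trial tables across paradigms into one frame."""
    return pd.concat([sd.trials for subs in cohort.values() for sd in subs],
                     ignore_index=True)


def with_params(params: SimulationParams, **kw) -> SimulationParams:
    """Copy params with fields replaced (validation re-runs)."""
    return replace(params, **kw)
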