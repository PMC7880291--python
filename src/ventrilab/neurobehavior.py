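"""Single-trial links between decoded EEG representations and behavior.

Two strands of analysis:

* AV-trial strand — train the left/right decoder for the audiovisual
  discrepancy (or the AV response) on AV-trial epochs and regress the
  paired A trial's aftereffect on the held-out decision values
  (``vae ~ β0 + β1·LDA``), within a paradigm or across paradigms.
* A-trial strand — train the decoder for the current sound's side on
  A-trial epochs and regress its held-out decision values on the previous
  trial's discrepancy or response (``LDA ~ β0 + β1·ΔVA``).

Both use threefold cross-validation repeated 30 times, averaging β1 over
folds and repeats; decision values are z-scored within each held-out fold
so β1 is comparable across windows, folds, and paradigms.  Group inference
is a one-sample t across subjects per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .behavior import compute_vae
from .decoding import (WindowGrid, binarize_label, decision_values,
                       train_rlda_windows, window_features)
from .simulate import SubjectData

__all__ = [
    "NeuroBehavResult",
    "link_within",
    "link_cross",
    "link_sound_encoding",
    "conjunction",
]


@dataclass
class NeuroBehavResult:
    """Per-subject β1 time courses and their group-level t and Cohen's d maps."""
    equation: str
    direction: str
    betas: np.ndarray      # subjects x windows
    centers: np.ndarray    # window centers (s)
    repeats: int
    folds: int
    seed: int
    metadata: dict | None = None

    @property
    def tmap(self) -> np.ndarray:
        S = self.betas.shape[0]
        sd = self.betas.std(axis=0, ddof=1)
        return self.betas.mean(axis=0) / np.maximum(sd, 1e-300) * np.sqrt(S)

    @property
    def dmap(self) -> np.ndarray:
        sd = self.betas.std(axis=0, ddof=1)
        return self.betas.mean(axis=0) / np.maximum(sd, 1e-300)

    def save(self, path: str) -> None:
        np.savez(path, equation=self.equation, direction=self.direction,
                 betas=self.betas, tmap=self.tmap, dmap=self.dmap,
                 centers=self.centers, repeats=self.repeats, folds=self.folds,
                 seed=self.seed)


def _fold_seed(seed: int, subject: int, repeat: int) -> int:
    return (1000003 * seed + 1009 * subject + repeat) % (2**31 - 1)


def _zscore_cols(dv: np.ndarray) -> np.ndarray:
    mu = dv.mean(axis=0, keepdims=True)
    sd = dv.std(axis=0, keepdims=True)
    return (dv - mu) / np.where(sd == 0, 1.0, sd)


def _slope_on_dv(dv_z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-window slope of y ~ decision value (z-scored)."""
    yc = y - y.mean()
    denom = np.einsum("tw,tw->w", dv_z, dv_z)
    denom = np.where(denom == 0, 1.0, denom)
    return np.einsum("tw,t->w", dv_z, yc) / denom


def _slope_of_dv(dv_z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-window slope of decision value ~ x (continuous predictor)."""
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return np.zeros(dv_z.shape[1])
    return np.einsum("tw,t->w", dv_z, xc) / denom


def _av_arrays(sd: SubjectData, variable: str, grid: WindowGrid,
               feature_mode: str = "mean"):
    """Windowed AV-trial features, decoder values, and paired vae per AV trial."""
    trials = sd.trials
    av = trials[trials.trial_type == "AV"].set_index("trial_index")
    av_mask = np.isin(sd.epochs.trial_index, av.index)
    ep = sd.epochs.select(av_mask)
    vae_tbl = compute_vae(trials).set_index("prev_av_index")
    vae = vae_tbl["vae"].reindex(ep.trial_index)
    if vae.isna().any():
        bad = list(ep.trial_index[vae.isna().to_numpy()][:10])
        raise ValueError(f"AV trials without a paired A trial: {bad}")
    col = {"dva": "delta_va", "rav": "response"}[variable]
    values = av.loc[ep.trial_index, col].to_numpy(dtype=float)
    Xw = window_features(ep, grid, mode=feature_mode)
    return Xw, values, vae.to_numpy()


def _a_arrays(sd: SubjectData, predictor: str, grid: WindowGrid,
              feature_mode: str = "mean"):
    """Windowed A-trial features, sound-side labels, and the previous-trial predictor."""
    trials = sd.trials
    a = trials[trials.trial_type == "A"].set_index("trial_index")
    a_mask = np.isin(sd.epochs.trial_index, a.index)
    ep = sd.epochs.select(a_mask)
    sound = a.loc[ep.trial_index, "a_loc"].to_numpy(dtype=float)
    av = trials[trials.trial_type == "AV"].set_index("trial_index")
    prev = a.loc[ep.trial_index, "prev_av_index"]
    col = {"dva": "delta_va", "rav": "response"}[predictor]
    x = av.loc[prev, col].to_numpy(dtype=float)
    Xw = window_features(ep, grid, mode=feature_mode)
    return Xw, sound, x


def default_grid(sd: SubjectData) -> WindowGrid:
    return WindowGrid.from_times(sd.epochs.times, sd.epochs.fs)


def _subject_beta_within(Xw, labels, y, repeats, folds, lam, seed, subject,
                         regress_dv_on_x: bool) -> np.ndarray:
    n, _, W = Xw.shape
    acc = np.zeros(W)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=_fold_seed(seed, subject, r))
        fold_acc = np.zeros(W)
        for tr, te in skf.split(np.zeros(n), labels):
            w, b = train_rlda_windows(Xw[tr], labels[tr], lam)
            dv = _zscore_cols(decision_values(Xw[te], w, b))
            fold_acc += (_slope_of_dv(dv, y[te]) if regress_dv_on_x
                         else _slope_on_dv(dv, y[te]))
        acc += fold_acc / folds
    return acc / repeats


def _subject_beta_cross(Xw_src, labels_src, Xw_dst, y_dst, repeats, folds, lam,
                        seed, subject, regress_dv_on_x: bool) -> np.ndarray:
    n, _, W = Xw_src.shape
    acc = np.zeros(W)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=_fold_seed(seed, subject, r))
        fold_acc = np.zeros(W)
        for tr, _ in skf.split(np.zeros(n), labels_src):
            w, b = train_rlda_windows(Xw_src[tr], labels_src[tr], lam)
            dv = _zscore_cols(decision_values(Xw_dst, w, b))
            fold_acc += (_slope_of_dv(dv, y_dst) if regress_dv_on_x
                         else _slope_on_dv(dv, y_dst))
        acc += fold_acc / folds
    return acc / repeats


def link_within(subject_data: list[SubjectData], variable: str = "dva",
                grid: WindowGrid | None = None, repeats: int = 30,
                folds: int = 3, lam: float = 0.1, seed: int = 0) -> NeuroBehavResult:
    """Within-paradigm neurobehavioral model: vae ~ β0 + β1·LDA(variable).

    For each subject and cross-validation repeat, the left/right decoder
    for ``variable`` ("dva" or "rav") is trained per window on the training
    AV trials; β1 is the slope of the held-out paired aftereffects on the
    z-scored held-out decision values, averaged over folds and repeats.
    """
    if grid is None:
        grid = default_grid(subject_data[0])
    betas = []
    for sd in subject_data:
        Xw, values, vae = _av_arrays(sd, variable, grid)
        labels, mask = binarize_label(values)
        betas.append(_subject_beta_within(Xw[mask], labels, vae[mask], repeats,
                                          folds, lam, seed, sd.subject, False))
    eq = "Eq3" if variable == "dva" else "Eq4"
    paradigm = subject_data[0].paradigm
    return NeuroBehavResult(eq, f"within-{paradigm}", np.array(betas),
                            grid.centers, repeats, folds, seed)


def link_cross(src_data: list[SubjectData], dst_data: list[SubjectData],
               variable: str = "dva", grid: WindowGrid | None = None,
               repeats: int = 30, folds: int = 3, lam: float = 0.1,
               seed: int = 0) -> NeuroBehavResult:
    """Cross-paradigm model: decoder trained on the source paradigm's AV
    trials predicts the destination paradigm's aftereffect.

    Fold models are trained on the source session exactly as in
    :func:`link_within`; each is applied to *all* destination AV trials and
    the per-fold regressions are averaged (fold-then-average).
    """
    if grid is None:
        grid = default_grid(src_data[0])
    by_subj = {sd.subject: sd for sd in dst_data}
    betas = []
    for sd in src_data:
        if sd.subject not in by_subj:
            raise ValueError(f"subject {sd.subject} missing from destination data")
        dd = by_subj[sd.subject]
        if sd.epochs.n_channels != dd.epochs.n_channels:
            raise ValueError("channel sets differ between paradigms")
        Xw_s, val_s, _ = _av_arrays(sd, variable, grid)
        lab_s, m_s = binarize_label(val_s)
        Xw_d, _, vae_d = _av_arrays(dd, variable, grid)
        betas.append(_subject_beta_cross(Xw_s[m_s], lab_s, Xw_d, vae_d, repeats,
                                         folds, lam, seed, sd.subject, False))
    eq = "Eq3" if variable == "dva" else "Eq4"
    direction = f"{src_data[0].paradigm}->{by_subj[src_data[0].subject].paradigm}"
    return NeuroBehavResult(eq, direction, np.array(betas), grid.centers,
                            repeats, folds, seed)


def link_sound_encoding(subject_data: list[SubjectData], predictor: str = "dva",
                        grid: WindowGrid | None = None,
                        cross_data: list[SubjectData] | None = None,
                        repeats: int = 30, folds: int = 3, lam: float = 0.1,
                        seed: int = 0) -> NeuroBehavResult:
    """A-trial strand: LDA(sound side) ~ β0 + β1·(previous ΔVA or R_AV).

    The decoder is trained on A-trial epochs to report the current sound's
    side (trials at 0° are excluded); its held-out, z-scored decision
    values are regressed on the previous AV trial's discrepancy
    (``predictor="dva"``) or response (``"rav"``).  With ``cross_data`` the
    decoder is trained on ``subject_data`` and evaluated on the other
    paradigm's A trials.
    """
    if grid is None:
        grid = default_grid(subject_data[0])
    by_subj = ({sd.subject: sd for sd in cross_data} if cross_data is not None else None)
    betas = []
    for sd in subject_data:
        Xw, sound, x = _a_arrays(sd, predictor, grid)
        labels, mask = binarize_label(sound)
        if by_subj is None:
            betas.append(_subject_beta_within(Xw[mask], labels, x[mask], repeats,
                                              folds, lam, seed, sd.subject, True))
        else:
            dd = by_subj[sd.subject]
            Xw_d, _, x_d = _a_arrays(dd, predictor, grid)
            betas.append(_subject_beta_cross(Xw[mask], labels, Xw_d, x_d, repeats,
                                             folds, lam, seed, sd.subject, True))
    eq = "Eq5" if predictor == "dva" else "Eq6"
    if by_subj is None:
        direction = f"within-{subject_data[0].paradigm}"
    else:
        direction = f"{subject_data[0].paradigm}->{cross_data[0].paradigm}"
    return NeuroBehavResult(eq, direction, np.array(betas), grid.centers,
                            repeats, folds, seed)


def conjunction(tmap_a: np.ndarray, tmap_b: np.ndarray):
    """Per-window conjunction: the smaller of the two t values.

    Returns ``(conj, opposite_sign)`` where ``opposite_sign`` flags windows
    whose two t values disagree in sign (the conjunction there is the
    negative one and should be interpreted with care).
    """
    a = np.asarray(tmap_a, dtype=float)
    b = np.asarray(tmap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("t maps are on different window grids")
    return np.minimum(a, b), np.sign(a) * np.sign(b) < 0
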