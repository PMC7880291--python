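import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import StratifiedKFold

from ventrilab.cluster_stats import cluster_test
from ventrilab.decoding import WindowGrid
from ventrilab.epochs import EpochArray, epoch_times
from ventrilab.neurobehavior import (_fold_seed, conjunction, link_cross,
                                     link_sound_encoding, link_within)
from ventrilab.simulate import SubjectData

from conftest import av_epochs_and_dva


def _tiny_subject(seed=0, n_pairs=12, subject=0):
    """Minimal AV->A session with random epochs for oracle comparisons."""
    rng = np.random.default_rng(seed)
    dva_pool = np.array([-34.8, -23.2, -11.6, 11.6, 23.2, 34.8])
    rows = []
    idx = 0
    for k in range(n_pairs):
        dva = dva_pool[k % 6]
        a_loc = 0.0
        rows.append(("ST", 1, idx, "AV", a_loc, a_loc + dva, dva,
                     rng.normal(0, 5), -1))
        idx += 1
        rows.append(("ST", 1, idx, "A", 11.6 * ((k % 4) - 1), np.nan, np.nan,
                     rng.normal(0, 5), idx - 1))
        idx += 1
    trials = pd.DataFrame(rows, columns=[
        "paradigm", "block", "trial_index", "trial_type", "a_loc", "v_loc",
        "delta_va", "response", "prev_av_index"])
    trials["subject"] = subject
    times = epoch_times(-0.1, 0.2, 150.0)
    data = rng.normal(size=(len(trials), 3, times.size))
    epochs = EpochArray(data, times, 150.0, trial_index=trials.trial_index.to_numpy())
    return SubjectData(subject, "ST", trials, epochs)


def _tiny_grid():
    return WindowGrid(starts=np.array([5, 15]), win_samples=6, step_samples=10,
                      centers=np.array([0.0, 0.1]))


def test_link_within_matches_hand_rolled_loop():
    """The full pipeline equals an explicit fold/LDA/least-squares loop."""
    sd = _tiny_subject(seed=1)
    grid = _tiny_grid()
    repeats, folds, lam, seed = 2, 3, 0.1, 4
    res = link_within([sd], "dva", grid=grid, repeats=repeats, folds=folds,
                      lam=lam, seed=seed)

    # --- independent oracle -------------------------------------------------
    trials = sd.trials
    av = trials[trials.trial_type == "AV"]
    a = trials[trials.trial_type == "A"].copy()
    mu = a.groupby("a_loc").response.transform("mean")
    vae_by_prev = dict(zip(a.prev_av_index, a.response - mu))
    y_all = np.array([vae_by_prev[i] for i in av.trial_index])
    labels = av.delta_va.to_numpy() > 0
    X = np.stack([sd.epochs.data[np.isin(sd.epochs.trial_index, av.trial_index)]
                  [:, :, s: s + 6].mean(axis=2) for s in grid.starts], axis=2)

    acc = np.zeros(2)
    for r in range(repeats):
        skf = StratifiedKFold(3, shuffle=True, random_state=_fold_seed(seed, 0, r))
        fold_acc = np.zeros(2)
        for tr, te in skf.split(np.zeros(len(labels)), labels):
            for j in range(2):
                Xtr = X[tr][:, :, j]
                mu_l = Xtr[~labels[tr]].mean(0)
                mu_r = Xtr[labels[tr]].mean(0)
                Xc = np.concatenate([Xtr[~labels[tr]] - mu_l, Xtr[labels[tr]] - mu_r])
                S = Xc.T @ Xc / (len(tr) - 2)
                Sreg = (1 - lam) * S + lam * np.trace(S) / 3 * np.eye(3)
                w = np.linalg.inv(Sreg) @ (mu_r - mu_l)
                b = -0.5 * w @ (mu_r + mu_l)
                dv = X[te][:, :, j] @ w + b
                z = (dv - dv.mean()) / dv.std()
                beta = np.linalg.lstsq(np.column_stack([np.ones(len(te)), z]),
                                       y_all[te], rcond=None)[0][1]
                fold_acc[j] += beta
        acc += fold_acc / folds
    oracle = acc / repeats
    assert np.allclose(res.betas[0], oracle, atol=1e-10)


def test_group_t_invariant_to_subject_order():
    subs = [_tiny_subject(seed=s, subject=s) for s in range(4)]
    grid = _tiny_grid()
    r1 = link_within(subs, "dva", grid=grid, repeats=1, seed=0)
    r2 = link_within(subs[::-1], "dva", grid=grid, repeats=1, seed=0)
    assert np.allclose(r1.tmap, r2.tmap)


def test_unpaired_av_trials_rejected():
    sd = _tiny_subject(seed=2)
    trials = sd.trials[sd.trials.trial_index != 1]  # drop one A trial
    broken = SubjectData(0, "ST", trials.reset_index(drop=True), sd.epochs)
    with pytest.raises(ValueError, match="paired"):
        link_within([broken], "dva", grid=_tiny_grid(), repeats=1)


def test_cross_requires_matching_subjects_and_channels():
    a = _tiny_subject(seed=1, subject=0)
    b = _tiny_subject(seed=2, subject=1)
    with pytest.raises(ValueError, match="missing"):
        link_cross([a], [b], grid=_tiny_grid(), repeats=1)
    c = _tiny_subject(seed=3, subject=0)
    c.epochs = EpochArray(c.epochs.data[:, :2], c.epochs.times, c.epochs.fs,
                          trial_index=c.epochs.trial_index)
    with pytest.raises(ValueError, match="channel"):
        link_cross([a], [c], grid=_tiny_grid(), repeats=1)


class TestConjunction:
    def test_smaller_t_taken(self):
        conj, opp = conjunction([3.0, 4.0], [4.0, 3.0])
        assert np.allclose(conj, [3.0, 3.0])
        assert not opp.any()

    def test_idempotent_and_bounded(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=20)
        conj, _ = conjunction(t, t)
        assert np.allclose(conj, t)
        u = rng.normal(size=20)
        c, _ = conjunction(t, u)
        assert np.all(c <= t + 1e-12) and np.all(c <= u + 1e-12)

    def test_opposite_sign_flagged(self):
        conj, opp = conjunction([2.0, -2.0], [-1.0, 3.0])
        assert np.allclose(conj, [-1.0, -2.0])
        assert opp.all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            conjunction(np.zeros(5), np.zeros(6))


def test_coupled_link_detected_and_shuffled_responses_are_null(st_cohort_small):
    """Eq-3 finds the coupling at the pattern latency; a label permutation
    destroys the R_AV association (construction-level specificity)."""
    subs, params = st_cohort_small
    grid = WindowGrid.from_times(subs[0].epochs.times, subs[0].epochs.fs)
    res = link_within(subs, "dva", grid=grid, repeats=3, seed=2)
    cr = cluster_test(res.betas, mode="beta", n_rand=800, seed=3, alpha=0.01)
    sig = cr.significant(0.01)
    assert sig, "expected a significant cluster with active coupling"
    lat = params.pattern_latency["dva"][0]
    assert any(grid.centers[c.start] <= lat <= grid.centers[c.stop] for c in sig)

    # shuffle AV responses across trials: the rav decoder now trains on
    # labels unrelated to the epochs, so no link should survive
    shuffled = []
    rng = np.random.default_rng(9)
    for sd in subs:
        t = sd.trials.copy()
        av = t.trial_type == "AV"
        t.loc[av, "response"] = rng.permutation(t.loc[av, "response"].to_numpy())
        shuffled.append(SubjectData(sd.subject, sd.paradigm, t, sd.epochs))
    res2 = link_within(shuffled, "rav", grid=grid, repeats=3, seed=2)
    cr2 = cluster_test(res2.betas, mode="beta", n_rand=800, seed=3, alpha=0.05)
    assert not cr2.significant(0.05)


def test_sound_encoding_reflects_previous_discrepancy():
    """The A-trial sound decoder is predicted by the preceding ΔVA exactly
    when the generator biases the sound-pattern amplitude by it."""
    from ventrilab.simulate import SimulationParams, simulate_subject, with_params

    params = SimulationParams(seed=23, n_channels=16, snr=1.5, sound_bias=0.6)
    subs = [simulate_subject("ST", params, s) for s in range(6)]
    grid = WindowGrid.from_times(subs[0].epochs.times, subs[0].epochs.fs)
    res = link_sound_encoding(subs, "dva", grid=grid, repeats=3, seed=1)
    assert res.equation == "Eq5"
    cr = cluster_test(res.betas, mode="beta", n_rand=600, seed=2, alpha=0.05)
    sig = cr.significant(0.05)
    lat = params.pattern_latency["aa"][0]
    assert sig and any(grid.centers[c.start] <= lat <= grid.centers[c.stop]
                       for c in sig)

    off = with_params(params, sound_bias=0.0)
    subs0 = [simulate_subject("ST", off, s) for s in range(6)]
    res0 = link_sound_encoding(subs0, "dva", grid=grid, repeats=3, seed=1)
    cr0 = cluster_test(res0.betas, mode="beta", n_rand=600, seed=2, alpha=0.05)
    assert not cr0.significant(0.05)
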