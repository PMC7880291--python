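"""Trial-wise bias measures and the mixed-model bias analyses.

The ventriloquism effect (ve) is the AV-trial response error relative to
the true sound position; the ventriloquism aftereffect (vae) is the A-trial
response centered on the subject's mean report for that sound position,
which removes any idiosyncratic localization bias.  Both biases are
modelled as mixed-effects regressions on the (signed-root and linear)
audiovisual discrepancy, optionally the previous response, paradigm
interactions, and a per-subject random intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .simulate import signed_sqrt

log = logging.getLogger(__name__)

__all__ = [
    "compute_ve",
    "compute_vae",
    "signed_sqrt",
    "GLMMFit",
    "fit_bias_glmm",
    "compare_models",
    "bin_bias_timecourse",
    "per_dva_tests",
]

_KEYS = ["subject", "paradigm", "block", "trial_index"]


def _key_cols(trials: pd.DataFrame) -> list[str]:
    return [c for c in _KEYS if c in trials.columns]


def compute_ve(trials: pd.DataFrame) -> pd.DataFrame:
    """Ventriloquism effect per AV trial: ve = response − true sound position."""
    av = trials[trials.trial_type == "AV"].copy()
    missing = av.response.isna()
    if missing.any():
        log.warning("dropping %d AV trials without a response", missing.sum())
        av = av[~missing]
    out = av[_key_cols(av) + ["a_loc", "delta_va"]].copy()
    out["ve"] = av.response - av.a_loc
    out["signed_sqrt_dva"] = signed_sqrt(out.delta_va)
    return out.reset_index(drop=True)


def compute_vae(trials: pd.DataFrame) -> pd.DataFrame:
    """Ventriloquism aftereffect per A trial: vae = R_A − mean(R_A | same sound position).

    Centering is within subject × paradigm × sound position, so constant
    response offsets at a position cancel.  Also attaches the paired AV
    trial's discrepancy (``delta_va``), its signed root, and its response
    (``r_av_prev``) via ``prev_av_index``.
    """
    a = trials[trials.trial_type == "A"].copy()
    missing = a.response.isna()
    if missing.any():
        log.warning("dropping %d A trials without a response", missing.sum())
        a = a[~missing]
    group_cols = [c for c in ("subject", "paradigm") if c in a.columns] + ["a_loc"]
    grp = a.groupby(group_cols)["response"]
    if (grp.size() == 1).any():
        log.warning("sound positions with a single A trial: vae set to 0 there")
    a["vae"] = a.response - grp.transform("mean")

    # paired AV covariates
    idx_cols = [c for c in ("subject", "paradigm") if c in trials.columns]
    av_cov = trials.loc[trials.trial_type == "AV",
                        idx_cols + ["trial_index", "delta_va", "response"]].rename(
        columns={"trial_index": "prev_av_index",
                 "delta_va": "pair_dva", "response": "pair_rav"})
    out = a[_key_cols(a) + ["a_loc", "prev_av_index", "vae"]].merge(
        av_cov, on=idx_cols + ["prev_av_index"], how="left")
    if out.pair_dva.isna().any():
        raise ValueError("A trials with undefined paired delta_va")
    out = out.rename(columns={"pair_dva": "delta_va", "pair_rav": "r_av_prev"})
    out["signed_sqrt_dva"] = signed_sqrt(out.delta_va)
    return out.reset_index(drop=True)


@dataclass
class GLMMFit:
    """Fitted mixed bias model: coefficient table and information criteria."""
    model: str
    formula: str
    coef: pd.DataFrame  # index = term; columns estimate, se, t, p, ci_low, ci_high
    re_var: float
    loglik: float
    n: int
    k: int  # parameters counted in the information criteria

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "formula": self.formula,
            "coefficients": self.coef.reset_index().to_dict(orient="records"),
            "random_intercept_var": self.re_var,
            "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
            "n": self.n, "k": self.k,
        }


_MODEL_RESPONSES = {"eq1-ve": "ve", "eq1-vae": "vae", "eq2-vae": "vae"}


def fit_bias_glmm(bias: pd.DataFrame, model: str = "eq1-vae") -> GLMMFit:
    """ML fit of the bias model with a per-subject random intercept.

    ``model`` selects the response and fixed effects:

    * ``eq1-ve`` / ``eq1-vae``: bias ~ ss(ΔVA) + ΔVA + P + ss(ΔVA):P + ΔVA:P
    * ``eq2-vae``: adds the previous AV response R_AV.

    Paradigm P is coded 0/1 with LT as reference; the paradigm terms are
    dropped automatically when only one paradigm is present.
    """
    if model not in _MODEL_RESPONSES:
        raise ValueError(f"unknown model {model!r}")
    resp = _MODEL_RESPONSES[model]
    df = bias.copy()
    if resp not in df.columns:
        raise ValueError(f"bias table lacks column {resp!r} for model {model}")
    if "subject" not in df.columns:
        raise ValueError("bias table needs a 'subject' column")
    if df.subject.nunique() < 2:
        raise ValueError("need >= 2 subjects for a mixed model")

    df["ss"] = df["signed_sqrt_dva"]
    df["dva"] = df["delta_va"]
    terms = ["ss", "dva"]
    if model == "eq2-vae":
        df["rav"] = df["r_av_prev"]
        terms.append("rav")
    two_paradigms = df.paradigm.nunique() > 1
    if two_paradigms:
        df["P"] = (df.paradigm == "ST").astype(float)
        terms += ["P", "ss:P", "dva:P"]
    formula = f"{resp} ~ " + " + ".join(terms)

    # reject rank-deficient fixed-effect designs up front, naming the culprit
    cols = {"Intercept": np.ones(len(df))}
    for t in terms:
        if ":" in t:
            a_, b_ = t.split(":")
            cols[t] = df[a_].to_numpy() * df[b_].to_numpy()
        else:
            cols[t] = df[t].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"rank-deficient design: term {names[j]!r} is collinear")
        raise ValueError("rank-deficient design")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm(formula, df, groups="subject").fit(reml=False, method="lbfgs")
        re_var = float(res.cov_re.iloc[0, 0])
        degenerate = (not np.isfinite(res.llf)) or res.bse.loc[res.fe_params.index].isna().any()
        if degenerate:
            # random-intercept variance on the 0 boundary: the ML solution
            # coincides with OLS, whose likelihood and SEs are then exact
            import statsmodels.api as sm
            ols = sm.OLS.from_formula(formula, df).fit()
            fe = ols.params.index
            ci = ols.conf_int()
            coef = pd.DataFrame({
                "estimate": ols.params, "se": ols.bse, "t": ols.tvalues,
                "p": ols.pvalues, "ci_low": ci[0], "ci_high": ci[1]})
            loglik = float(ols.llf)
            re_var = min(re_var, 0.0) if np.isfinite(re_var) else 0.0
        else:
            fe = res.fe_params.index
            ci = res.conf_int().loc[fe]
            coef = pd.DataFrame({
                "estimate": res.fe_params, "se": res.bse.loc[fe],
                "t": res.tvalues.loc[fe], "p": res.pvalues.loc[fe],
                "ci_low": ci[0], "ci_high": ci[1]})
            loglik = float(res.llf)
    coef.index.name = "term"
    k = len(coef) + 2  # + random-intercept variance + residual variance
    return GLMMFit(model=model, formula=formula, coef=coef, re_var=max(re_var, 0.0),
                   loglik=loglik, n=int(res.nobs), k=k)


def compare_models(fit1: GLMMFit, fit2: GLMMFit) -> float:
    """ΔBIC = BIC(fit1) − BIC(fit2); positive favors fit2."""
    if fit1.n != fit2.n:
        raise ValueError("fits are on different numbers of observations")
    return fit1.bic - fit2.bic


def bin_bias_timecourse(bias: pd.DataFrame, paradigm: str, value: str = "vae",
                        n_bins: int = 36, increment: int | None = None,
                        n_boot: int = 199, seed: int = 0) -> pd.DataFrame:
    """Temporal progression of a bias, averaged in fixed-size trial bins.

    Trials are ordered within each sign-constant run (the 3-block LT halves,
    with the bias sign-aligned by negating leftward-half values before
    pooling; the whole ST session), then grouped into ``n_bins`` bins of
    ``increment`` consecutive trials (defaults 5 for LT, 9 for ST; trials
    beyond ``n_bins * increment`` are dropped).  The CI is a hybrid (basic)
    bootstrap over subjects with ``n_boot`` resamples.
    """
    if increment is None:
        increment = 5 if paradigm == "LT" else 9
    df = bias[bias.paradigm == paradigm].copy() if "paradigm" in bias.columns else bias.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    if paradigm == "LT":
        df["half"] = np.where(df.block <= 3, "L", "R")
        df["signed"] = np.where(df.half == "L", -df[value], df[value])
        grouping = ["subject", "half"]
    else:
        df["signed"] = df[value]
        grouping = ["subject"]
    df = df.sort_values("trial_index")
    df["pos"] = df.groupby(grouping).cumcount()
    per_group = int(df.groupby(grouping)["pos"].max().min()) + 1
    if per_group < n_bins * increment:
        raise ValueError(
            f"only {per_group} trials per run; need {n_bins * increment} "
            f"for {n_bins} bins of {increment}")
    df["bin"] = df["pos"] // increment
    df = df[df["bin"] < n_bins]

    subj_bin = df.groupby(["subject", "bin"])["signed"].mean().unstack("bin")
    mean = subj_bin.mean(axis=0)
    rng = np.random.default_rng(seed)
    n_subj = subj_bin.shape[0]
    if n_subj > 1:
        idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
        boots = subj_bin.to_numpy()[idx].mean(axis=1)
    else:  # single subject: bootstrap over trials within bins
        boots = np.stack([
            df.sample(frac=1.0, replace=True, random_state=rng.integers(2**31))
            .groupby("bin")["signed"].mean().reindex(range(n_bins)).to_numpy()
            for _ in range(n_boot)])
    # hybrid/basic bootstrap: 2*estimate - percentile
    lo = 2.0 * mean.to_numpy() - np.nanpercentile(boots, 97.5, axis=0)
    hi = 2.0 * mean.to_numpy() - np.nanpercentile(boots, 2.5, axis=0)
    return pd.DataFrame({"bin": mean.index.to_numpy(), "mean": mean.to_numpy(),
                         "ci_low": lo, "ci_high": hi})


def per_dva_tests(bias: pd.DataFrame, value: str | None = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Signed-rank test of the subject-mean bias against 0 per ΔVA level.

    Two-sided Wilcoxon signed-rank on the per-subject mean bias at each of
    the six discrepancies, Holm-adjusted across the family.
    """
    if value is None:
        value = "vae" if "vae" in bias.columns else "ve"
    if "subject" not in bias.columns or bias.subject.nunique() < 2:
        raise ValueError("need >= 2 subjects")
    means = bias.groupby(["delta_va", "subject"])[value].mean()
    rows = []
    for dva, sub in means.groupby(level="delta_va"):
        x = sub.to_numpy()
        if np.allclose(x, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(x, alternative="two-sided").pvalue)
        rows.append((dva, x.mean(), p))
    out = pd.DataFrame(rows, columns=["delta_va", "mean", "p"])
    rej, p_adj, _, _ = multipletests(out.p, alpha=alpha, method="holm")
    out["p_holm"] = p_adj
    out["significant"] = rej
    return out


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]
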