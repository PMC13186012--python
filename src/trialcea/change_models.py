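"""Per-wave change-from-baseline models and responder/remitter contrasts.

The clinical estimand is the between-arm difference in change from baseline
at each follow-up wave, from a repeated-measures linear model with
categorical time, a saturated arm-by-wave mean structure (each arm keeps its
own baseline; no equality constraint) and a subject-level random intercept,
fitted by maximum likelihood on all available rows (likelihood-based MAR
handling).  With complete data this reduces to differences of raw arm-wave
means, which is the oracle the tests use.

Cohen's d is reported two ways, mirroring the distinction between
change-score standardisation (between-arm change difference over the pooled
baseline SD) and endpoint standardisation (over the model-implied follow-up
SD); the standardiser used is always reported alongside d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from trialcea.data_model import FOLLOWUP_WAVES, WAVES, TrialDataset

Z95 = stats.norm.ppf(0.975)


class EstimationError(RuntimeError):
    """The change model could not be estimated."""


@dataclass
class WaveContrast:
    """Between-arm difference in change from baseline at one wave."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class EffectSize:
    d_change: float
    d_endpoint: float
    standardiser_change: float  # pooled baseline SD
    standardiser_endpoint: float  # model-implied follow-up SD


@dataclass
class ChangeModelFit:
    outcome: str
    waves: list[str]
    change: dict[str, dict[str, float]]  # arm -> wave -> change from baseline
    contrasts: dict[str, WaveContrast]  # wave -> dCBT-I minus PE
    effect_sizes: dict[str, EffectSize] = field(default_factory=dict)
    var_intercept: float = float("nan")
    var_residual: float = float("nan")
    n_per_wave: dict[str, int] = field(default_factory=dict)
    robust: bool = False

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "waves": self.waves,
            "change": self.change,
            "contrasts": {
                w: vars(c) for w, c in self.contrasts.items()
            },
            "effect_sizes": {w: vars(e) for w, e in self.effect_sizes.items()},
            "var_intercept": self.var_intercept,
            "var_residual": self.var_residual,
            "n_per_wave": self.n_per_wave,
            "robust": self.robust,
        }


def _cluster_sandwich(result, df: pd.DataFrame) -> np.ndarray:
    """Cluster-robust (sandwich) covariance of the fixed effects of a fitted
    random-intercept model, with the variance components held at their ML
    estimates."""
    model = result.model
    X = model.exog
    y = model.endog
    groups = np.asarray(model.groups)
    beta = result.fe_params.to_numpy()
    tau2 = float(np.asarray(result.cov_re)[0, 0])
    sig2 = float(result.scale)
    r = y - X @ beta
    k = X.shape[1]
    A = np.zeros((k, k))
    B = np.zeros((k, k))
    for _, idx in pd.Series(np.arange(len(y))).groupby(groups).groups.items():
        idx = np.asarray(idx)
        Xi, ri = X[idx], r[idx]
        ni = len(idx)
        # V^{-1} = (I - J tau2/(sig2 + ni tau2)) / sig2, via Woodbury
        c = tau2 / (sig2 + ni * tau2)
        XtVi = (Xi.T - c * np.outer(Xi.sum(axis=0), np.ones(ni))) / sig2
        A += XtVi @ Xi
        u = XtVi @ ri
        B += np.outer(u, u)
    Ainv = np.linalg.inv(A)
    return Ainv @ B @ Ainv


def fit_change_model(
    data: TrialDataset, outcome: str, robust: bool = False
) -> ChangeModelFit:
    """Fit the repeated-measures random-intercept change model for one outcome.

    Parameters
    ----------
    robust
        If True, report cluster-robust (sandwich) standard errors instead of
        the model-based ones.
    """
    df = data.df[["participant_id", "arm", "wave", outcome]].dropna(subset=[outcome])
    df = df.rename(columns={outcome: "y"}).copy()
    waves_present = [w for w in WAVES if (df["wave"] == w).any()]
    followups = [w for w in waves_present if w != "baseline"]
    if not followups:
        raise EstimationError(f"no follow-up observations for outcome {outcome!r}")
    df["wave"] = pd.Categorical(df["wave"].astype(str), categories=waves_present)

    formula = "y ~ C(arm, Treatment(reference='PE')) * C(wave)"
    model = smf.mixedlm(formula, df, groups=df["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            result = model.fit(reml=False)
        except np.linalg.LinAlgError:
            # retry from an inflated residual-variance start point
            try:
                result = model.fit(reml=False, start_params=None, method="powell")
            except Exception as exc:  # pragma: no cover - degenerate data
                raise EstimationError(f"change model failed for {outcome!r}: {exc}") from exc

    params = result.fe_params
    cov = (
        _cluster_sandwich(result, df)
        if robust
        else result.cov_params().iloc[: len(params), : len(params)].to_numpy()
    )
    names = list(params.index)

    def ix(name: str) -> int:
        return names.index(name)

    arm_key = "C(arm, Treatment(reference='PE'))[T.dCBT-I]"
    change = {"dCBT-I": {}, "PE": {}}
    contrasts: dict[str, WaveContrast] = {}
    for w in followups:
        wave_key = f"C(wave)[T.{w}]"
        inter_key = f"{arm_key}:{wave_key}"
        pe_change = float(params[wave_key])
        diff = float(params[inter_key])
        change["PE"][w] = pe_change
        change["dCBT-I"][w] = pe_change + diff
        se = float(np.sqrt(cov[ix(inter_key), ix(inter_key)]))
        p = 2 * stats.norm.sf(abs(diff) / se) if se > 0 else (0.0 if diff else 1.0)
        contrasts[w] = WaveContrast(
            estimate=diff,
            se=se,
            ci_low=diff - Z95 * se,
            ci_high=diff + Z95 * se,
            p=p,
        )

    tau2 = float(np.asarray(result.cov_re)[0, 0])
    sig2 = float(result.scale)
    fit = ChangeModelFit(
        outcome=outcome,
        waves=waves_present,
        change=change,
        contrasts=contrasts,
        var_intercept=tau2,
        var_residual=sig2,
        n_per_wave={w: int((df["wave"] == w).sum()) for w in waves_present},
        robust=robust,
    )

    # effect sizes: change-score (pooled baseline SD) and endpoint
    base = data.df[data.df["wave"] == "baseline"][["arm", outcome]].dropna()
    sd_end = float(np.sqrt(tau2 + sig2))
    g = base.groupby("arm")[outcome]
    if g.ngroups == 2 and (g.count() >= 2).all():
        s = g.std()
        n = g.count()
        sd_base = pooled_sd(s.iloc[0], int(n.iloc[0]), s.iloc[1], int(n.iloc[1]))
        for w, c in contrasts.items():
            fit.effect_sizes[w] = EffectSize(
                d_change=c.estimate / sd_base if sd_base > 0 else float("nan"),
                d_endpoint=c.estimate / sd_end if sd_end > 0 else float("nan"),
                standardiser_change=sd_base,
                standardiser_endpoint=sd_end,
            )
    return fit


def pooled_sd(s1: float, n1: int, s2: float, n2: int) -> float:
    return float(np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)))


def cohens_d_change(diff: float, s1: float, n1: int, s2: float, n2: int) -> EffectSize:
    """Standardise a between-arm change difference by the pooled baseline SD.

    pooled SD = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)); d = diff / pooled.
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per arm")
    sd = pooled_sd(s1, n1, s2, n2)
    d = diff / sd
    return EffectSize(
        d_change=d, d_endpoint=float("nan"), standardiser_change=sd,
        standardiser_endpoint=float("nan"),
    )


def newcombe_diff_ci(
    x1: int, n1: int, x2: int, n2: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Difference in proportions p1 - p2 with the Newcombe hybrid score CI
    assembled from the per-arm Wilson limits."""
    p1, p2 = x1 / n1, x2 / n2
    l1, u1 = proportion_confint(x1, n1, alpha=alpha, method="wilson")
    l2, u2 = proportion_confint(x2, n2, alpha=alpha, method="wilson")
    d = p1 - p2
    lower = d - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = d + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return d, float(lower), float(upper)


def is_responder(isi_baseline: float, isi_wave: float) -> bool:
    """Response: a reduction of at least 8 ISI points from baseline."""
    return (isi_baseline - isi_wave) >= 8


def is_remitter(isi_wave: float) -> bool:
    """Remission: wave ISI score below 8."""
    return isi_wave < 8


@dataclass
class ProportionContrast:
    criterion: str
    wave: str
    counts: dict[str, int]
    totals: dict[str, int]
    proportions: dict[str, float]
    diff: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float


def response_remission(data: TrialDataset, wave: str) -> dict[str, ProportionContrast]:
    """Observed-case response/remission contrast (dCBT-I minus PE) at a wave.

    Pearson chi-square (no continuity correction) for the test, Newcombe
    hybrid score interval for the difference in proportions.
    """
    if wave not in FOLLOWUP_WAVES:
        raise ValueError(f"wave must be a follow-up wave, got {wave!r}")
    isi = data.wide("isi")
    arm = data.arm_of()
    ok = isi["baseline"].notna() & isi[wave].notna()
    out: dict[str, ProportionContrast] = {}
    for criterion in ("response", "remission"):
        if criterion == "response":
            hit = (isi.loc[ok, "baseline"] - isi.loc[ok, wave]) >= 8
        else:
            hit = isi.loc[ok, wave] < 8
        counts, totals, props = {}, {}, {}
        for a in ("dCBT-I", "PE"):
            ids = arm.index[arm == a]
            sub = hit.reindex(ids).dropna()
            if len(sub) == 0:
                raise EstimationError(f"no observed cases in arm {a} at wave {wave}")
            counts[a] = int(sub.sum())
            totals[a] = int(len(sub))
            props[a] = counts[a] / totals[a]
        table = np.array(
            [
                [counts["dCBT-I"], totals["dCBT-I"] - counts["dCBT-I"]],
                [counts["PE"], totals["PE"] - counts["PE"]],
            ]
        )
        if table[:, 0].sum() in (0, table.sum()):  # degenerate: all same outcome
            chi2_stat, p = 0.0, 1.0
        else:
            chi2_stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        d, lo, hi = newcombe_diff_ci(
            counts["dCBT-I"], totals["dCBT-I"], counts["PE"], totals["PE"]
        )
        out[criterion] = ProportionContrast(
            criterion=criterion,
            wave=wave,
            counts=counts,
            totals=totals,
            proportions=props,
            diff=d,
            ci_low=lo,
            ci_high=hi,
            chi2=float(chi2_stat),
            p=float(p),
        )
    return out
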