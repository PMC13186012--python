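"""Missing-data sensitivity machinery.

Three layers, mirroring the trial's sensitivity programme for the 2-year
insomnia outcome:

* **Pattern-mixture models.**  Participants are stratified by missingness
  pattern ("complete" = outcome observed at both the 6-month and 2-year
  follow-ups), optionally crossed with treatment arm, the change model is
  fitted per stratum on available data, and the overall effect is the
  stratum-proportion-weighted average.
* **Delta-adjusted tipping point.**  Missing 2-year outcomes are multiply
  imputed under MAR, an additive departure δ (in outcome points) is applied
  to the *imputed* values of one arm only, the between-arm 2-year change
  difference is re-estimated and Rubin-pooled per δ, and δ* is the smallest
  grid value at which significance is lost.  Because δ shifts a fixed set of
  imputed cells, the completed-data estimate is exactly linear in δ (slope =
  imputed fraction of the shifted arm), so the whole grid is evaluated from
  one fit per imputation.
* **Multiple imputation.**  Chained equations with predictive mean matching
  (k nearest donors, type-1 matching with a posterior draw of the regression
  coefficients), run separately per arm, visit order by increasing
  missingness, fixed iteration count, fully seeded; pooled with Rubin's
  rules using the Barnard–Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from trialcea.change_models import Z95, ChangeModelFit, EstimationError, fit_change_model
from trialcea.data_model import ARMS, WAVES, TrialDataset

#: follow-up waves defining pattern "completeness"
PATTERN_WAVES: tuple[str, str] = ("6mo", "2yr")

#: outcome variables entering the default chained-equations model
DEFAULT_MI_VARIABLES: tuple[str, ...] = (
    "isi", "bis", "hads", "cfq", "sf6d",
    "gp_visit", "psychiatrist_visit", "specialist_visit", "sleepmed_use",
)


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    estimate: float
    within: float
    between: float
    total: float
    df: float
    ci_low: float
    ci_high: float
    p: float
    m: int


def rubin_pool(
    estimates, within_variances, m: int | None = None, df_complete: float | None = None
) -> PooledEstimate:
    """Combine per-imputation estimates with Rubin's rules.

    Q̄ = mean(Q_j); B = between-imputation variance; T = W̄ + (1 + 1/m)B.
    Degrees of freedom follow Barnard–Rubin when a complete-data df is
    supplied, else the classic large-sample formula.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(within_variances, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and within_variances must have equal length")
    m = int(m if m is not None else len(q))
    if m < 2 or len(q) != m:
        raise ValueError("need m >= 2 imputations matching the estimates")
    qbar = float(q.mean())
    wbar = float(w.mean())
    b = float(q.var(ddof=1))
    t = wbar + (1 + 1 / m) * b
    if b == 0.0 or t == 0.0:
        df = float("inf")
    else:
        lam = (1 + 1 / m) * b / t
        df_old = (m - 1) / lam**2
        if df_complete is None or not np.isfinite(df_complete):
            df = df_old
        else:
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = np.sqrt(t)
    if se == 0:
        ci_low = ci_high = qbar
        p = 0.0 if qbar != 0 else 1.0
    else:
        tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else Z95
        ci_low, ci_high = qbar - tcrit * se, qbar + tcrit * se
        if np.isfinite(df):
            p = float(2 * stats.t.sf(abs(qbar) / se, df))
        else:
            p = float(2 * stats.norm.sf(abs(qbar) / se))
    return PooledEstimate(
        estimate=qbar, within=wbar, between=b, total=t, df=float(df),
        ci_low=float(ci_low), ci_high=float(ci_high), p=p, m=m,
    )


# ---------------------------------------------------------------------------
# Pattern-mixture models
# ---------------------------------------------------------------------------

@dataclass
class PatternStratification:
    scheme: str  # "completeness" | "completeness×arm"
    assignment: pd.Series  # participant_id -> stratum label
    weights: dict[str, float]  # stratum proportions of the randomised sample


def stratify_patterns(
    data: TrialDataset, outcome: str, scheme: str = "completeness"
) -> PatternStratification:
    """Assign each participant to a missingness-pattern stratum.

    "complete" means the outcome is observed at both follow-ups entering the
    sensitivity analysis (6 months and 2 years)."""
    if scheme not in ("completeness", "completeness×arm"):
        raise ValueError(f"unknown scheme {scheme!r}")
    wide = data.wide(outcome)
    complete = wide[list(PATTERN_WAVES)].notna().all(axis=1)
    labels = complete.map({True: "complete", False: "incomplete"})
    if scheme == "completeness×arm":
        arm = data.arm_of().reindex(labels.index)
        labels = arm.str.cat(labels, sep="/")
    weights = (labels.value_counts() / len(labels)).to_dict()
    return PatternStratification(scheme=scheme, assignment=labels, weights=weights)


def _single_arm_changes(data: TrialDataset, outcome: str) -> dict[str, tuple[float, float]]:
    """Change-from-baseline (estimate, SE) per follow-up wave for a one-arm
    subset, from a wave-only random-intercept model."""
    df = data.df[["participant_id", "wave", outcome]].dropna(subset=[outcome])
    df = df.rename(columns={outcome: "y"}).copy()
    waves_present = [w for w in WAVES if (df["wave"] == w).any()]
    followups = [w for w in waves_present if w != "baseline"]
    if not followups:
        raise EstimationError("no follow-up data in stratum")
    df["wave"] = pd.Categorical(df["wave"].astype(str), categories=waves_present)
    model = smf.mixedlm("y ~ C(wave)", df, groups=df["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(reml=False)
    out = {}
    for w in followups:
        key = f"C(wave)[T.{w}]"
        out[w] = (float(res.fe_params[key]), float(res.bse_fe[key]))
    return out


@dataclass
class PMMEstimate:
    wave: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class PMMReport:
    scheme: str
    outcome: str
    weights: dict[str, float]
    stratum_estimates: dict  # stratum -> wave -> dict
    weighted: dict[str, PMMEstimate]  # wave -> weighted-average contrast
    fallbacks: list[str] = field(default_factory=list)


def pmm_weighted_estimate(
    data: TrialDataset,
    outcome: str,
    scheme: str = "completeness",
    waves: tuple[str, ...] = PATTERN_WAVES,
) -> PMMReport:
    """Pattern-mixture estimate of the between-arm change differences.

    Under the ``completeness`` scheme the arm-by-wave change model is fitted
    within each pattern stratum and the between-arm differences are averaged
    with stratum-proportion weights.  Under ``completeness×arm`` each
    arm-pattern cell contributes its own change trajectory; arm-level changes
    are averaged across that arm's pattern strata (weights renormalised
    within arm) and the contrast is the difference of the averaged changes.
    Stratum SEs combine under independence: sqrt(sum of (weight × SE)^2).
    A stratum whose model is inestimable falls back to the overall-model
    estimate and is flagged.
    """
    strat = stratify_patterns(data, outcome, scheme)
    overall = fit_change_model(data, outcome)
    report = PMMReport(
        scheme=scheme, outcome=outcome, weights=strat.weights,
        stratum_estimates={}, weighted={},
    )

    if scheme == "completeness":
        per_stratum: dict[str, dict[str, tuple[float, float]]] = {}
        for stratum in strat.weights:
            ids = strat.assignment.index[strat.assignment == stratum]
            sub = data.subset(ids)
            try:
                fit = fit_change_model(sub, outcome)
                per_stratum[stratum] = {
                    w: (fit.contrasts[w].estimate, fit.contrasts[w].se)
                    for w in waves if w in fit.contrasts
                }
            except (EstimationError, KeyError):
                per_stratum[stratum] = {}
            for w in waves:
                if w not in per_stratum[stratum]:
                    per_stratum[stratum][w] = (
                        overall.contrasts[w].estimate, overall.contrasts[w].se,
                    )
                    report.fallbacks.append(f"{stratum}:{w}")
        report.stratum_estimates = {
            s: {w: {"estimate": e, "se": se} for w, (e, se) in d.items()}
            for s, d in per_stratum.items()
        }
        for w in waves:
            est = sum(strat.weights[s] * per_stratum[s][w][0] for s in strat.weights)
            var = sum(
                (strat.weights[s] * per_stratum[s][w][1]) ** 2 for s in strat.weights
            )
            report.weighted[w] = _pmm_estimate(w, est, np.sqrt(var))
        return report

    # completeness×arm: average each arm's change across its pattern strata
    arm_changes: dict[str, dict[str, tuple[float, float]]] = {}
    for arm in ARMS:
        strata = [s for s in strat.weights if s.startswith(f"{arm}/")]
        wsum = sum(strat.weights[s] for s in strata)
        acc = {w: [0.0, 0.0] for w in waves}
        for s in strata:
            ids = strat.assignment.index[strat.assignment == s]
            sub = data.subset(ids)
            try:
                changes = _single_arm_changes(sub, outcome)
            except EstimationError:
                changes = {}
            wgt = strat.weights[s] / wsum
            for w in waves:
                if w in changes:
                    e, se = changes[w]
                else:
                    e = overall.change[arm][w]
                    se = overall.contrasts[w].se  # conservative stand-in
                    report.fallbacks.append(f"{s}:{w}")
                acc[w][0] += wgt * e
                acc[w][1] += (wgt * se) ** 2
            report.stratum_estimates[s] = {
                w: {"estimate": changes.get(w, (np.nan, np.nan))[0],
                    "se": changes.get(w, (np.nan, np.nan))[1]}
                for w in waves
            }
        arm_changes[arm] = {w: (acc[w][0], np.sqrt(acc[w][1])) for w in waves}
    for w in waves:
        est = arm_changes["dCBT-I"][w][0] - arm_changes["PE"][w][0]
        se = float(np.hypot(arm_changes["dCBT-I"][w][1], arm_changes["PE"][w][1]))
        report.weighted[w] = _pmm_estimate(w, est, se)
    return report


def _pmm_estimate(wave: str, est: float, se: float) -> PMMEstimate:
    se = float(se)
    p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else (0.0 if est else 1.0)
    return PMMEstimate(
        wave=wave, estimate=float(est), se=se,
        ci_low=float(est - Z95 * se), ci_high=float(est + Z95 * se), p=p,
    )


# ---------------------------------------------------------------------------
# Chained-equations multiple imputation with predictive mean matching
# ---------------------------------------------------------------------------

def _pmm_impute_column(
    X: np.ndarray, y: np.ndarray, miss: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """One PMM step: regress observed y on X, draw coefficients from their
    approximate posterior, match each missing case to the k observed donors
    with nearest predicted means, return y with missing entries filled by a
    uniformly drawn donor's observed value."""
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    n, p = Xo.shape
    ridge = 1e-8 * np.eye(p)
    xtx = Xo.T @ Xo + ridge
    beta = np.linalg.solve(xtx, Xo.T @ yo)
    resid = yo - Xo @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    beta_star = rng.multivariate_normal(beta, cov, method="svd")
    pred_obs = Xo @ beta
    pred_mis = X[miss] @ beta_star
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    out = y.copy()
    kk = min(k, n)
    # candidate window of 2k observed donors around each insertion point
    pos = np.searchsorted(sorted_pred, pred_mis)
    offsets = np.arange(-kk, kk)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n - 1)
    cand_idx = order[cand]  # (n_mis, 2k) indices into observed subset
    dist = np.abs(pred_obs[cand_idx] - pred_mis[:, None])
    nearest = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(kk, size=len(pred_mis))]
    donors = cand_idx[np.arange(len(pred_mis)), pick]
    out[miss] = yo[donors]
    return out


def _chained_pmm(
    wide: pd.DataFrame,
    impute_cols: list[str],
    k: int,
    iterations: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run chained equations with PMM on one (already arm-stratified) wide
    table; returns a completed copy."""
    work = wide.copy()
    miss_mask = {c: work[c].isna().to_numpy() for c in impute_cols}
    # visit order: increasing missingness fraction
    order = sorted(
        (c for c in impute_cols if miss_mask[c].any()),
        key=lambda c: miss_mask[c].mean(),
    )
    for c in order:
        obs = work[c].dropna().to_numpy()
        if len(obs) == 0:
            raise EstimationError(f"variable {c!r} has no observed values to initialise from")
        work.loc[miss_mask[c], c] = rng.choice(obs, size=int(miss_mask[c].sum()))
    predictors = [c for c in work.columns if work[c].notna().all() or c in impute_cols]
    for _ in range(iterations):
        for c in order:
            others = [p for p in predictors if p != c]
            X = np.column_stack(
                [np.ones(len(work))] + [work[p].to_numpy(float) for p in others]
            )
            y = work[c].to_numpy(float)
            work[c] = _pmm_impute_column(X, y, miss_mask[c], k, rng)
    return work


def _to_wide(data: TrialDataset, variables) -> tuple[pd.DataFrame, pd.Series]:
    base = data.df[data.df["wave"] == "baseline"].set_index("participant_id")
    cols = {"age": base["age"], "sex": base["sex"]}
    for v in variables:
        w = data.wide(v)
        for wave in WAVES:
            cols[f"{v}@{wave}"] = w[wave]
    wide = pd.DataFrame(cols)
    return wide, base["arm"]


def mi_impute(
    data: TrialDataset,
    m: int = 50,
    k: int = 5,
    variables=DEFAULT_MI_VARIABLES,
    by_arm: bool = True,
    iterations: int = 10,
    seed: int = 0,
) -> list[TrialDataset]:
    """Multiple imputation by chained equations with predictive mean matching.

    Returns ``m`` completed datasets.  Imputation is stratified by arm,
    variables are visited in order of increasing missingness, each incomplete
    variable is regressed on all others in the wide participant table (plus
    age and sex), and PMM draws the observed value of one of the ``k``
    nearest predicted-mean donors.  Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    variables = [v for v in variables]
    wide, arm = _to_wide(data, variables)
    impute_cols = [c for c in wide.columns if "@" in c]
    for c in impute_cols:
        if wide[c].isna().all():
            raise EstimationError(f"variable {c!r} has no observed values")
    seeds = np.random.SeedSequence(seed).spawn(m)
    completed: list[TrialDataset] = []
    for j in range(m):
        rng = np.random.default_rng(seeds[j])
        parts = []
        arm_w = arm.reindex(wide.index)
        groups = [wide[(arm_w == a).to_numpy()] for a in ARMS] if by_arm else [wide]
        for g in groups:
            parts.append(_chained_pmm(g, impute_cols, k, iterations, rng))
        filled = pd.concat(parts).reindex(wide.index)
        df = data.df.copy()
        for v in variables:
            for wave in WAVES:
                col = f"{v}@{wave}"
                vals = filled[col]
                rows = df["wave"] == wave
                df.loc[rows, v] = df.loc[rows, "participant_id"].map(vals).to_numpy()
        completed.append(TrialDataset(df))
    return completed


# ---------------------------------------------------------------------------
# Delta-adjusted tipping point
# ---------------------------------------------------------------------------

@dataclass
class TippingPointResult:
    outcome: str
    shifted_arm: str
    delta_grid: np.ndarray
    estimates: np.ndarray  # pooled estimate per delta
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    delta_star: float | None  # smallest grid delta with p >= 0.05; None if beyond grid
    estimate_at_star: float | None
    mar_estimate: float
    imputed_fraction: float


def tipping_point(
    data: TrialDataset,
    outcome: str = "isi",
    delta_grid=None,
    shifted_arm: str = "dCBT-I",
    wave: str = "2yr",
    m: int = 20,
    seed: int = 0,
    mi_kwargs: dict | None = None,
) -> TippingPointResult:
    """Delta-adjusted MNAR tipping-point analysis (impute, shift, pool).

    Missing outcomes are multiply imputed under MAR; for each δ on the grid
    the imputed ``wave`` values of ``shifted_arm`` are worsened by δ points,
    the between-arm change difference at ``wave`` is re-estimated and pooled
    with Rubin's rules.  δ only moves already-imputed cells, so per
    imputation the completed-data estimate is linear in δ with slope equal
    to the imputed fraction of the shifted arm; the grid is evaluated in
    closed form from the δ = 0 fit of each imputation.
    """
    grid = np.asarray(
        np.arange(0.0, 3.0 + 1e-9, 0.01) if delta_grid is None else delta_grid, float
    )
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("delta grid must be non-negative and ascending")
    wide = data.wide(outcome)
    arm = data.arm_of()
    shifted_ids = arm.index[arm == shifted_arm]
    miss_frac = float(wide.loc[shifted_ids, wave].isna().mean())

    completed = mi_impute(data, m=m, seed=seed, **(mi_kwargs or {}))
    ests, variances = [], []
    for ds_j in completed:
        fit = fit_change_model(ds_j, outcome)
        c = fit.contrasts[wave]
        ests.append(c.estimate)
        variances.append(c.se**2)
    ests = np.asarray(ests)
    variances = np.asarray(variances)

    n_params = 8  # saturated two-arm four-wave mean structure
    df_com = max(data.n_participants - n_params, 1)
    est_grid = np.empty(len(grid))
    lo = np.empty(len(grid))
    hi = np.empty(len(grid))
    pv = np.empty(len(grid))
    for i, d in enumerate(grid):
        pooled = rubin_pool(ests + d * miss_frac, variances, m=m, df_complete=df_com)
        est_grid[i], lo[i], hi[i], pv[i] = (
            pooled.estimate, pooled.ci_low, pooled.ci_high, pooled.p,
        )
    crossed = np.nonzero(pv >= 0.05)[0]
    if len(crossed):
        i_star = int(crossed[0])
        delta_star: float | None = float(grid[i_star])
        est_star: float | None = float(est_grid[i_star])
    else:
        delta_star, est_star = None, None
    return TippingPointResult(
        outcome=outcome,
        shifted_arm=shifted_arm,
        delta_grid=grid,
        estimates=est_grid,
        ci_low=lo,
        ci_high=hi,
        p_values=pv,
        delta_star=delta_star,
        estimate_at_star=est_star,
        mar_estimate=float(est_grid[0]),
        imputed_fraction=miss_frac,
    )


def pooled_change_contrast(
    completed: list[TrialDataset], outcome: str, wave: str, df_complete: float | None = None
) -> PooledEstimate:
    """Fit the change model on each completed dataset and Rubin-pool the
    between-arm change difference at one wave."""
    ests, variances = [], []
    for ds in completed:
        fit = fit_change_model(ds, outcome)
        c = fit.contrasts[wave]
        ests.append(c.estimate)
        variances.append(c.se**2)
    return rubin_pool(ests, variances, m=len(completed), df_complete=df_complete)
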