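"""QALYs, perspective-specific costs, bootstrapped ICER/CEAC and scenario
analyses for the within-trial cost-utility analysis.

QALYs are the area under the piecewise-linear SF-6D utility curve over the
trial horizon (trapezoid rule, no discounting); participants missing
intermediate waves contribute their observed points only.  Costs are built
per participant from four components — programme, medical (GP, psychiatrist
and other specialist outpatient visits, sleep medication), productivity
(absenteeism and presenteeism valued at the national mean wage,
human-capital approach, employed participants only) and out-of-pocket — in
2019 NOK converted to euros at the configured rate.  Perspectives are masks
over these components: societal sums all four; healthcare keeps programme +
medical; employer keeps programme + productivity; patient keeps programme +
out-of-pocket.

Uncertainty around the ICER comes from non-parametric bootstrap resampling
of participants (stratified by arm, preserving each participant's cost-QALY
pairing), summarised as the cost-effectiveness plane and the
cost-effectiveness acceptability curve CEAC(λ) = P(λ·ΔE − ΔC ≥ 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from trialcea.data_model import (
    PERSPECTIVE_MASKS,
    WAVES,
    ConfigError,
    EconConfig,
    TrialDataset,
)

DAYS_PER_YEAR = 365.25
WEEKS_PER_YEAR = DAYS_PER_YEAR / 7.0
QUARTER_YEARS = 0.25

_COMPONENT_COLS = {
    "programme": ["programme"],
    "medical": ["gp", "psychiatrist", "specialist", "sleepmed"],
    "productivity": ["absenteeism", "presenteeism"],
    "out_of_pocket": ["out_of_pocket"],
}


def compute_qalys(utilities, times) -> float:
    """Trapezoid-rule area under one participant's utility curve.

    NaN utilities are skipped (piecewise-linear through observed points).
    Returns NaN when fewer than two points are observed.
    """
    u = np.asarray(utilities, dtype=float)
    t = np.asarray(times, dtype=float)
    if u.shape != t.shape:
        raise ValueError("utilities and times must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    ok = ~np.isnan(u)
    if ok.sum() < 2:
        return float("nan")
    return float(np.trapezoid(u[ok], t[ok]))


def qalys_per_participant(ds: TrialDataset, cfg: EconConfig) -> pd.Series:
    """Vector of per-participant QALYs over the trial horizon."""
    wide = ds.wide("sf6d")
    t = cfg.times
    return wide.apply(lambda row: compute_qalys(row.to_numpy(), t), axis=1).rename("qaly")


def _piecewise_linear_integral(values: np.ndarray, times: np.ndarray) -> float:
    """Integral of the piecewise-linear interpolant through observed points."""
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        if ok.sum() == 1:
            # single observation: carried flat over the full horizon
            return float(values[ok][0] * (times[-1] - times[0]))
        return float("nan")
    return float(np.trapezoid(values[ok], times[ok]))


def _left_constant_integral(values: np.ndarray, times: np.ndarray) -> float:
    """Integral carrying each observed value flat until the next observed wave."""
    ok = ~np.isnan(values)
    v, t = values[ok], times[ok]
    if len(v) == 0:
        return float("nan")
    if len(v) == 1:
        return float(v[0] * (times[-1] - times[0]))
    total = sum(v[i] * (t[i + 1] - t[i]) for i in range(len(v) - 1))
    # last observed value carried to the end of the horizon
    total += v[-1] * (times[-1] - t[-1])
    return float(total)


@dataclass
class CostLedgerEntry:
    """One participant's cost components, in EUR over the analysis horizon."""

    participant_id: str
    arm: str
    programme: float
    gp: float
    psychiatrist: float
    specialist: float
    sleepmed: float
    absenteeism: float
    presenteeism: float
    out_of_pocket: float

    def component(self, name: str) -> float:
        return float(sum(getattr(self, c) for c in _COMPONENT_COLS[name]))

    def total(self, perspective: str) -> float:
        return float(sum(self.component(c) for c in PERSPECTIVE_MASKS[perspective]))


def cost_components(ds: TrialDataset, cfg: EconConfig) -> pd.DataFrame:
    """Per-participant cost components (EUR), one row per participant.

    Visit indicators (3-month recall) become expected volumes through
    piecewise-linear quarterly visit probabilities anchored at the assessment
    waves and integrated over the horizon, times a configurable expected
    visit count per quarter.  Sleep-medication indicator days are valued at a
    per-day price; WPAI hours/week are carried piecewise-constant between
    waves and valued at the national mean hourly wage for employed
    participants.
    """
    uc = cfg.unit_costs
    needed = ["gp_visit", "psychiatrist_visit", "specialist_visit", "sleepmed_day"]
    missing = [k for k in needed if k not in uc]
    if missing:
        raise ConfigError(f"missing unit cost(s): {missing}")
    t = cfg.times
    arm = ds.arm_of()
    base = ds.df[ds.df["wave"] == "baseline"].set_index("participant_id")
    employed = base["employed"].fillna(0).astype(float)

    wide = {c: ds.wide(c) for c in (
        "gp_visit", "psychiatrist_visit", "specialist_visit", "sleepmed_use",
        "absenteeism_hours_wk", "presenteeism_hours_wk",
    )}
    pids = wide["gp_visit"].index
    rows = []
    for pid in pids:
        a = arm.loc[pid]
        visits = {}
        for res in ("gp_visit", "psychiatrist_visit", "specialist_visit"):
            integral = _piecewise_linear_integral(wide[res].loc[pid].to_numpy(float), t)
            volume = 0.0 if np.isnan(integral) else integral / QUARTER_YEARS * cfg.visits_per_quarter
            visits[res] = volume
        smd = _piecewise_linear_integral(wide["sleepmed_use"].loc[pid].to_numpy(float), t)
        sleepmed_days = 0.0 if np.isnan(smd) else smd * DAYS_PER_YEAR

        prod_nok = {}
        for col in ("absenteeism_hours_wk", "presenteeism_hours_wk"):
            if employed.loc[pid] != 1:
                prod_nok[col] = 0.0
                continue
            integral = _left_constant_integral(wide[col].loc[pid].to_numpy(float), t)
            hours = 0.0 if np.isnan(integral) else integral * WEEKS_PER_YEAR
            prod_nok[col] = hours * cfg.hourly_wage_nok

        oop_nok = visits["gp_visit"] * uc.get("copay_gp", 0.0) + (
            visits["psychiatrist_visit"] + visits["specialist_visit"]
        ) * uc.get("copay_specialist", 0.0)

        rows.append(
            {
                "participant_id": pid,
                "arm": a,
                "programme": cfg.programme_cost_eur[a],
                "gp": cfg.nok_to_eur(visits["gp_visit"] * uc["gp_visit"]),
                "psychiatrist": cfg.nok_to_eur(
                    visits["psychiatrist_visit"] * uc["psychiatrist_visit"]
                ),
                "specialist": cfg.nok_to_eur(visits["specialist_visit"] * uc["specialist_visit"]),
                "sleepmed": cfg.nok_to_eur(sleepmed_days * uc["sleepmed_day"]),
                "absenteeism": cfg.nok_to_eur(prod_nok["absenteeism_hours_wk"]),
                "presenteeism": cfg.nok_to_eur(prod_nok["presenteeism_hours_wk"]),
                "out_of_pocket": cfg.nok_to_eur(oop_nok),
            }
        )
    out = pd.DataFrame(rows).set_index("participant_id")
    for comp, cols in _COMPONENT_COLS.items():
        if comp not in out.columns:
            out[comp] = out[cols].sum(axis=1)
    return out


def cost_participant(ds: TrialDataset, participant_id: str, cfg: EconConfig,
                     perspective: str | None = None) -> CostLedgerEntry:
    """Cost ledger entry for one participant (convenience wrapper)."""
    sub = ds.subset([participant_id])
    row = cost_components(sub, cfg).loc[str(participant_id)]
    entry = CostLedgerEntry(
        participant_id=str(participant_id),
        arm=row["arm"],
        programme=row["programme"],
        gp=row["gp"],
        psychiatrist=row["psychiatrist"],
        specialist=row["specialist"],
        sleepmed=row["sleepmed"],
        absenteeism=row["absenteeism"],
        presenteeism=row["presenteeism"],
        out_of_pocket=row["out_of_pocket"],
    )
    return entry


def participant_totals(
    ds: TrialDataset, cfg: EconConfig, perspective: str | None = None
) -> pd.DataFrame:
    """Per-participant (cost, QALY) pairs for the chosen perspective."""
    perspective = perspective or cfg.perspective
    comp = cost_components(ds, cfg)
    cols = [c for name in PERSPECTIVE_MASKS[perspective] for c in _COMPONENT_COLS[name]]
    comp["cost"] = comp[cols].sum(axis=1)
    comp["qaly"] = qalys_per_participant(ds, cfg)
    comp["perspective"] = perspective
    return comp.reset_index()


@dataclass
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    cost_ci: tuple[float, float]
    qaly_ci: tuple[float, float]
    cost_p: float
    qaly_p: float
    arm_means: dict


def _mean_difference(totals: pd.DataFrame, col: str) -> tuple[float, tuple, float]:
    """dCBT-I minus PE group-mean difference with model-based (OLS) CI."""
    sub = totals.dropna(subset=[col])
    x = (sub["arm"] == "dCBT-I").astype(float)
    X = sm.add_constant(x.to_numpy())
    fit = sm.OLS(sub[col].to_numpy(), X).fit()
    ci = fit.conf_int()[1]
    return float(fit.params[1]), (float(ci[0]), float(ci[1])), float(fit.pvalues[1])


def incremental_analysis(totals: pd.DataFrame) -> IncrementalResult:
    """ΔC and ΔE (dCBT-I minus PE) from per-participant totals."""
    for a in ("dCBT-I", "PE"):
        if not (totals["arm"] == a).any():
            raise ValueError(f"arm {a!r} is empty")
    dc, cost_ci, cost_p = _mean_difference(totals, "cost")
    de, qaly_ci, qaly_p = _mean_difference(totals, "qaly")
    means = totals.groupby("arm")[["cost", "qaly"]].mean().to_dict("index")
    return IncrementalResult(
        delta_cost=dc, delta_qaly=de, cost_ci=cost_ci, qaly_ci=qaly_ci,
        cost_p=cost_p, qaly_p=qaly_p, arm_means=means,
    )


def _quadrant(dc: float, de: float) -> str:
    if dc < 0 and de > 0:
        return "dominant"
    if dc > 0 and de < 0:
        return "dominated"
    if dc >= 0 and de >= 0:
        return "trade-off NE"
    return "trade-off SW"


@dataclass
class CEResult:
    delta_cost: float
    delta_qaly: float
    icer: float
    icer_defined: bool
    quadrant: str
    replicates: pd.DataFrame  # columns delta_cost, delta_qaly
    ceac: dict[float, float]
    prob_cost_effective: float
    prob_dominant: float
    wtp_threshold: float

    def nmb(self, wtp: float) -> float:
        return wtp * self.delta_qaly - self.delta_cost


def ceac_curve(replicates: pd.DataFrame, wtp_grid) -> dict[float, float]:
    """CEAC(λ) = fraction of replicates with non-negative net monetary benefit."""
    dc = replicates["delta_cost"].to_numpy()
    de = replicates["delta_qaly"].to_numpy()
    return {
        float(lam): float(np.mean(lam * de - dc >= 0)) for lam in wtp_grid
    }


def bootstrap_cea(
    totals: pd.DataFrame,
    cfg: EconConfig,
    B: int | None = None,
    seed: int | None = None,
) -> CEResult:
    """Non-parametric bootstrap of (ΔC, ΔE), stratified by arm.

    Resampling is at the participant level with replacement, keeping each
    participant's cost-QALY pairing intact, so the joint uncertainty of the
    incremental pair is propagated to the CE plane and CEAC.
    """
    B = int(B if B is not None else cfg.bootstrap_reps)
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    sub = totals.dropna(subset=["cost", "qaly"])
    groups = {
        a: sub[sub["arm"] == a][["cost", "qaly"]].to_numpy() for a in ("dCBT-I", "PE")
    }
    for a, g in groups.items():
        if len(g) == 0:
            raise ValueError(f"arm {a!r} has no complete (cost, qaly) pairs")
    dc0 = float(groups["dCBT-I"][:, 0].mean() - groups["PE"][:, 0].mean())
    de0 = float(groups["dCBT-I"][:, 1].mean() - groups["PE"][:, 1].mean())

    reps = np.empty((B, 2))
    for b in range(B):
        means = {}
        for a, g in groups.items():
            idx = rng.integers(0, len(g), len(g))
            means[a] = g[idx].mean(axis=0)
        reps[b] = means["dCBT-I"] - means["PE"]
    replicates = pd.DataFrame(reps, columns=["delta_cost", "delta_qaly"])
    ceac = ceac_curve(replicates, cfg.wtp_grid_eur)
    lam = cfg.wtp_threshold_eur
    prob_ce = float(
        np.mean(lam * replicates["delta_qaly"] - replicates["delta_cost"] >= 0)
    )
    prob_dom = float(
        np.mean((replicates["delta_cost"] < 0) & (replicates["delta_qaly"] > 0))
    )
    defined = de0 != 0.0
    return CEResult(
        delta_cost=dc0,
        delta_qaly=de0,
        icer=dc0 / de0 if defined else float("nan"),
        icer_defined=defined,
        quadrant=_quadrant(dc0, de0),
        replicates=replicates,
        ceac=ceac,
        prob_cost_effective=prob_ce,
        prob_dominant=prob_dom,
        wtp_threshold=lam,
    )


# ---------------------------------------------------------------------------
# Deterministic sensitivity analyses
# ---------------------------------------------------------------------------

_SA_COMPONENTS = ("programme_cost_dCBT-I", "medical_costs_dCBT-I", "productivity_costs_dCBT-I")


@dataclass
class OneWayResult:
    component: str
    table: pd.DataFrame  # value -> icer
    threshold: float | None  # break-even price (programme) or max uplift factor
    threshold_defined: bool


def break_even_programme_price(
    delta_qaly: float, wtp: float, delta_cost_nonprog: float, programme_cost_pe: float
) -> float:
    """Largest dCBT-I programme price keeping ICER ≤ WTP (requires ΔE > 0):
    p* = c_PE + λ·ΔE − ΔC_nonprogramme."""
    if delta_qaly <= 0:
        raise ValueError("break-even price undefined for ΔE <= 0")
    return programme_cost_pe + wtp * delta_qaly - delta_cost_nonprog


def one_way_sa(
    totals: pd.DataFrame,
    cfg: EconConfig,
    vary: str,
    values,
) -> OneWayResult:
    """Recompute the ICER while varying one dCBT-I cost component.

    ``values`` are absolute programme prices (EUR) for the programme
    component, or multiplicative factors for medical/productivity costs.
    """
    if vary not in _SA_COMPONENTS:
        raise ValueError(f"vary must be one of {_SA_COMPONENTS}")
    tot = totals.dropna(subset=["cost", "qaly"]).copy()
    is_dcbt = tot["arm"] == "dCBT-I"
    de = float(tot.loc[is_dcbt, "qaly"].mean() - tot.loc[~is_dcbt, "qaly"].mean())
    dc_base = float(tot.loc[is_dcbt, "cost"].mean() - tot.loc[~is_dcbt, "cost"].mean())
    lam = cfg.wtp_threshold_eur

    rows = []
    threshold: float | None = None
    defined = de > 0
    if vary == "programme_cost_dCBT-I":
        p0 = cfg.programme_cost_eur["dCBT-I"]
        c_pe = cfg.programme_cost_eur["PE"]
        dc_nonprog = dc_base - (p0 - c_pe)
        for p in values:
            dc = dc_nonprog + (p - c_pe)
            rows.append({"value": p, "delta_cost": dc, "icer": dc / de if de else np.nan})
        if defined:
            threshold = break_even_programme_price(de, lam, dc_nonprog, c_pe)
    else:
        comp = "medical" if vary.startswith("medical") else "productivity"
        base_comp = float(tot.loc[is_dcbt, comp].mean())
        for f in values:
            dc = dc_base + (f - 1.0) * base_comp
            rows.append({"value": f, "delta_cost": dc, "icer": dc / de if de else np.nan})
        if defined and base_comp > 0:
            threshold = 1.0 + (lam * de - dc_base) / base_comp
    return OneWayResult(
        component=vary,
        table=pd.DataFrame(rows),
        threshold=threshold,
        threshold_defined=defined,
    )


def mnar_scenarios(
    totals: pd.DataFrame,
    cfg: EconConfig,
    qaly_cuts=(0.05, 0.10, 0.15, 0.20),
    cost_uplifts=(0.05, 0.10, 0.15, 0.20),
    B: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Conservative MNAR scenario grid: dCBT-I QALYs reduced by q and dCBT-I
    costs increased by c; ΔC, ΔE, ICER and P(cost-effective) recomputed per
    cell (q = c = 0 reproduces the base case)."""
    rows = []
    for q in qaly_cuts:
        for c in cost_uplifts:
            mod = totals.copy()
            mask = mod["arm"] == "dCBT-I"
            mod.loc[mask, "qaly"] = mod.loc[mask, "qaly"] * (1.0 - q)
            mod.loc[mask, "cost"] = mod.loc[mask, "cost"] * (1.0 + c)
            ce = bootstrap_cea(mod, cfg, B=B, seed=seed)
            rows.append(
                {
                    "qaly_cut": q,
                    "cost_uplift": c,
                    "delta_cost": ce.delta_cost,
                    "delta_qaly": ce.delta_qaly,
                    "icer": ce.icer,
                    "prob_cost_effective": ce.prob_cost_effective,
                    "quadrant": ce.quadrant,
                }
            )
    return pd.DataFrame(rows)
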