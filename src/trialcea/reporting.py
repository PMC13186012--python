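"""Pipeline orchestration: simulate → fit → sensitivity → mediate → cea.

A run executes the requested stages in dependency order under a single
top-level seed, fans out per-stage sub-seeds through
:func:`numpy.random.SeedSequence.spawn`, writes publication-style tables
(arm-level descriptives, change-model estimates, incremental cost/QALY
summaries) plus machine-readable JSON per stage, and records everything in
a manifest (seed, config hash, versions, file inventory) so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

import trialcea
from trialcea.change_models import fit_change_model, response_remission
from trialcea.data_model import EconConfig, TrialDataset, write_trial_csv
from trialcea.health_econ import (
    bootstrap_cea,
    incremental_analysis,
    mnar_scenarios,
    one_way_sa,
    participant_totals,
)
from trialcea.mediation import causal_mediation
from trialcea.missing_sensitivity import pmm_weighted_estimate, tipping_point
from trialcea.synthetic_trial import GeneratorConfig, apply_dropout, generate_trial

log = logging.getLogger("trialcea")

ALL_STAGES = ("simulate", "fit", "sensitivity", "mediate", "cea")

CLINICAL_OUTCOMES = ("isi", "bis", "hads", "cfq")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage sub-seeds (below 2^31) from one top seed."""
    children = np.random.SeedSequence(seed).spawn(len(ALL_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % 2**31)
        for stage, child in zip(ALL_STAGES, children)
    }


def _config_hash(obj) -> str:
    payload = json.dumps(
        dataclasses.asdict(obj), sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default, sort_keys=True))


def run_pipeline(
    out_dir: str | Path,
    gen_config: GeneratorConfig | None = None,
    econ_config: EconConfig | None = None,
    seed: int = 1,
    stages=ALL_STAGES,
    data: TrialDataset | None = None,
    tipping_m: int = 10,
    mediation_B: int = 1000,
) -> Path:
    """Run the analysis pipeline into ``out_dir`` and write a manifest.

    Either simulates a trial (``simulate`` stage) or analyses a supplied
    ``data``.  Any stage error aborts with the stage name in the exception.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    gcfg = gen_config or GeneratorConfig(seed=seeds["simulate"])
    ecfg = econ_config or EconConfig()
    manifest = {
        "seed": seed,
        "stage_seeds": seeds,
        "generator_config_hash": _config_hash(gcfg),
        "econ_config_hash": _config_hash(ecfg),
        "version": trialcea.__version__,
        "stages": list(stages),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": [],
    }

    def emit(name: str) -> Path:
        manifest["files"].append(name)
        return out / name

    try:
        if "simulate" in stages:
            log.info("stage simulate: generating synthetic trial")
            gcfg.seed = seeds["simulate"]
            complete = generate_trial(gcfg)
            data = apply_dropout(complete, gcfg)
            write_trial_csv(data, emit("trial.csv"))
            shadow = TrialDataset(data.shadow)
            write_trial_csv(shadow, emit("shadow.csv"))
        if data is None:
            raise ValueError("no data: include the simulate stage or pass data=")

        if "fit" in stages:
            log.info("stage fit: change models for %s", CLINICAL_OUTCOMES)
            fits = {o: fit_change_model(data, o) for o in CLINICAL_OUTCOMES}
            _write_json(emit("fit.json"), {o: f.to_dict() for o, f in fits.items()})
            rows = []
            for o, f in fits.items():
                for w, c in f.contrasts.items():
                    es = f.effect_sizes.get(w)
                    rows.append(
                        {
                            "outcome": o, "wave": w,
                            "change_dCBT-I": f.change["dCBT-I"][w],
                            "change_PE": f.change["PE"][w],
                            "estimate": c.estimate, "ci_low": c.ci_low,
                            "ci_high": c.ci_high, "p": c.p,
                            "cohens_d_change": es.d_change if es else np.nan,
                            "cohens_d_endpoint": es.d_endpoint if es else np.nan,
                        }
                    )
            pd.DataFrame(rows).to_csv(emit("table1.csv"), index=False)
            rr = response_remission(data, "2yr")
            _write_json(emit("response_remission.json"), {k: vars(v) for k, v in rr.items()})

        if "sensitivity" in stages:
            log.info("stage sensitivity: PMM1/PMM2 and tipping point")
            pmm1 = pmm_weighted_estimate(data, "isi", scheme="completeness")
            pmm2 = pmm_weighted_estimate(data, "isi", scheme="completeness×arm")
            tp = tipping_point(data, "isi", m=tipping_m, seed=seeds["sensitivity"])
            _write_json(
                emit("sens.json"),
                {
                    "pmm1": {w: vars(e) for w, e in pmm1.weighted.items()},
                    "pmm2": {w: vars(e) for w, e in pmm2.weighted.items()},
                    "tipping": {
                        "delta_star": tp.delta_star,
                        "estimate_at_star": tp.estimate_at_star,
                        "mar_estimate": tp.mar_estimate,
                        "imputed_fraction": tp.imputed_fraction,
                    },
                },
            )

        if "mediate" in stages:
            log.info("stage mediate: ISI@post -> HADS/CFQ @2yr")
            med = {}
            for out_col in ("hads", "cfq"):
                r = causal_mediation(
                    data,
                    outcome=(out_col, "2yr"),
                    B=mediation_B,
                    seed=seeds["mediate"],
                )
                med[out_col] = {
                    "acme": r.acme, "ade": r.ade, "total_effect": r.total_effect,
                    "proportion_mediated": r.proportion_mediated,
                    "acme_ci": r.acme_ci, "ade_ci": r.ade_ci,
                    "total_ci": r.total_ci, "n": r.n,
                    "full_mediation": r.full_mediation,
                }
            _write_json(emit("med.json"), med)

        if "cea" in stages:
            log.info("stage cea: costs, QALYs, bootstrap, scenarios")
            cea_dir = out / "cea"
            cea_dir.mkdir(exist_ok=True)
            totals = participant_totals(data, ecfg)
            inc = incremental_analysis(totals.dropna(subset=["qaly"]))
            ce = bootstrap_cea(totals, ecfg, seed=seeds["cea"])
            totals.to_csv(emit("cea/participant_totals.csv"), index=False)
            ce.replicates.to_csv(emit("cea/ce_plane.csv"), index=False)
            pd.DataFrame(
                {"wtp_eur": list(ce.ceac), "prob_cost_effective": list(ce.ceac.values())}
            ).to_csv(emit("cea/ceac.csv"), index=False)
            sa = one_way_sa(
                totals, ecfg, "programme_cost_dCBT-I",
                values=np.linspace(0, 1500, 31),
            )
            sa.table.to_csv(emit("cea/one_way_programme_cost.csv"), index=False)
            scen = mnar_scenarios(totals, ecfg, B=200, seed=seeds["cea"])
            scen.to_csv(emit("cea/mnar_scenarios.csv"), index=False)
            _write_json(
                emit("cea/summary.json"),
                {
                    "delta_cost": ce.delta_cost,
                    "delta_qaly": ce.delta_qaly,
                    "icer": ce.icer,
                    "quadrant": ce.quadrant,
                    "prob_cost_effective": ce.prob_cost_effective,
                    "prob_dominant": ce.prob_dominant,
                    "wtp_threshold": ce.wtp_threshold,
                    "delta_cost_ci": inc.cost_ci,
                    "delta_qaly_ci": inc.qaly_ci,
                    "break_even_programme_price": sa.threshold,
                },
            )
            _plot_cea(ce, cea_dir, manifest)

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_json(out / "manifest.json", manifest)
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc


def _plot_cea(ce, cea_dir: Path, manifest: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ce.replicates["delta_qaly"], ce.replicates["delta_cost"], s=4, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (EUR)")
    fig.tight_layout()
    fig.savefig(cea_dir / "ce_plane.png", dpi=120)
    plt.close(fig)
    manifest["files"].append("cea/ce_plane.png")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(list(ce.ceac), list(ce.ceac.values()))
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness-to-pay (EUR per QALY)")
    ax.set_ylabel("P(cost-effective)")
    fig.tight_layout()
    fig.savefig(cea_dir / "ceac.png", dpi=120)
    plt.close(fig)
    manifest["files"].append("cea/ceac.png")
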