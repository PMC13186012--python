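"""Counterfactual mediation of long-term outcomes through post-treatment
insomnia severity.

The decomposition follows the potential-outcomes framework with linear
mediator and outcome models:

    M = alpha_0 + a*T + alpha_X' X + e_M
    Y = beta_0 + c'*T + b*M + beta_X' X + e_Y

where T is the randomised arm (dCBT-I = 1), M the mediator (ISI at the
9-week wave), Y the distal outcome (HADS or CFQ at 2 years) and X the
age/sex covariates.  Without a treatment-mediator interaction the average
causal mediation effect is ACME = a*b, the average direct effect ADE = c',
and the total effect TE = ADE + ACME exactly; with an interaction the
arm-specific effects are averaged over the two arms.  Confidence intervals
are percentile bootstrap over participants.  Analysis is observed-case on
(T, M, Y, X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trialcea.data_model import WAVES, TrialDataset


class MediationError(ValueError):
    pass


@dataclass
class MediationResult:
    acme: float
    ade: float
    total_effect: float
    proportion_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    a_path: float
    b_path: float
    n: int
    B: int
    covariates: tuple[str, ...]
    interaction: bool

    @property
    def full_mediation(self) -> bool:
        """Descriptive flag: ADE interval covers 0 while ACME's excludes it."""
        return (
            self.ade_ci[0] <= 0.0 <= self.ade_ci[1]
            and not (self.acme_ci[0] <= 0.0 <= self.acme_ci[1])
        )


def _lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _effects(
    t: np.ndarray, m: np.ndarray, y: np.ndarray, X: np.ndarray, interaction: bool
) -> tuple[float, float, float, float, float]:
    """(ACME, ADE, TE, a, b) from the two linear fits on one (re)sample."""
    ones = np.ones_like(t)
    Xm = np.column_stack([ones, t, X])
    am = _lstsq(Xm, m)
    a = am[1]
    if interaction:
        Xy = np.column_stack([ones, t, m, t * m, X])
        by = _lstsq(Xy, y)
        cprime, b, theta = by[1], by[2], by[3]
        m0 = float((Xm @ am)[t == 0].mean()) if (t == 0).any() else float(m.mean())
        # arm-specific effects averaged over the two treatment levels
        acme = a * (b + theta * 0.5)
        ade = cprime + theta * (m0 + a * 0.5)
        te = a * b + a * theta + cprime + theta * m0
    else:
        Xy = np.column_stack([ones, t, m, X])
        by = _lstsq(Xy, y)
        cprime, b = by[1], by[2]
        acme = a * b
        ade = cprime
        te = acme + ade
    return float(acme), float(ade), float(te), float(a), float(b)


def causal_mediation(
    data: TrialDataset,
    mediator: tuple[str, str] = ("isi", "post"),
    outcome: tuple[str, str] = ("hads", "2yr"),
    covariates: tuple[str, ...] = ("age", "sex"),
    B: int = 1000,
    seed: int = 0,
    interaction: bool = False,
) -> MediationResult:
    """Counterfactual mediation decomposition with percentile bootstrap CIs.

    ``mediator`` and ``outcome`` are (column, wave) pairs; the mediator wave
    must precede the outcome wave.
    """
    med_col, med_wave = mediator
    out_col, out_wave = outcome
    if WAVES.index(med_wave) >= WAVES.index(out_wave):
        raise MediationError(
            f"mediator wave {med_wave!r} must precede outcome wave {out_wave!r}"
        )
    if B < 1:
        raise ValueError("B must be >= 1")

    arm = data.arm_of()
    base = data.df[data.df["wave"] == "baseline"].set_index("participant_id")
    frame = pd.DataFrame(
        {
            "t": (arm == "dCBT-I").astype(float),
            "m": data.wide(med_col)[med_wave],
            "y": data.wide(out_col)[out_wave],
        }
    )
    for c in covariates:
        frame[c] = base[c]
    frame = frame.dropna()
    n = len(frame)
    if n < len(covariates) + 4:
        raise MediationError("too few complete cases for mediation")
    t = frame["t"].to_numpy()
    m = frame["m"].to_numpy()
    y = frame["y"].to_numpy()
    X = frame[list(covariates)].to_numpy(float)
    if np.std(m) == 0:
        raise MediationError("mediator has zero variance")

    acme, ade, te, a, b = _effects(t, m, y, X, interaction)

    rng = np.random.default_rng(seed)
    boots = np.empty((B, 3))
    for i in range(B):
        idx = rng.integers(0, n, n)
        boots[i] = _effects(t[idx], m[idx], y[idx], X[idx], interaction)[:3]
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)

    return MediationResult(
        acme=acme,
        ade=ade,
        total_effect=te,
        proportion_mediated=acme / te if te != 0 else float("nan"),
        acme_ci=(float(lo[0]), float(hi[0])),
        ade_ci=(float(lo[1]), float(hi[1])),
        total_ci=(float(lo[2]), float(hi[2])),
        a_path=a,
        b_path=b,
        n=n,
        B=B,
        covariates=tuple(covariates),
        interaction=interaction,
    )
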