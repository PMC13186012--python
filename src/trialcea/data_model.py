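"""Core domain types, tabular I/O and configuration shared by all stages.

A trial is stored long-format: one row per participant per assessment wave.
``TrialDataset`` wraps a :class:`pandas.DataFrame` and enforces the
structural invariants every downstream stage assumes (one arm per
participant, a baseline row for everyone, no duplicate participant-wave
pairs, instrument scores within range).  Missing values are plain NaN /
empty CSV cells; absence is recorded, never silently imputed at ingest.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ARMS: tuple[str, str] = ("dCBT-I", "PE")
WAVES: tuple[str, ...] = ("baseline", "post", "6mo", "2yr")
FOLLOWUP_WAVES: tuple[str, ...] = WAVES[1:]

#: closed instrument / plausibility ranges, checked when a value is present
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "isi": (0, 28),
    "bis": (0, 42),
    "hads": (0, 42),
    "cfq": (0, 33),
    "sf6d": (0.29, 1.0),
    "age": (18, 110),
    "absenteeism_hours_wk": (0, 168),
    "presenteeism_hours_wk": (0, 168),
    "activity_impairment_pct": (0, 100),
}

BINARY_FIELDS: tuple[str, ...] = (
    "sex",
    "employed",
    "gp_visit",
    "psychiatrist_visit",
    "specialist_visit",
    "sleepmed_use",
)

MANDATORY_COLUMNS: tuple[str, ...] = ("participant_id", "arm", "wave")

OUTCOME_COLUMNS: tuple[str, ...] = (
    "isi",
    "bis",
    "hads",
    "cfq",
    "sf6d",
    "gp_visit",
    "psychiatrist_visit",
    "specialist_visit",
    "sleepmed_use",
    "absenteeism_hours_wk",
    "presenteeism_hours_wk",
    "activity_impairment_pct",
)

ALL_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "arm",
    "wave",
    "age",
    "sex",
    "employed",
) + OUTCOME_COLUMNS


class SchemaError(ValueError):
    """A file does not have the expected columns/structure."""


class IntegrityError(ValueError):
    """Rows violate dataset invariants; carries row-level diagnostics."""

    def __init__(self, diagnostics: Sequence[str]):
        self.diagnostics = list(diagnostics)
        preview = "; ".join(self.diagnostics[:10])
        more = "" if len(self.diagnostics) <= 10 else f" (+{len(self.diagnostics) - 10} more)"
        super().__init__(f"{len(self.diagnostics)} invariant violation(s): {preview}{more}")


class ConfigError(ValueError):
    """Economic or generator configuration violates its invariants."""


@dataclass
class ParticipantWaveRecord:
    """One participant at one assessment wave; None marks a missing value."""

    participant_id: str
    arm: str
    wave: str
    age: float | None = None
    sex: int | None = None
    employed: int | None = None
    isi: float | None = None
    bis: float | None = None
    hads: float | None = None
    cfq: float | None = None
    sf6d: float | None = None
    gp_visit: int | None = None
    psychiatrist_visit: int | None = None
    specialist_visit: int | None = None
    sleepmed_use: int | None = None
    absenteeism_hours_wk: float | None = None
    presenteeism_hours_wk: float | None = None
    activity_impairment_pct: float | None = None


def _row_diagnostics(df: pd.DataFrame) -> list[str]:
    diags: list[str] = []
    bad_arm = ~df["arm"].isin(ARMS)
    for idx in df.index[bad_arm]:
        diags.append(f"row {idx}: unknown arm {df.at[idx, 'arm']!r}")
    bad_wave = ~df["wave"].isin(WAVES)
    for idx in df.index[bad_wave]:
        diags.append(f"row {idx}: unknown wave {df.at[idx, 'wave']!r}")

    dup = df.duplicated(subset=["participant_id", "wave"], keep=False)
    for idx in df.index[dup]:
        diags.append(
            f"row {idx}: duplicate (participant, wave) = "
            f"({df.at[idx, 'participant_id']!r}, {df.at[idx, 'wave']!r})"
        )

    arms_per_pid = df.groupby("participant_id")["arm"].nunique()
    for pid in arms_per_pid.index[arms_per_pid > 1]:
        diags.append(f"participant {pid!r}: appears in more than one arm")

    has_baseline = df[df["wave"] == "baseline"]["participant_id"]
    missing_base = set(df["participant_id"]) - set(has_baseline)
    for pid in sorted(missing_base, key=str):
        diags.append(f"participant {pid!r}: no baseline row")

    for col, (lo, hi) in SCORE_RANGES.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        out = vals.notna() & ((vals < lo) | (vals > hi))
        for idx in df.index[out]:
            diags.append(f"row {idx}: {col} = {df.at[idx, col]} outside [{lo}, {hi}]")
    for col in BINARY_FIELDS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        out = vals.notna() & ~vals.isin([0, 1])
        for idx in df.index[out]:
            diags.append(f"row {idx}: {col} = {df.at[idx, col]} not in {{0, 1}}")
    return diags


@dataclass
class TrialDataset:
    """Long-format trial table with validated structure.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per (participant, wave); columns as in :data:`ALL_COLUMNS`
        (absent optional columns are added as NaN).
    shadow : pandas.DataFrame, optional
        The pre-dropout complete table, retained by
        :func:`trialcea.synthetic_trial.apply_dropout` for oracle testing.
    """

    df: pd.DataFrame
    shadow: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        for col in ALL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(ALL_COLUMNS)].reset_index(drop=True)
        df["participant_id"] = df["participant_id"].astype(str)
        for col in ALL_COLUMNS:
            if col not in MANDATORY_COLUMNS:
                df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        diags = _row_diagnostics(df)
        if diags:
            raise IntegrityError(diags)
        df["wave"] = pd.Categorical(df["wave"], categories=WAVES, ordered=True)
        self.df = df

    # -- convenience accessors -------------------------------------------------
    @property
    def participants(self) -> pd.Index:
        return pd.Index(self.df["participant_id"].unique())

    @property
    def n_participants(self) -> int:
        return self.df["participant_id"].nunique()

    def arm_of(self) -> pd.Series:
        """Series mapping participant_id -> arm label."""
        base = self.df[self.df["wave"] == "baseline"]
        return base.set_index("participant_id")["arm"]

    def wide(self, column: str) -> pd.DataFrame:
        """Pivot one outcome column to participants × waves."""
        w = self.df.pivot(index="participant_id", columns="wave", values=column)
        return w.reindex(columns=list(WAVES))

    def to_records(self) -> list[ParticipantWaveRecord]:
        recs = []
        for row in self.df.itertuples(index=False):
            kwargs = {}
            for f in dataclasses.fields(ParticipantWaveRecord):
                v = getattr(row, f.name)
                if isinstance(v, float) and math.isnan(v):
                    v = None
                kwargs[f.name] = v
            recs.append(ParticipantWaveRecord(**kwargs))
        return recs

    def subset(self, participant_ids: Iterable[str]) -> "TrialDataset":
        ids = set(map(str, participant_ids))
        return TrialDataset(self.df[self.df["participant_id"].isin(ids)].copy())


def read_trial_csv(path: str | Path, schema: Mapping[str, str] | None = None) -> TrialDataset:
    """Read a long-format trial CSV into a validated :class:`TrialDataset`.

    Parameters
    ----------
    schema
        Optional mapping of file column name -> canonical field name, for
        files whose headers differ from the canonical ones.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    return TrialDataset(df)


def write_trial_csv(ds: TrialDataset, path: str | Path) -> None:
    """Write the dataset long-format; missing values become empty cells."""
    out = ds.df.copy()
    out["wave"] = out["wave"].astype(str)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Economic configuration
# ---------------------------------------------------------------------------

DEFAULT_WAVE_TIMES: dict[str, float] = {
    # 9 weeks = 63 d; later follow-ups are anchored after the 9-week wave
    "baseline": 0.0,
    "post": 0.1725,
    "6mo": 0.6725,
    "2yr": 2.1725,
}

#: Unit costs in NOK. These are configurable placeholders for national-tariff
#: values that are not part of this package's calibrated quantities.
DEFAULT_UNIT_COSTS: dict[str, float] = {
    "gp_visit": 420.0,
    "psychiatrist_visit": 1050.0,
    "specialist_visit": 1050.0,
    "sleepmed_day": 2.0,
    "copay_gp": 155.0,
    "copay_specialist": 351.0,
}

PERSPECTIVES: tuple[str, ...] = ("societal", "healthcare", "employer", "patient")

#: cost components summed under each analytic perspective
PERSPECTIVE_MASKS: dict[str, tuple[str, ...]] = {
    "societal": ("programme", "medical", "productivity", "out_of_pocket"),
    "healthcare": ("programme", "medical"),
    "employer": ("programme", "productivity"),
    "patient": ("programme", "out_of_pocket"),
}


@dataclass
class EconConfig:
    """Unit costs, wage, currency, wave clock and CEA settings."""

    wave_times_years: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WAVE_TIMES))
    unit_costs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_UNIT_COSTS))
    hourly_wage_nok: float = 290.0
    nok_per_eur: float = 9.85
    programme_cost_eur: dict[str, float] = field(
        default_factory=lambda: {"dCBT-I": 70.16, "PE": 23.80}
    )
    wtp_grid_eur: list[float] = field(
        default_factory=lambda: [float(x) for x in range(0, 100001, 2500)]
    )
    wtp_threshold_eur: float = 30000.0
    bootstrap_reps: int = 1000
    rng_seed: int = 1
    perspective: str = "societal"
    visits_per_quarter: float = 1.0

    def __post_init__(self) -> None:
        wt = self.wave_times_years
        if set(wt) != set(WAVES):
            raise ConfigError(f"wave_times_years must define exactly {WAVES}")
        if wt["baseline"] != 0.0:
            raise ConfigError("baseline wave time must be 0")
        times = [wt[w] for w in WAVES]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError(f"wave times must be strictly increasing, got {times}")
        for name, c in {**self.unit_costs, **self.programme_cost_eur}.items():
            if c < 0:
                raise ConfigError(f"negative cost for {name!r}: {c}")
        if self.hourly_wage_nok < 0:
            raise ConfigError("hourly wage must be non-negative")
        if self.nok_per_eur <= 0:
            raise ConfigError("nok_per_eur must be positive")
        grid = list(map(float, self.wtp_grid_eur))
        if grid != sorted(grid):
            raise ConfigError("wtp_grid_eur must be sorted ascending")
        self.wtp_grid_eur = grid
        if self.perspective not in PERSPECTIVES:
            raise ConfigError(f"perspective must be one of {PERSPECTIVES}")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")

    @property
    def times(self) -> np.ndarray:
        """Wave times as an array ordered like :data:`WAVES`."""
        return np.array([self.wave_times_years[w] for w in WAVES])

    @property
    def horizon_years(self) -> float:
        return self.wave_times_years[WAVES[-1]]

    def nok_to_eur(self, nok: float | np.ndarray) -> float | np.ndarray:
        return nok / self.nok_per_eur

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def read_config(path: str | Path) -> EconConfig:
    """Read an :class:`EconConfig` from JSON, applying documented defaults."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top-level JSON value must be an object")
    known = {f.name for f in dataclasses.fields(EconConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    try:
        return EconConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
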