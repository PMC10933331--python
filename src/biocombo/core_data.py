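"""Data model and I/O for checkpoint-style insect mortality bioassays.

A bioassay here is a factorial exposure experiment: cohorts of larvae
receive a treatment (a pyrethrum dose, a *Beauveria bassiana* conidial
dose, a combination of the two, or a surfactant-only control) and the
cumulative number of dead individuals is recorded at a fixed schedule of
observation days.  The long-format table of per-replicate cumulative
counts is the universal input to every downstream analysis: interaction
classification, dose-response fitting and survival analysis all start
from a :class:`BioassayTable`.

Cumulative counts (rather than per-interval increments) are the stored
representation: day-14 proportional mortality and Kaplan-Meier event
intervals are both derived from the same numbers without reconciliation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_OBSERVATION_DAYS",
    "REQUIRED_COLUMNS",
    "SchemaError",
    "ValidationError",
    "TreatmentSpec",
    "BioassayTable",
    "read_bioassay",
    "write_bioassay",
    "proportional_mortality",
    "median_and_quartiles",
    "Quartiles",
]

#: Default observation schedule (days after exposure).
DEFAULT_OBSERVATION_DAYS: tuple[int, ...] = (1, 2, 4, 7, 10, 14)

#: Canonical CSV column order (UTF-8, header row, "." decimal separator).
REQUIRED_COLUMNS: tuple[str, ...] = (
    "treatment_label",
    "pyrethrum_ppm",
    "conidia_per_ml",
    "replicate",
    "day",
    "n_start",
    "n_dead_cum",
)


class SchemaError(ValueError):
    """An input file does not provide the required columns."""


class ValidationError(ValueError):
    """A table violates a bioassay invariant (counts, monotonicity...)."""


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment arm: a pyrethrum dose and/or a fungal conidia dose.

    ``(0, 0)`` denotes the vehicle control (0.01% Triton).  Labels must
    be unique within an experiment.
    """

    label: str
    pyrethrum_ppm: float = 0.0
    conidia_per_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.pyrethrum_ppm < 0 or self.conidia_per_ml < 0:
            raise ValueError(f"doses must be non-negative: {self}")

    @property
    def is_control(self) -> bool:
        return self.pyrethrum_ppm == 0 and self.conidia_per_ml == 0

    @property
    def is_combination(self) -> bool:
        return self.pyrethrum_ppm > 0 and self.conidia_per_ml > 0


class BioassayTable:
    """Validated long-format table of cumulative death counts.

    One row per (treatment, replicate, observation day).  Construction
    validates every invariant: counts within ``[0, n_start]``, cumulative
    deaths non-decreasing within a (treatment, replicate) series,
    constant ``n_start`` per series, and a consistent dose pair per
    treatment label.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = data.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["treatment_label"] = df["treatment_label"].astype(str)
        for col in ("pyrethrum_ppm", "conidia_per_ml"):
            df[col] = pd.to_numeric(df[col])
        for col in ("replicate", "day", "n_start", "n_dead_cum"):
            df[col] = pd.to_numeric(df[col], downcast=None).astype(int)
        df = df.sort_values(
            ["treatment_label", "replicate", "day"], kind="stable"
        ).reset_index(drop=True)
        self._df = df
        self._validate()

    def _validate(self) -> None:
        df = self._df
        bad = df[(df["n_dead_cum"] < 0) | (df["n_dead_cum"] > df["n_start"])]
        if not bad.empty:
            r = bad.iloc[0]
            raise ValidationError(
                f"n_dead_cum={r.n_dead_cum} outside [0, n_start={r.n_start}] "
                f"for treatment {r.treatment_label!r} replicate {r.replicate} "
                f"day {r.day}"
            )
        if df.duplicated(["treatment_label", "replicate", "day"]).any():
            raise ValidationError("duplicate (treatment, replicate, day) rows")
        for (label, rep), grp in df.groupby(["treatment_label", "replicate"]):
            if grp["n_start"].nunique() != 1:
                raise ValidationError(
                    f"n_start varies within treatment {label!r} replicate {rep}"
                )
            if (np.diff(grp["n_dead_cum"].to_numpy()) < 0).any():
                raise ValidationError(
                    "cumulative deaths decrease within treatment "
                    f"{label!r} replicate {rep}"
                )
        doses = df.groupby("treatment_label")[["pyrethrum_ppm", "conidia_per_ml"]]
        if (doses.nunique() != 1).any(axis=None):
            raise ValidationError("a treatment label maps to more than one dose pair")
        if (df[["pyrethrum_ppm", "conidia_per_ml"]] < 0).any(axis=None):
            raise ValidationError("doses must be non-negative")

    # -- accessors -----------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying long-format DataFrame (do not mutate)."""
        return self._df

    @property
    def observation_days(self) -> tuple[int, ...]:
        return tuple(int(d) for d in sorted(self._df["day"].unique()))

    @property
    def treatments(self) -> list[TreatmentSpec]:
        out = []
        for label, grp in self._df.groupby("treatment_label", sort=False):
            r = grp.iloc[0]
            out.append(
                TreatmentSpec(
                    label=label,
                    pyrethrum_ppm=float(r.pyrethrum_ppm),
                    conidia_per_ml=float(r.conidia_per_ml),
                )
            )
        return sorted(out, key=lambda t: (t.pyrethrum_ppm, t.conidia_per_ml, t.label))

    def equals(self, other: "BioassayTable") -> bool:
        return self._df.equals(other._df)

    # -- schedule repair ----------------------------------------------

    def complete_schedule(self, schedule: Sequence[int] | None = None) -> "BioassayTable":
        """Fill missing observation days by carrying the last count forward.

        A replicate missing a scheduled checkpoint gets the previous
        day's cumulative count (with a warning); days before the first
        recorded observation are filled with zero deaths.
        """
        days = sorted(schedule) if schedule is not None else list(self.observation_days)
        frames = []
        warned = False
        for (label, rep), grp in self._df.groupby(["treatment_label", "replicate"]):
            missing = sorted(set(days) - set(grp["day"]))
            if missing:
                if not warned:
                    warnings.warn(
                        f"carrying counts forward for missing observation days "
                        f"(first: treatment {label!r} replicate {rep} days {missing})",
                        stacklevel=2,
                    )
                    warned = True
                base = grp.set_index("day").reindex(sorted(set(days) | set(grp["day"])))
                base["n_dead_cum"] = base["n_dead_cum"].ffill().fillna(0)
                base[["treatment_label", "pyrethrum_ppm", "conidia_per_ml"]] = (
                    base[["treatment_label", "pyrethrum_ppm", "conidia_per_ml"]]
                    .ffill()
                    .bfill()
                )
                base["replicate"] = rep
                base["n_start"] = grp["n_start"].iloc[0]
                grp = base.reset_index()
            frames.append(grp)
        return BioassayTable(pd.concat(frames, ignore_index=True))

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path) -> None:
        self._df.to_csv(path, index=False)


def read_bioassay(path, schema: dict[str, str] | None = None) -> BioassayTable:
    """Read a bioassay CSV, optionally renaming columns via ``schema``.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``{file_column: canonical_column}`` for files
        whose headers differ from :data:`REQUIRED_COLUMNS`.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    return BioassayTable(df)


def write_bioassay(table: BioassayTable, path) -> None:
    """Write a table in the canonical CSV dialect (round-trip safe)."""
    table.to_csv(path)


def proportional_mortality(table: BioassayTable, day: int) -> pd.DataFrame:
    """Per-replicate proportional mortality at one observation day.

    Returns a DataFrame with columns ``treatment_label, pyrethrum_ppm,
    conidia_per_ml, replicate, day, proportion_dead`` where
    ``proportion_dead = n_dead_cum / n_start`` exactly (no rounding).
    Replicates missing the requested day are carried forward first.
    """
    days = table.observation_days
    if day not in days:
        raise ValueError(f"day {day} was not observed; available days: {list(days)}")
    full = table.complete_schedule()
    df = full.df[full.df["day"] == day].copy()
    df["proportion_dead"] = df["n_dead_cum"] / df["n_start"]
    return df[
        [
            "treatment_label",
            "pyrethrum_ppm",
            "conidia_per_ml",
            "replicate",
            "day",
            "proportion_dead",
        ]
    ].reset_index(drop=True)


class Quartiles(NamedTuple):
    median: float
    q1: float
    q3: float


def median_and_quartiles(values: Iterable[float]) -> Quartiles:
    """Median and quartiles, linear interpolation between order statistics.

    Uses the "type 7" quantile definition (numpy's default), fixed and
    documented because published tables rarely state a convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_and_quartiles requires a non-empty collection")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return Quartiles(float(med), float(q1), float(q3))
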