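"""Synthetic bioassay generator with the structure of the real assays.

No raw insect data accompany the study design this package analyses, so
every pipeline stage is exercised on simulated data that reproduces the
design and the qualitative biology:

* 9 treatment arms (control, 2 pyrethrum doses, 2 fungal doses, 4
  combinations) × 4 replicates × 10 larvae, observed on days
  1, 2, 4, 7, 10 and 14;
* background (control) mortality accruing at a constant daily hazard,
  reaching ≈20% by day 14 with a near-linear decline;
* pyrethrum acting as a day-1 knockdown (dose-dependent point mass)
  plus a small residual daily hazard;
* the entomopathogenic fungus killing only after an onset lag (default
  day 4), at a dose-dependent daily hazard thereafter;
* a tunable deviation from Bliss independence, ψ: in combination arms
  the fungal daily survival factor is raised to the power ψ, so ψ = 1
  composes the two agents exactly independently, ψ < 1 attenuates the
  fungal hazard (antagonism, e.g. ψ = 0.5 halves the cumulative fungal
  hazard) and ψ > 1 amplifies it (synergy).

Default hazards are back-solved so the single-agent arms match the
study's day-14 corrected mortality medians in expectation; see
``docs/methods.md`` for the numbers and their derivation.

Identical seeds give identical output from every generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ancillary import GrowthSeries, HyphaeCount, PLUG_RADIUS_MM
from .core_data import DEFAULT_OBSERVATION_DAYS, BioassayTable, TreatmentSpec
from .dose_response import DoseGroup, predict

__all__ = [
    "SimulationConfig",
    "default_paper_treatments",
    "pyrethrum_day_probability",
    "epf_day_probability",
    "combination_day_probability",
    "treatment_day_probability",
    "simulate_combination_experiment",
    "simulate_dose_series",
    "simulate_radial_growth",
    "simulate_hyphae",
]


def default_paper_treatments() -> tuple[TreatmentSpec, ...]:
    """The 9-arm combination design: control, singles, and 2×2 combos."""
    return (
        TreatmentSpec("control", 0, 0),
        TreatmentSpec("pyr25", 25, 0),
        TreatmentSpec("pyr100", 100, 0),
        TreatmentSpec("epf1e4", 0, 1e4),
        TreatmentSpec("epf1e5", 0, 1e5),
        TreatmentSpec("pyr25+epf1e4", 25, 1e4),
        TreatmentSpec("pyr100+epf1e4", 100, 1e4),
        TreatmentSpec("pyr25+epf1e5", 25, 1e5),
        TreatmentSpec("pyr100+epf1e5", 100, 1e5),
    )


@dataclass
class SimulationConfig:
    """All generator knobs for the combination experiment.

    Daily hazards are per-larva death probabilities per calendar day;
    the simulation steps every day from 1 to the last observation day
    and records cumulative deaths at the scheduled checkpoints.
    """

    n_replicates: int = 4
    larvae_per_replicate: int = 10
    observation_days: tuple[int, ...] = DEFAULT_OBSERVATION_DAYS
    #: constant daily hazard giving ≈20% control mortality by day 14
    control_daily_hazard: float = 0.0158
    #: day-1 knockdown probability curve (log-logistic in dose)
    knockdown_slope: float = -2.0
    knockdown_lc50_ppm: float = 193.0
    #: small flat hazard on later days for any pyrethrum-treated arm
    pyrethrum_residual_daily_hazard: float = 0.0075
    #: fungal kill begins this many days after exposure
    epf_onset_day: int = 4
    #: day-14 corrected mortality targets at the standard doses;
    #: other doses fall back to a log-logistic curve in dose
    epf_day14_mortality: dict = field(
        default_factory=lambda: {1e4: 0.42, 1e5: 0.44}
    )
    epf_lc50: float = 1.48e6
    epf_slope: float = -0.25
    #: Bliss-deviation multiplier (1 = independence)
    bliss_psi: float = 1.0
    seed: int = 0
    treatments: tuple[TreatmentSpec, ...] = field(
        default_factory=default_paper_treatments
    )

    def __post_init__(self) -> None:
        if self.bliss_psi <= 0:
            raise ValueError("bliss_psi must be positive")
        for p in (self.control_daily_hazard, self.pyrethrum_residual_daily_hazard):
            if not 0 <= p <= 1:
                raise ValueError("hazards must lie in [0, 1]")

    @property
    def last_day(self) -> int:
        return max(self.observation_days)

    def with_psi(self, psi: float) -> "SimulationConfig":
        return replace(self, bliss_psi=psi)


def pyrethrum_day_probability(dose_ppm: float, day: int, config: SimulationConfig) -> float:
    """Pyrethrum-attributable death probability on one calendar day."""
    if dose_ppm <= 0:
        return 0.0
    if day == 1:
        return float(
            predict("LL2", config.knockdown_slope, config.knockdown_lc50_ppm, dose_ppm)
        )
    return config.pyrethrum_residual_daily_hazard


def epf_day_probability(dose: float, day: int, config: SimulationConfig) -> float:
    """Fungus-attributable death probability on one calendar day.

    Zero before the onset day; afterwards a constant hazard back-solved
    from the dose's day-14 corrected mortality target ``m`` via
    ``h = 1 − (1 − m)^(1/n)`` with ``n`` post-onset days up to day 14.
    """
    if dose <= 0 or day < config.epf_onset_day:
        return 0.0
    m = config.epf_day14_mortality.get(dose)
    if m is None:
        m = float(predict("LL2", config.epf_slope, config.epf_lc50, dose))
    n_days = config.last_day - config.epf_onset_day + 1
    return float(1.0 - (1.0 - m) ** (1.0 / n_days))


def combination_day_probability(p_pyr: float, p_epf: float, psi: float) -> float:
    """Compose per-day kill probabilities of the two agents.

    ``1 − (1 − p_pyr) (1 − p_epf)^ψ``: exact Bliss independence at
    ψ = 1; ψ rescales the fungal cumulative hazard.  The result is
    clipped to [0, 1] (only reachable in degenerate limits).
    """
    return float(np.clip(1.0 - (1.0 - p_pyr) * (1.0 - p_epf) ** psi, 0.0, 1.0))


def treatment_day_probability(
    treatment: TreatmentSpec, day: int, config: SimulationConfig
) -> float:
    """Total per-day death probability for one arm, control included.

    Background mortality composes independently with the treatment
    effect in every arm; ψ applies only to the fungal component of
    combination arms.
    """
    p_pyr = pyrethrum_day_probability(treatment.pyrethrum_ppm, day, config)
    p_epf = epf_day_probability(treatment.conidia_per_ml, day, config)
    psi = config.bliss_psi if treatment.is_combination else 1.0
    p_trt = combination_day_probability(p_pyr, p_epf, psi)
    return float(
        np.clip(1.0 - (1.0 - config.control_daily_hazard) * (1.0 - p_trt), 0.0, 1.0)
    )


def simulate_combination_experiment(
    config: SimulationConfig | None = None, rng: np.random.Generator | None = None
) -> BioassayTable:
    """Simulate the full combination design as a validated table."""
    config = config if config is not None else SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    reps = np.arange(1, config.n_replicates + 1)
    rows = []
    for treatment in config.treatments:
        day_probs = {
            day: treatment_day_probability(treatment, day, config)
            for day in range(1, config.last_day + 1)
        }
        alive = np.full(len(reps), config.larvae_per_replicate, dtype=np.int64)
        dead_cum = np.zeros(len(reps), dtype=np.int64)
        for day in range(1, config.last_day + 1):
            deaths = rng.binomial(alive, day_probs[day])
            alive -= deaths
            dead_cum += deaths
            if day in config.observation_days:
                for rep, dc in zip(reps, dead_cum):
                    rows.append(
                        {
                            "treatment_label": treatment.label,
                            "pyrethrum_ppm": treatment.pyrethrum_ppm,
                            "conidia_per_ml": treatment.conidia_per_ml,
                            "replicate": int(rep),
                            "day": day,
                            "n_start": config.larvae_per_replicate,
                            "n_dead_cum": int(dc),
                        }
                    )
    return BioassayTable(pd.DataFrame(rows))


def simulate_dose_series(
    family: str,
    b: float,
    e: float,
    doses,
    n_per_dose: int,
    seed: int | np.random.Generator = 0,
) -> list[DoseGroup]:
    """Binomial draws from a dose-response curve, one group per dose."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = []
    for dose in doses:
        p = float(predict(family, b, e, dose))
        groups.append(DoseGroup(dose=float(dose), n=n_per_dose, dead=int(rng.binomial(n_per_dose, p))))
    return groups


def simulate_radial_growth(
    rates: dict[float, float],
    plate_sd: float = 0.05,
    replicate_sd: float = 0.05,
    noise_sd: float = 0.3,
    days=(0, 5, 9, 14, 19),
    temperature: float = 20.0,
    n_replicates: int = 3,
    plates_per_replicate: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[GrowthSeries]:
    """Simulate colony-radius series per (concentration, replicate, plate).

    ``radius(day) = plug + (rate + replicate effect + plate effect)·day
    + noise``, floored to be non-decreasing and capped at the dish
    radius (45 mm).  Variance components are in mm/day (slopes) and mm
    (measurement noise).
    """
    for sd in (plate_sd, replicate_sd, noise_sd):
        if sd < 0:
            raise ValueError("variance components must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.asarray(days, dtype=float)
    out = []
    plate_id = 0
    for ppm, rate in rates.items():
        for rep in range(1, n_replicates + 1):
            rep_eff = rng.normal(0.0, replicate_sd)
            for _ in range(plates_per_replicate):
                plate_id += 1
                slope = rate + rep_eff + rng.normal(0.0, plate_sd)
                radii = PLUG_RADIUS_MM + slope * days + rng.normal(0.0, noise_sd, len(days))
                radii = np.maximum.accumulate(np.maximum(radii, PLUG_RADIUS_MM))
                radii = np.minimum(radii, 45.0)
                out.append(
                    GrowthSeries(
                        replicate=rep,
                        plate=plate_id,
                        temperature=temperature,
                        pyrethrum_ppm=float(ppm),
                        days=days.copy(),
                        radii=radii,
                    )
                )
    return out


def simulate_hyphae(
    probabilities: dict[str, float],
    dead_counts: dict[str, int],
    seed: int | np.random.Generator = 0,
) -> list[HyphaeCount]:
    """Binomial hyphal-outgrowth counts per treatment."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for treatment, p in probabilities.items():
        if not 0 <= p <= 1:
            raise ValueError(f"probability for {treatment!r} outside [0, 1]")
        n = dead_counts[treatment]
        out.append(
            HyphaeCount(treatment=treatment, total_dead=n, with_hyphae=int(rng.binomial(n, p)))
        )
    return out
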