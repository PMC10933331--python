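"""Bliss-independence interaction analysis for two-agent bioassays.

The core question of a combination bioassay: does a pyrethrum + fungus
mixture kill more, fewer, or about as many larvae as expected if the two
agents acted independently?  The workflow is

1. correct each treated replicate's mortality against that replicate's
   control using Schneider-Orelli's formula ``(b − k) / (1 − k)``;
2. form the Bliss-independence expectation for each combination,
   ``Me = 1 − (1 − A)(1 − B)``, from the corrected single-agent
   mortalities A and B of the same replicate;
3. summarise observed and expected corrected mortality as medians across
   replicates, and compare them with the statistic
   ``χ² = (Mo − Me)² / Me`` on the percentage (0-100) scale;
4. classify against the χ²(1) upper-α quantile (3.841 at α = 0.05):
   additive when χ² is below the critical value, otherwise antagonistic
   (Mo < Me) or synergistic (Mo > Me).

The percentage scale matters: χ² on proportions is exactly 1/100 of χ²
on percentages, and only the percentage scale reproduces published
classification tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import BioassayTable, TreatmentSpec, median_and_quartiles, proportional_mortality

__all__ = [
    "ANTAGONISTIC",
    "ADDITIVE",
    "SYNERGISTIC",
    "ConfigurationError",
    "InteractionResult",
    "schneider_orelli",
    "bliss_expected",
    "interaction_chisq",
    "critical_value",
    "classify_interaction",
    "analyze_combinations",
    "results_to_frame",
    "round_half_up",
]

ANTAGONISTIC = "antagonistic"
ADDITIVE = "additive"
SYNERGISTIC = "synergistic"


class ConfigurationError(ValueError):
    """The experiment lacks an arm the analysis requires."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def schneider_orelli(b, k):
    """Control-corrected mortality ``(b − k) / (1 − k)``, floored at 0.

    Parameters
    ----------
    b
        Treated mortality proportion in [0, 1] (scalar or array).
    k
        Control mortality proportion in [0, 1) from the same replicate.

    A treated mortality below the control would give a negative
    proportion; it is floored at 0 with a warning (a mortality
    proportion cannot be negative).
    """
    b_arr = np.asarray(b, dtype=float)
    k_arr = np.asarray(k, dtype=float)
    if np.any((b_arr < 0) | (b_arr > 1)) or np.any((k_arr < 0) | (k_arr > 1)):
        raise ValueError("mortality proportions must lie in [0, 1]")
    if np.any(k_arr >= 1):
        raise ValueError(
            "control mortality of 1 leaves no survivors to correct against"
        )
    corrected = (b_arr - k_arr) / (1.0 - k_arr)
    if np.any(corrected < 0):
        warnings.warn(
            "treated mortality below control; corrected mortality floored at 0",
            stacklevel=2,
        )
        corrected = np.maximum(corrected, 0.0)
    if np.isscalar(b) and np.isscalar(k):
        return float(corrected)
    return corrected


def bliss_expected(a, b):
    """Bliss-independence expected mortality ``1 − (1 − A)(1 − B)``.

    Symmetric in its arguments and never below ``max(A, B)``.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any((a_arr < 0) | (a_arr > 1)) or np.any((b_arr < 0) | (b_arr > 1)):
        raise ValueError("component mortalities must lie in [0, 1]")
    out = 1.0 - (1.0 - a_arr) * (1.0 - b_arr)
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out


def interaction_chisq(mo: float, me: float) -> float:
    """Interaction statistic ``(Mo − Me)² / Me`` on the percentage scale.

    Both arguments are corrected percentage mortalities (0-100).
    """
    if me <= 0:
        raise ValueError(
            "expected corrected mortality must be positive; with Me = 0 the "
            "interaction statistic is undefined (no expected deaths to compare "
            "against) — check that at least one single-agent arm kills"
        )
    return (mo - me) ** 2 / me


def critical_value(alpha: float = 0.05, df: int = 1) -> float:
    """Upper-``alpha`` chi-square quantile (3.841 at alpha=0.05, df=1)."""
    return float(stats.chi2.ppf(1.0 - alpha, df))


def classify_interaction(
    chi_squared: float, mo: float, me: float, alpha: float = 0.05
) -> str:
    """Three-way call: additive / antagonistic / synergistic.

    Additive when ``chi_squared`` does not exceed the χ²(1) critical
    value; otherwise the sign of ``Mo − Me`` separates antagonism
    (observed below expected) from synergy (observed above).
    """
    if chi_squared < 0:
        raise ValueError("chi-squared statistic cannot be negative")
    if chi_squared <= critical_value(alpha):
        return ADDITIVE
    return ANTAGONISTIC if mo < me else SYNERGISTIC


@dataclass
class InteractionResult:
    """Interaction classification for one combination treatment.

    ``mo``/``me`` are medians across replicates of observed and
    expected corrected mortality on the percentage scale; ``a``/``b``
    are the median corrected proportional mortalities of the fungal and
    pyrethrum single-agent partners.
    """

    treatment: TreatmentSpec
    mo: float
    mo_quartiles: tuple[float, float]
    me: float
    me_quartiles: tuple[float, float]
    a: float
    b: float
    chi_squared: float
    critical_value: float
    classification: str
    n_replicates: int = 0
    alpha: float = 0.05
    day: int = 14
    per_replicate: pd.DataFrame = field(default=None, repr=False)


def analyze_combinations(
    table: BioassayTable, day: int = 14, alpha: float = 0.05
) -> list[InteractionResult]:
    """Classify every combination arm of a bioassay at one observation day.

    Per replicate, all treatments are corrected against that replicate's
    control and each combination's Bliss expectation is formed from its
    two single-agent partners.  Medians across replicates of observed
    and expected corrected mortality then feed one χ² per combination,
    on the percentage scale.  Quartiles accompany the medians.
    """
    props = proportional_mortality(table, day)
    control = props[(props["pyrethrum_ppm"] == 0) & (props["conidia_per_ml"] == 0)]
    if control.empty:
        raise ConfigurationError("no control (0 ppm, 0 conidia/mL) arm in the table")
    k_by_rep = control.set_index("replicate")["proportion_dead"]

    def corrected_by_rep(sub: pd.DataFrame) -> pd.Series:
        k = k_by_rep.reindex(sub["replicate"])
        if k.isna().any():
            missing = sub.loc[k.isna().to_numpy(), "replicate"].tolist()
            raise ConfigurationError(
                f"control arm missing replicates {missing} needed for correction"
            )
        vals = schneider_orelli(sub["proportion_dead"].to_numpy(), k.to_numpy())
        return pd.Series(vals, index=sub["replicate"].to_numpy())

    by_dose = {
        (float(r.pyrethrum_ppm), float(r.conidia_per_ml)): g
        for r, g in (
            (grp.iloc[0], grp)
            for _, grp in props.groupby(["pyrethrum_ppm", "conidia_per_ml"])
        )
    }

    results: list[InteractionResult] = []
    for treatment in table.treatments:
        if not treatment.is_combination:
            continue
        combo = by_dose[(treatment.pyrethrum_ppm, treatment.conidia_per_ml)]
        pyr_key = (treatment.pyrethrum_ppm, 0.0)
        epf_key = (0.0, treatment.conidia_per_ml)
        for key, agent in ((pyr_key, "pyrethrum"), (epf_key, "B. bassiana")):
            if key not in by_dose:
                raise ConfigurationError(
                    f"combination {treatment.label!r} lacks its single-agent "
                    f"{agent} partner at dose {key}"
                )
        obs = corrected_by_rep(combo)
        a_epf = corrected_by_rep(by_dose[epf_key])
        b_pyr = corrected_by_rep(by_dose[pyr_key])
        common = obs.index.intersection(a_epf.index).intersection(b_pyr.index)
        obs, a_epf, b_pyr = obs[common], a_epf[common], b_pyr[common]
        expected = pd.Series(
            bliss_expected(a_epf.to_numpy(), b_pyr.to_numpy()), index=common
        )

        mo_med, mo_q1, mo_q3 = median_and_quartiles(obs)
        me_med, me_q1, me_q3 = median_and_quartiles(expected)
        mo_pct, me_pct = 100.0 * mo_med, 100.0 * me_med
        if me_pct == 0:
            # degenerate small-sample case: no expected deaths to compare
            # against.  Zero observed agrees perfectly with zero expected;
            # any observed deaths are an unbounded departure above it.
            warnings.warn(
                f"expected corrected mortality is 0 for {treatment.label!r}; "
                "statistic degenerate",
                stacklevel=2,
            )
            chi2 = 0.0 if mo_pct == 0 else float("inf")
        else:
            chi2 = interaction_chisq(mo_pct, me_pct)
        results.append(
            InteractionResult(
                treatment=treatment,
                mo=mo_pct,
                mo_quartiles=(100.0 * mo_q1, 100.0 * mo_q3),
                me=me_pct,
                me_quartiles=(100.0 * me_q1, 100.0 * me_q3),
                a=float(np.median(a_epf)),
                b=float(np.median(b_pyr)),
                chi_squared=chi2,
                critical_value=critical_value(alpha),
                classification=classify_interaction(chi2, mo_pct, me_pct, alpha),
                n_replicates=len(common),
                alpha=alpha,
                day=day,
                per_replicate=pd.DataFrame(
                    {"observed": obs, "expected": expected}
                ).rename_axis("replicate"),
            )
        )
    return results


def results_to_frame(results: list[InteractionResult]) -> pd.DataFrame:
    """Tabulate interaction results the way published tables present them.

    Mortalities are reported back on the proportion scale rounded
    half-up to two decimals; χ² to two decimals.  Internal computation
    is unrounded.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "treatment": r.treatment.label,
                "pyrethrum_ppm": r.treatment.pyrethrum_ppm,
                "conidia_per_ml": r.treatment.conidia_per_ml,
                "observed_corrected_median": round_half_up(r.mo / 100, 2),
                "observed_corrected_q1": round_half_up(r.mo_quartiles[0] / 100, 2),
                "observed_corrected_q3": round_half_up(r.mo_quartiles[1] / 100, 2),
                "expected_corrected_median": round_half_up(r.me / 100, 2),
                "expected_corrected_q1": round_half_up(r.me_quartiles[0] / 100, 2),
                "expected_corrected_q3": round_half_up(r.me_quartiles[1] / 100, 2),
                "chi_squared": round_half_up(r.chi_squared, 2),
                "effect_type": r.classification,
            }
        )
    return pd.DataFrame(rows)
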