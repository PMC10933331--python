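"""Hyphal-outgrowth and radial-growth analyses.

Two side assays accompany a combination bioassay of a fungal
biopesticide:

* **Hyphal outgrowth** — of the larvae that died in each treatment, how
  many cadavers produced fungal hyphae (confirming infection and the
  potential for secondary cycling)?  Treatments are compared with a
  binomial logistic regression likelihood-ratio test: deviance of the
  intercept-only model minus deviance of the treatment-factor model,
  referred to χ² with ``#treatments − 1`` degrees of freedom.  With one
  count pair per treatment the factor model is saturated, so the
  statistic equals the classical G-test of homogeneity.

* **Radial growth** — does the botanical partner inhibit fungal colony
  growth on agar?  Colony radius is tracked over days on plates amended
  with different pyrethrum concentrations.  The analysis is two-stage:
  a least-squares growth rate (mm/day) per plate, then a comparison of
  plate slopes across concentrations with replicate run as a blocking
  factor and Tukey-adjusted all-pairs contrasts, summarised as letter
  groups.  Measurements after a plate reaches the dish edge are
  excluded from the slope fits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .survival import compact_letter_display

__all__ = [
    "HyphaeCount",
    "GrowthSeries",
    "SlopeComparison",
    "EDGE_RADIUS_MM",
    "PLUG_RADIUS_MM",
    "hyphae_lr_test",
    "hyphae_percentages",
    "growth_rates",
]

#: Radius (mm) at which a colony is considered to have reached the edge
#: of a 90 mm dish (45 mm minus a margin); later points are excluded.
EDGE_RADIUS_MM = 42.5

#: Radius of the 1 cm inoculation plug.
PLUG_RADIUS_MM = 5.0


@dataclass(frozen=True)
class HyphaeCount:
    """Cadaver counts for one treatment: total dead, dead with hyphae."""

    treatment: str
    total_dead: int
    with_hyphae: int

    def __post_init__(self) -> None:
        if not 0 <= self.with_hyphae <= self.total_dead:
            raise ValueError(
                f"with_hyphae={self.with_hyphae} outside [0, total_dead={self.total_dead}]"
            )


@dataclass
class GrowthSeries:
    """Colony radius measurements for one plate."""

    replicate: int
    plate: int
    temperature: float
    pyrethrum_ppm: float
    days: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.days.shape != self.radii.shape:
            raise ValueError("days and radii must have the same length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("measurement days must be strictly increasing")
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")


@dataclass
class SlopeComparison:
    """Growth-rate comparison across concentrations at one temperature."""

    temperature: float
    rates: pd.DataFrame  # per-concentration mean rate, se, n_plates
    pairwise: pd.DataFrame  # pair, difference, q, p_raw-analogue, p_tukey
    letters: dict[float, str]
    f_statistic: float
    f_p: float
    plate_slopes: pd.DataFrame = field(default=None, repr=False)


def hyphae_lr_test(counts: list[HyphaeCount]) -> tuple[float, int, float]:
    """Likelihood-ratio χ² for a treatment effect on hyphal outgrowth.

    Fits intercept-only and treatment-factor binomial logistic models
    (IRLS via statsmodels GLM) and returns the deviance difference,
    ``df = #treatments − 1`` and the chi-square p-value.  Treatments
    with no dead larvae carry no information and are dropped with a
    warning; all-0% or all-100% groups are handled by the deviance
    convention 0·ln 0 = 0.
    """
    kept = [c for c in counts if c.total_dead > 0]
    dropped = [c.treatment for c in counts if c.total_dead == 0]
    if dropped:
        warnings.warn(f"treatments with no dead larvae dropped: {dropped}")
    if len(kept) < 2:
        raise ValueError("need at least 2 treatments with dead larvae")
    endog = np.array([[c.with_hyphae, c.total_dead - c.with_hyphae] for c in kept], dtype=float)
    labels = pd.get_dummies([c.treatment for c in kept], dtype=float)
    with warnings.catch_warnings():
        # the factor model is saturated by construction (one count pair per
        # treatment): zero residual df and perfect prediction are expected
        warnings.simplefilter("ignore", RuntimeWarning)
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        warnings.simplefilter("ignore", PerfectSeparationWarning)
        null_fit = sm.GLM(endog, np.ones((len(kept), 1)), family=sm.families.Binomial()).fit()
        full_fit = sm.GLM(endog, labels.to_numpy(), family=sm.families.Binomial()).fit()
    statistic = float(null_fit.deviance - full_fit.deviance)
    df = len(kept) - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))


def hyphae_percentages(counts: list[HyphaeCount]) -> pd.DataFrame:
    """Percentage of cadavers producing hyphae, per treatment.

    Rounded half-up to whole percent for reporting; treatments with no
    dead larvae get a blank (NA) percentage.
    """
    from .interaction import round_half_up

    rows = []
    for c in counts:
        pct = (
            round_half_up(100.0 * c.with_hyphae / c.total_dead, 0)
            if c.total_dead > 0
            else np.nan
        )
        rows.append(
            {
                "treatment": c.treatment,
                "total_dead": c.total_dead,
                "with_hyphae": c.with_hyphae,
                "percentage": pct,
            }
        )
    return pd.DataFrame(rows)


def _plate_slope(series: GrowthSeries) -> float | None:
    """Least-squares growth rate of one plate, truncated at the dish edge."""
    reached = np.nonzero(series.radii >= EDGE_RADIUS_MM)[0]
    if reached.size:
        cut = reached[0] + 1  # keep the first at-edge point, drop later ones
        days, radii = series.days[:cut], series.radii[:cut]
    else:
        days, radii = series.days, series.radii
    if len(days) < 2:
        return None
    return float(np.polyfit(days, radii, 1)[0])


def growth_rates(
    series: list[GrowthSeries], temperature: float, alpha: float = 0.05
) -> SlopeComparison:
    """Compare radial growth rates across pyrethrum concentrations.

    Two-stage: per-plate least-squares slope of radius on day, then an
    OLS of slopes on concentration with replicate as a blocking factor.
    The overall concentration effect is an F test; all-pairs contrasts
    use the Tukey-Kramer studentized-range adjustment on the blocked
    model's residual variance, with letter groups at adjusted
    p < ``alpha``.
    """
    rows = []
    for s in series:
        if s.temperature != temperature:
            continue
        slope = _plate_slope(s)
        if slope is None:
            warnings.warn(
                f"plate {s.plate} (replicate {s.replicate}, "
                f"{s.pyrethrum_ppm} ppm) has fewer than 2 usable points; excluded"
            )
            continue
        rows.append(
            {
                "replicate": s.replicate,
                "plate": s.plate,
                "ppm": s.pyrethrum_ppm,
                "slope": slope,
            }
        )
    slopes = pd.DataFrame(rows)
    if slopes.empty:
        raise ValueError(f"no growth series at temperature {temperature}")
    counts = slopes.groupby("ppm").size()
    if (counts < 2).any():
        raise ValueError(
            "need at least 2 plates per concentration; short: "
            f"{counts[counts < 2].index.tolist()}"
        )

    if slopes["ppm"].nunique() > 1:
        formula = "slope ~ C(ppm) + C(replicate)"
        if slopes["replicate"].nunique() == 1:
            formula = "slope ~ C(ppm)"
        model = smf.ols(formula, data=slopes).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        f_stat = float(anova.loc["C(ppm)", "F"])
        f_p = float(anova.loc["C(ppm)", "PR(>F)"])
    else:
        # single concentration: rates are still reported, but there is
        # no between-concentration effect to test
        model = smf.ols("slope ~ 1", data=slopes).fit()
        f_stat, f_p = float("nan"), float("nan")
    mse = float(model.mse_resid) if model.df_resid > 0 else 0.0
    df_resid = int(model.df_resid)

    means = slopes.groupby("ppm")["slope"].agg(["mean", "count"])
    means["se"] = np.sqrt(mse / means["count"])
    k = len(means)

    pairs = []
    significant: set[frozenset] = set()
    for c1, c2 in itertools.combinations(means.index, 2):
        m1, n1 = means.loc[c1, "mean"], means.loc[c1, "count"]
        m2, n2 = means.loc[c2, "mean"], means.loc[c2, "count"]
        diff = m1 - m2
        se_pair = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
        if se_pair == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se_pair
        p_tukey = float(stats.studentized_range.sf(q, k, df_resid))
        p_raw = float(2 * stats.t.sf(q / np.sqrt(2.0), df_resid))
        pairs.append(
            {
                "ppm_1": c1,
                "ppm_2": c2,
                "difference": diff,
                "q": q,
                "p_unadjusted": p_raw,
                "p_tukey": p_tukey,
            }
        )
        if p_tukey < alpha:
            significant.add(frozenset((c1, c2)))

    letters = compact_letter_display(list(means.index), significant)
    rates = means.rename(columns={"mean": "rate", "count": "n_plates"})[
        ["rate", "se", "n_plates"]
    ]
    return SlopeComparison(
        temperature=temperature,
        rates=rates,
        pairwise=pd.DataFrame(pairs),
        letters=letters,
        f_statistic=f_stat,
        f_p=f_p,
        plate_slopes=slopes,
    )
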