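"""Kaplan-Meier estimation and log-rank comparison of checkpoint data.

Mortality recorded at scheduled checkpoints converts naturally to
subject-level survival records: each death is assigned the first day it
was observed dead, and survivors at the final observation are
right-censored there.  Estimation and testing then follow the standard
toolkit — product-limit survival curves per treatment, a global
log-rank test across all arms (df = number of arms − 1) and all-pairs
log-rank tests with Bonferroni adjustment, summarised as compact
significance letters.

Ties are handled with the usual simultaneous-death hypergeometric
variance, no continuity correction.  Interval-censored likelihoods are
deliberately out of scope; the checkpoint day itself is the event time.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .core_data import BioassayTable

__all__ = [
    "KMCurve",
    "LogRankResult",
    "to_subjects",
    "km_estimate",
    "logrank",
    "pairwise_logrank_bonferroni",
    "compact_letter_display",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate for one treatment arm."""

    treatment: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray


@dataclass
class LogRankResult:
    groups: tuple[str, ...]
    statistic: float
    df: int
    p: float
    adjusted_p: float | None = None


def to_subjects(table: BioassayTable) -> pd.DataFrame:
    """Expand cumulative counts into one row per larva.

    Columns ``treatment_label, replicate, time, event`` with
    ``event = 1`` for deaths (at the first checkpoint observed dead) and
    ``event = 0`` for survivors censored at the final observation day.
    Counts are conserved: deaths + censored = n_start per replicate.
    """
    full = table.complete_schedule()
    rows = []
    last_day = max(full.observation_days)
    for (label, rep), grp in full.df.groupby(["treatment_label", "replicate"]):
        grp = grp.sort_values("day")
        prev = 0
        for _, r in grp.iterrows():
            new_deaths = int(r.n_dead_cum) - prev
            prev = int(r.n_dead_cum)
            rows.extend(
                {"treatment_label": label, "replicate": rep, "time": int(r.day), "event": 1}
                for _ in range(new_deaths)
            )
        survivors = int(grp["n_start"].iloc[0]) - prev
        rows.extend(
            {"treatment_label": label, "replicate": rep, "time": last_day, "event": 0}
            for _ in range(survivors)
        )
    return pd.DataFrame(rows, columns=["treatment_label", "replicate", "time", "event"])


def km_estimate(subjects: pd.DataFrame, treatment: str) -> KMCurve:
    """Kaplan-Meier curve for one treatment arm."""
    sub = subjects[subjects["treatment_label"] == treatment]
    if sub.empty:
        raise ValueError(f"no subjects for treatment {treatment!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    tbl = kmf.event_table.iloc[1:] if 0 in kmf.event_table.index and sub["time"].min() > 0 else kmf.event_table
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        treatment=treatment,
        times=times,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(dtype=int),
        deaths=tbl["observed"].to_numpy(dtype=int),
    )


def logrank(subjects: pd.DataFrame, groups: list[str] | None = None) -> LogRankResult:
    """Log-rank test across two or more treatment arms.

    Standard hypergeometric O−E/V chi-square over shared event times;
    df = number of groups − 1.  Groups with no subjects are excluded
    with a warning.
    """
    if groups is None:
        groups = sorted(subjects["treatment_label"].unique())
    keep = []
    for g in groups:
        if (subjects["treatment_label"] == g).any():
            keep.append(g)
        else:
            warnings.warn(f"group {g!r} has no subjects; excluded from log-rank test")
    if len(keep) < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    sub = subjects[subjects["treatment_label"].isin(keep)]
    res = multivariate_logrank_test(sub["time"], sub["treatment_label"], sub["event"])
    return LogRankResult(
        groups=tuple(keep),
        statistic=float(res.test_statistic),
        df=len(keep) - 1,
        p=float(res.p_value),
    )


def pairwise_logrank_bonferroni(
    subjects: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[LogRankResult], dict[str, str]]:
    """All-pairs log-rank tests with Bonferroni adjustment and letters.

    ``adjusted_p = min(1, p × C(k, 2))``.  Letter groups (arms sharing a
    letter are not significantly different at adjusted p < ``alpha``)
    are a presentation aid built by insert-and-absorb.
    """
    groups = sorted(subjects["treatment_label"].unique())
    if len(groups) < 2:
        raise ValueError("pairwise comparison needs at least 2 groups")
    m = len(groups) * (len(groups) - 1) // 2
    results = []
    significant: set[frozenset] = set()
    for g1, g2 in itertools.combinations(groups, 2):
        res = logrank(subjects, [g1, g2])
        res.adjusted_p = min(1.0, res.p * m)
        results.append(res)
        if res.adjusted_p < alpha:
            significant.add(frozenset((g1, g2)))
    letters = compact_letter_display(groups, significant)
    return results, letters


def compact_letter_display(
    items: list[str], significant_pairs: set[frozenset]
) -> dict[str, str]:
    """Assign shared letters to items not significantly different.

    Insert-and-absorb: start from one all-inclusive group; each
    significant pair splits every group containing both members into two
    subgroups, and groups contained in another are absorbed.  Items in a
    common group share a letter.
    """
    groups: list[set[str]] = [set(items)]
    for pair in sorted(significant_pairs, key=sorted):
        a, b = sorted(pair)
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    groups.sort(key=lambda g: sorted(items.index(i) for i in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {i: "" for i in items}
    for letter, g in zip(alphabet, groups):
        for item in g:
            letters[item] += letter
    return letters
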