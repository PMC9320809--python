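"""Per-trial courtship metrics and the progeny-latency isolation assay.

A trial's *initiation* is either the first non-``separate`` timepoint
(``"first"``) or the first element of the earliest run of at least three
consecutive non-``separate`` timepoints (``"consecutive3"``, the default —
single spurious "engaging" scores followed by long gaps are not courtship).
*Copulation latency* runs from initiation to the onset of ``copulating``;
the *time budget* is the fraction of timepoints spent in each behaviour
between initiation and copulation (the denominator includes post-initiation
``separate`` timepoints).

Trials without copulation are right-censored.  Their budget window can be
matched to the mean successful latency of the same strain pair
(:func:`impute_censored_window`), so censored trials are scored over a
comparable span rather than the full 30-min recording.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticsError, NoReferenceLatencyError, ValidationError
from .io import EthogramTrial
from .states import ACTIVE_STATES, COPULATING, SEPARATE

__all__ = [
    "CourtshipSummary",
    "ProgenyTrial",
    "detect_initiation",
    "summarize_trial",
    "summarize_panel",
    "impute_censored_window",
    "compare_initiation_methods",
    "mating_index",
    "progeny_latency_test",
]


@dataclasses.dataclass
class CourtshipSummary:
    trial_id: str
    male_strain: str
    female_strain: str
    initiation_index: int | None
    initiation_time_s: float | None
    copulation_latency_s: float | None
    censored: bool
    latency_imputed: bool
    budget: dict[str, float]
    separate_fraction: float
    n_timepoints: int

    def as_row(self) -> dict:
        row = {
            "trial_id": self.trial_id,
            "male_strain": self.male_strain,
            "female_strain": self.female_strain,
            "initiation_index": self.initiation_index,
            "initiation_time_s": self.initiation_time_s,
            "copulation_latency_s": self.copulation_latency_s,
            "censored": self.censored,
            "latency_imputed": self.latency_imputed,
            "separate": self.separate_fraction,
            "n_timepoints": self.n_timepoints,
        }
        row.update(self.budget)
        return row


@dataclasses.dataclass
class ProgenyTrial:
    """Single-pair cross watched up to 16 days for first progeny."""

    cross_id: str
    female_strain: str
    male_strain: str
    days_to_first_progeny: float
    censored: bool = False
    window_days: float = 16.0

    def __post_init__(self) -> None:
        if not (1 <= self.days_to_first_progeny <= self.window_days):
            raise ValidationError(
                f"cross {self.cross_id}: days-to-first-progeny must lie in "
                f"[1, {self.window_days}]"
            )


def detect_initiation(trial: EthogramTrial, method: str = "consecutive3") -> int | None:
    """Grid index of courtship initiation, or ``None`` if the male never courts."""
    non_sep = [s != SEPARATE for s in trial.states]
    if method == "first":
        return non_sep.index(True) if any(non_sep) else None
    if method == "consecutive3":
        run = 0
        for i, flag in enumerate(non_sep):
            run = run + 1 if flag else 0
            if run == 3:
                return i - 2
        return None
    raise ValueError(f"unknown initiation method {method!r}")


def summarize_trial(
    trial: EthogramTrial,
    initiation_method: str = "consecutive3",
    budget_window: int | None = None,
) -> CourtshipSummary:
    """Initiation, latency and time budget for one trial.

    ``budget_window`` limits the budget to that many timepoints from
    initiation (used for censored trials via
    :func:`impute_censored_window`); when set on a censored trial the
    imputed copulation latency is reported and flagged.
    """
    init = detect_initiation(trial, initiation_method)
    censored = not trial.copulated
    if init is None:
        return CourtshipSummary(
            trial_id=trial.trial_id,
            male_strain=trial.male_strain,
            female_strain=trial.female_strain,
            initiation_index=None,
            initiation_time_s=None,
            copulation_latency_s=None,
            censored=censored,
            latency_imputed=False,
            budget={},
            separate_fraction=float("nan"),
            n_timepoints=0,
        )

    if trial.copulated:
        cop_index = len(trial.states) - 1
        end = cop_index  # budget excludes the copulating point itself
        latency = (cop_index - init) * trial.interval_s
        imputed = False
    else:
        end = len(trial.states)
        latency = None
        imputed = False
        if budget_window is not None:
            end = min(end, init + int(budget_window))
            latency = budget_window * trial.interval_s
            imputed = True
    window = trial.states[init:end]
    if not window:  # copulation immediately at initiation is impossible on a
        raise ValidationError(  # valid grid, but guard the empty window
            f"trial {trial.trial_id}: empty budget window"
        )
    n = len(window)
    budget = {s: window.count(s) / n for s in ACTIVE_STATES}
    sep_frac = window.count(SEPARATE) / n
    return CourtshipSummary(
        trial_id=trial.trial_id,
        male_strain=trial.male_strain,
        female_strain=trial.female_strain,
        initiation_index=init,
        initiation_time_s=init * trial.interval_s,
        copulation_latency_s=latency,
        censored=censored,
        latency_imputed=imputed,
        budget=budget,
        separate_fraction=sep_frac,
        n_timepoints=n,
    )


def impute_censored_window(
    trials: Sequence[EthogramTrial],
    initiation_method: str = "consecutive3",
) -> dict[str, int]:
    """Budget window (timepoints) for each censored trial of one strain pair.

    The window equals the mean copulation latency of the *successful* trials
    in the group, rounded to the grid.  All trials passed in must share one
    (male strain, female strain) combination; a group with zero successes has
    no reference latency and raises :class:`NoReferenceLatencyError` — the
    caller may fall back to the full recording.
    """
    groups = {(t.male_strain, t.female_strain) for t in trials}
    if len(groups) > 1:
        raise ValidationError(
            f"impute_censored_window expects a single strain pair, got {sorted(groups)}"
        )
    latencies = []
    interval = trials[0].interval_s
    for t in trials:
        if t.copulated:
            s = summarize_trial(t, initiation_method)
            if s.copulation_latency_s is not None:
                latencies.append(s.copulation_latency_s)
    if not latencies:
        raise NoReferenceLatencyError(
            f"group {next(iter(groups))}: no successful trials to provide a "
            "reference latency"
        )
    window = int(round(float(np.mean(latencies)) / interval))
    return {t.trial_id: max(window, 1) for t in trials if not t.copulated}


def summarize_panel(
    trials: Sequence[EthogramTrial],
    initiation_method: str = "consecutive3",
    impute: bool = True,
) -> pd.DataFrame:
    """Summaries for a whole panel, with group-wise censoring windows.

    Censored trials get a budget window equal to the group's mean successful
    latency where one exists; groups with zero successes fall back to the
    full recording.
    """
    by_pair: dict[tuple[str, str], list[EthogramTrial]] = defaultdict(list)
    for t in trials:
        by_pair[(t.male_strain, t.female_strain)].append(t)
    windows: dict[str, int] = {}
    if impute:
        for pair_trials in by_pair.values():
            try:
                windows.update(impute_censored_window(pair_trials, initiation_method))
            except NoReferenceLatencyError:
                pass
    rows = [
        summarize_trial(t, initiation_method, budget_window=windows.get(t.trial_id)).as_row()
        for t in trials
    ]
    return pd.DataFrame(rows)


def compare_initiation_methods(trials: Iterable[EthogramTrial]) -> dict[str, float]:
    """Mean/max absolute discrepancy (s) between the two initiation rules.

    Diagnostic over trials where both rules fire; large values flag bouts
    where an isolated early "engaging" score was not real courtship.
    """
    diffs = []
    for t in trials:
        a = detect_initiation(t, "first")
        b = detect_initiation(t, "consecutive3")
        if a is not None and b is not None:
            diffs.append(abs(b - a) * t.interval_s)
    if not diffs:
        return {"n": 0, "mean_abs_s": float("nan"), "max_abs_s": float("nan")}
    return {
        "n": len(diffs),
        "mean_abs_s": float(np.mean(diffs)),
        "max_abs_s": float(np.max(diffs)),
    }


def mating_index(
    latencies: Sequence[float | None],
    successes: int,
    trials: int,
    max_observed: float,
) -> float:
    """Latency-based fitness proxy that penalizes failed trials.

    Censored latencies (``None``/NaN) are replaced by the maximum observed
    time, then the mean latency is divided by the proportion of trials that
    mated.  Larger = worse.  With zero successes the index is ``inf`` —
    the flag for a completely unsuccessful combination.
    """
    if trials < 1:
        raise ValidationError("mating_index needs at least one trial")
    filled = []
    for lat in latencies:
        if lat is None or (isinstance(lat, float) and math.isnan(lat)):
            filled.append(float(max_observed))
        else:
            if lat < 0:
                raise ValidationError("negative copulation latency")
            filled.append(float(lat))
    if successes == 0:
        return float("inf")
    return float(np.mean(filled)) / (successes / trials)


def progeny_latency_test(
    trials: Sequence[ProgenyTrial],
    reference_male: str,
    test_males: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Kaplan–Meier comparison of days-to-first-progeny against a reference.

    Crosses are right-censored at the end of the observation window (16
    days).  Each test strain is compared with the reference strain by a
    log-rank test; returns one row per test strain with the statistic, p,
    and group sizes.
    """
    from lifelines.statistics import logrank_test

    by_male: dict[str, list[ProgenyTrial]] = defaultdict(list)
    for t in trials:
        by_male[t.male_strain].append(t)
    if reference_male not in by_male:
        raise ValidationError(f"no trials for reference strain {reference_male!r}")
    ref = by_male[reference_male]
    if test_males is None:
        test_males = sorted(m for m in by_male if m != reference_male)
    rows = []
    for male in test_males:
        if male not in by_male or not by_male[male]:
            raise ValidationError(f"no trials for test strain {male!r}")
        grp = by_male[male]
        if len(ref) < 2 or len(grp) < 2:
            raise DegenerateStatisticsError(
                f"need ≥2 trials per strain to compare {male} vs {reference_male}"
            )
        if all(t.censored for t in ref) and all(t.censored for t in grp):
            raise DegenerateStatisticsError(
                f"all crosses censored in both {male} and {reference_male}: "
                "survival curves are indistinguishable"
            )
        res = logrank_test(
            [t.days_to_first_progeny for t in ref],
            [t.days_to_first_progeny for t in grp],
            event_observed_A=[not t.censored for t in ref],
            event_observed_B=[not t.censored for t in grp],
        )
        rows.append(
            {
                "male_strain": male,
                "reference": reference_male,
                "statistic": float(res.test_statistic),
                "p": float(res.p_value),
                "n_test": len(grp),
                "n_reference": len(ref),
            }
        )
    return pd.DataFrame(rows)
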