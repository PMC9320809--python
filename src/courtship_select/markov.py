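"""Behavioural sequences as discrete-time Markov chains.

Transitions between the eight courtship states are counted over all trials
of a (male strain × female strain) combination, never across trial
boundaries.  Whether a male runs the same behavioural program against
different female genotypes is tested as Markov-chain homogeneity: do the
per-context transition count matrices share one underlying transition
matrix?

The homogeneity statistic compares per-group row distributions with the
pooled rows.  Two forms are provided:

* ``"pearson"`` (default) — X² = Σ (n_gij − n_gi·p̂_ij)² / (n_gi·p̂_ij),
  summed over groups and cells with pooled support;
* ``"lrt"`` — G² = 2 Σ n_gij log[(n_gij/n_gi·)/(n_+ij/n_+i·)], the
  likelihood-ratio form.

Both are referred to a chi-square distribution with
df = Σ_i (G_i − 1)(k_i − 1), where the sum runs over rows with pooled
support, G_i counts groups that visited row i and k_i counts columns with
pooled support in row i.  Pearson is the default because it holds its
nominal size at the moderate transition counts (a few hundred per group)
typical of 30-min courtship bouts, where the likelihood-ratio form is
anticonservative.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .errors import DegenerateStatisticsError, ValidationError
from .io import EthogramTrial
from .states import BEHAVIOR_STATES, COPULATING, STATE_INDEX

__all__ = [
    "TransitionCounts",
    "HomogeneityResult",
    "count_transitions",
    "estimate_matrix",
    "homogeneity_test",
    "homogeneity_by_male_strain",
    "per_trial_transition_freq",
]

K = len(BEHAVIOR_STATES)
_COP = STATE_INDEX[COPULATING]


@dataclasses.dataclass
class TransitionCounts:
    """k×k one-step transition counts pooled over the trials of one group."""

    group: Hashable
    counts: np.ndarray
    states: tuple[str, ...] = BEHAVIOR_STATES
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.states)
        if self.counts.shape != (k, k):
            raise ValidationError(f"counts must be {k}×{k}")
        if (self.counts < 0).any():
            raise ValidationError("negative transition counts")
        cop = self.states.index(COPULATING) if COPULATING in self.states else None
        if cop is not None and self.counts[cop].sum() != 0:
            raise ValidationError("'copulating' is absorbing: its row must be zero")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclasses.dataclass
class HomogeneityResult:
    statistic: float
    df: int
    p: float
    groups: tuple
    method: str = "pearson"


def count_transitions(
    trials: Sequence[EthogramTrial], group: Hashable | None = None
) -> TransitionCounts:
    """Sum one-step transitions over trials; boundaries are never crossed."""
    if not trials:
        raise ValidationError("count_transitions: empty trial set")
    counts = np.zeros((K, K), dtype=np.int64)
    for t in trials:
        idx = np.fromiter((STATE_INDEX[s] for s in t.states), dtype=np.int64)
        if len(idx) >= 2:
            np.add.at(counts, (idx[:-1], idx[1:]), 1)
    if group is None:
        group = (trials[0].male_strain, trials[0].female_strain)
    return TransitionCounts(group=group, counts=counts, n_trials=len(trials))


def estimate_matrix(counts: TransitionCounts, smoothing: float = 0.0) -> np.ndarray:
    """Row-stochastic MLE with optional pseudo-count smoothing.

    p[i,j] = (n_ij + α) / (n_i· + kα).  The absorbing ``copulating`` row is
    the identity; a non-absorbing row with zero support and α = 0 has no MLE
    and falls back to uniform (with a warning).
    """
    c = counts.counts.astype(float)
    k = c.shape[0]
    P = np.zeros_like(c)
    cop = counts.states.index(COPULATING) if COPULATING in counts.states else None
    for i in range(k):
        if i == cop:
            P[i, i] = 1.0
            continue
        denom = c[i].sum() + k * smoothing
        if denom <= 0:
            warnings.warn(
                f"row {counts.states[i]!r} has no observed transitions; "
                "using a uniform fallback",
                stacklevel=2,
            )
            P[i] = 1.0 / k
        else:
            P[i] = (c[i] + smoothing) / denom
    return P


def _homogeneity_terms(mats: list[np.ndarray], statistic: str):
    pooled = np.sum(mats, axis=0).astype(float)
    k = pooled.shape[0]
    stat = 0.0
    df = 0
    for i in range(k):
        row_tot = pooled[i].sum()
        if row_tot == 0:
            continue
        ki = int((pooled[i] > 0).sum())
        Gi = sum(1 for m in mats if m[i].sum() > 0)
        if Gi >= 2 and ki >= 2:
            df += (Gi - 1) * (ki - 1)
        p_pool = pooled[i] / row_tot
        for m in mats:
            n_i = m[i].sum()
            if n_i == 0:
                continue
            if statistic == "pearson":
                supp = p_pool > 0
                expected = n_i * p_pool[supp]
                stat += float(np.sum((m[i][supp] - expected) ** 2 / expected))
            else:  # lrt
                nz = m[i] > 0
                stat += float(
                    2.0
                    * np.sum(m[i][nz] * np.log((m[i][nz] / n_i) / p_pool[nz]))
                )
    return stat, df


def homogeneity_test(
    groups: Sequence[TransitionCounts], statistic: str = "pearson"
) -> HomogeneityResult:
    """Test whether ≥2 groups share one transition matrix."""
    if len(groups) < 2:
        raise ValidationError("homogeneity_test needs at least 2 groups")
    k0 = groups[0].counts.shape[0]
    if any(g.counts.shape[0] != k0 for g in groups):
        raise ValidationError("groups must share one state set")
    if statistic not in {"pearson", "lrt"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    mats = [g.counts.astype(float) for g in groups]
    if np.sum(mats) == 0:
        raise DegenerateStatisticsError("all groups have zero transitions")
    stat, df = _homogeneity_terms(mats, statistic)
    if df == 0:
        raise DegenerateStatisticsError(
            "no transition-matrix row is supported in ≥2 groups with ≥2 "
            "destination states: the homogeneity test is degenerate"
        )
    return HomogeneityResult(
        statistic=float(stat),
        df=int(df),
        p=float(chi2.sf(stat, df)),
        groups=tuple(g.group for g in groups),
        method=statistic,
    )


def homogeneity_by_male_strain(
    trials: Sequence[EthogramTrial],
    statistic: str = "pearson",
) -> "pd.DataFrame":
    """Per-male-strain homogeneity test across female contexts.

    For each male strain observed with ≥2 female strains, pools transitions
    per (male, female) combination and tests the female contexts against
    each other.  Strains observed in a single context are skipped.
    """
    import pandas as pd

    by_male: dict[str, dict[str, list[EthogramTrial]]] = {}
    for t in trials:
        by_male.setdefault(t.male_strain, {}).setdefault(t.female_strain, []).append(t)
    rows = []
    for male, ctx in sorted(by_male.items()):
        if len(ctx) < 2:
            continue
        counts = [
            count_transitions(ts, group=(male, female))
            for female, ts in sorted(ctx.items())
        ]
        try:
            res = homogeneity_test(counts, statistic=statistic)
        except DegenerateStatisticsError:
            continue
        rows.append(
            {
                "male_strain": male,
                "female_strains": ",".join(sorted(ctx)),
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def per_trial_transition_freq(trial: EthogramTrial) -> dict[tuple[str, str], float]:
    """Fraction of a trial's transitions spent on each (from, to) pair.

    These per-trial fractions are the response variables used to localize
    sequence plasticity to individual transitions (after variable
    reduction); they sum to 1 within a trial.
    """
    if len(trial.states) < 2:
        raise ValidationError(
            f"trial {trial.trial_id}: needs ≥2 states to have transitions"
        )
    n = len(trial.states) - 1
    freq: dict[tuple[str, str], float] = {}
    for a, b in zip(trial.states[:-1], trial.states[1:]):
        freq[(a, b)] = freq.get((a, b), 0.0) + 1.0 / n
    return freq
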