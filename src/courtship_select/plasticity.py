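"""Aligned-rank-transform (ART) factorial ANOVA for plasticity detection.

The design is two crossed factors: male strain (genetic differences among
males) and female strain (the social context a male courts in).  A *female*
main effect on a male trait is phenotypic plasticity; a *male × female*
interaction means strains do not shift in parallel.

Trait measurements (time-budget fractions, normalized CHC abundances,
per-trial transition frequencies) are far from normal, so a nonparametric
factorial procedure is used: for each effect the response is *aligned*
(every other estimated effect is subtracted out), the aligned values are
ranked (midranks for ties), a standard two-factor ANOVA is fitted to the
ranks, and only the target effect's F is read off.  Unbalanced designs use
Type-III sums of squares with sum-to-zero coding; marginal and grand means
are unweighted means of cell means, so alignment and the linear-model
effects agree.

One deliberate refinement over align-the-raw-data ART: ``art_anova`` first
midrank-transforms the response and aligns the *ranks*.  The procedure is
then exactly invariant under any strictly monotone transformation of the
response (only the ordering enters), while keeping the null calibration and
power of classic ART; on rank-scaled input the two coincide.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist, rankdata

from .errors import DegenerateStatisticsError, ValidationError

__all__ = [
    "EFFECTS",
    "PlasticityResult",
    "art_align",
    "art_anova",
    "art_anova_table",
    "reaction_norms",
]

EFFECTS = ("male", "female", "interaction")


@dataclasses.dataclass
class PlasticityResult:
    """F, df and p per effect for one response variable."""

    trait: str
    effects: dict[str, dict[str, float]]  # effect -> {F, df_num, df_den, p}

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for eff in EFFECTS:
            row = {"trait": self.trait, "effect": eff}
            row.update(self.effects[eff])
            rows.append(row)
        return pd.DataFrame(rows)


def _codes(df: pd.DataFrame, male: str, female: str):
    a_levels = sorted(df[male].astype(str).unique())
    b_levels = sorted(df[female].astype(str).unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValidationError("both factors need ≥2 observed levels")
    a = df[male].astype(str).map({l: i for i, l in enumerate(a_levels)}).to_numpy()
    b = df[female].astype(str).map({l: i for i, l in enumerate(b_levels)}).to_numpy()
    return a, b, a_levels, b_levels


def _cell_means(y, a, b, na, nb):
    """Unweighted cell means; raises naming any empty cell."""
    sums = np.zeros((na, nb))
    ns = np.zeros((na, nb))
    np.add.at(sums, (a, b), y)
    np.add.at(ns, (a, b), 1.0)
    if (ns == 0).any():
        empty = [(int(i), int(j)) for i, j in zip(*np.nonzero(ns == 0))]
        raise ValidationError(
            f"empty design cells make the ART alignment undefined: {empty}"
        )
    return sums / ns


def art_align(
    data: pd.DataFrame,
    effect: str,
    response: str = "response",
    male: str = "male_strain",
    female: str = "female_strain",
) -> np.ndarray:
    """Align responses for one effect, removing the other estimated effects.

    main effect:   y − cellmean(A×B) + margmean(target)
    interaction:   y − margmean(A) − margmean(B) + grand

    Marginal/grand means are unweighted means of cell means; in a balanced
    design every non-target estimated effect is exactly removed from the
    aligned responses.
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    y = data[response].to_numpy(dtype=float)
    a, b, a_levels, b_levels = _codes(data, male, female)
    cm = _cell_means(y, a, b, len(a_levels), len(b_levels))
    marg_a = cm.mean(axis=1)
    marg_b = cm.mean(axis=0)
    grand = cm.mean()
    if effect == "male":
        return y - cm[a, b] + marg_a[a]
    if effect == "female":
        return y - cm[a, b] + marg_b[b]
    return y - marg_a[a] - marg_b[b] + grand


def _sum_code(codes: np.ndarray, k: int) -> np.ndarray:
    X = np.zeros((len(codes), k - 1))
    for j in range(k - 1):
        X[:, j] = (codes == j).astype(float) - (codes == k - 1).astype(float)
    return X


def _sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def art_anova(
    data: pd.DataFrame,
    response: str = "response",
    male: str = "male_strain",
    female: str = "female_strain",
    trait: str | None = None,
    prerank: bool = True,
) -> PlasticityResult:
    """ART two-factor ANOVA: one (F, df, p) triple per effect.

    ``prerank=True`` (default) midranks the response first, which makes the
    whole procedure exactly monotone-transform invariant; ``False`` aligns
    the raw values (classic ART).
    """
    df = data.dropna(subset=[response]).copy()
    y0 = df[response].to_numpy(dtype=float)
    a, b, a_levels, b_levels = _codes(df, male, female)
    na, nb = len(a_levels), len(b_levels)
    n = len(y0)
    df_den = n - na * nb
    if df_den <= 0:
        raise DegenerateStatisticsError(
            "no residual degrees of freedom: need ≥2 replicates in some cell"
        )
    _cell_means(y0, a, b, na, nb)  # validates all cells are filled
    if prerank:
        y0 = rankdata(y0)

    one = np.ones((n, 1))
    Xa = _sum_code(a, na)
    Xb = _sum_code(b, nb)
    Xab = np.hstack(
        [Xa[:, [i]] * Xb[:, [j]] for i in range(na - 1) for j in range(nb - 1)]
    )
    full = np.hstack([one, Xa, Xb, Xab])
    reduced = {
        "male": np.hstack([one, Xb, Xab]),
        "female": np.hstack([one, Xa, Xab]),
        "interaction": np.hstack([one, Xa, Xb]),
    }
    df_num = {"male": na - 1, "female": nb - 1, "interaction": (na - 1) * (nb - 1)}

    work = pd.DataFrame({response: y0, male: df[male].to_numpy(), female: df[female].to_numpy()})
    effects = {}
    scale = float(n * n)  # tolerance on rank-scale sums of squares
    for eff in EFFECTS:
        ranked = rankdata(art_align(work, eff, response, male, female))
        sse_full = _sse(ranked, full)
        ss_eff = _sse(ranked, reduced[eff]) - sse_full
        if ss_eff <= 1e-10 * scale:
            F, p = 0.0, 1.0
        elif sse_full <= 1e-10 * scale:
            F, p = float("inf"), 0.0
        else:
            F = (ss_eff / df_num[eff]) / (sse_full / df_den)
            p = float(f_dist.sf(F, df_num[eff], df_den))
        effects[eff] = {
            "F": float(F),
            "df_num": int(df_num[eff]),
            "df_den": int(df_den),
            "p": p,
        }
    return PlasticityResult(trait=trait or response, effects=effects)


def art_anova_table(
    data: pd.DataFrame,
    traits: list[str],
    male: str = "male_strain",
    female: str = "female_strain",
) -> pd.DataFrame:
    """Wide per-trait table: F and p for male, female and interaction effects."""
    rows = []
    for trait in traits:
        res = art_anova(data, response=trait, male=male, female=female, trait=trait)
        row = {"trait": trait}
        for eff in EFFECTS:
            row[f"{eff}_F"] = res.effects[eff]["F"]
            row[f"{eff}_p"] = res.effects[eff]["p"]
        rows.append(row)
    return pd.DataFrame(rows)


def reaction_norms(
    data: pd.DataFrame,
    response: str = "response",
    male: str = "male_strain",
    female: str = "female_strain",
) -> dict:
    """Per-male-strain means in each female context plus a parallelism summary.

    With exactly two contexts, each strain observed in both gets a context
    difference (second sorted level minus first); strains seen in one
    context only are reported with ``difference = None`` — males that never
    copulated with the other female strain.  The parallelism summary counts
    difference signs (e.g. 12/12 negative = consistent plasticity).
    """
    df = data.dropna(subset=[response])
    means = (
        df.groupby([male, female], sort=True)[response]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_response", "count": "n"})
    )
    contexts = sorted(df[female].astype(str).unique())
    differences: dict[str, float | None] = {}
    if len(contexts) == 2:
        lo, hi = contexts
        for strain, sub in means.groupby(male):
            vals = {str(r[female]): r["mean_response"] for _, r in sub.iterrows()}
            if lo in vals and hi in vals:
                differences[str(strain)] = float(vals[hi] - vals[lo])
            else:
                differences[str(strain)] = None
    signs = [d for d in differences.values() if d is not None]
    summary = {
        "contexts": contexts,
        "n_strains": means[male].nunique(),
        "n_compared": len(signs),
        "n_positive": sum(d > 0 for d in signs),
        "n_negative": sum(d < 0 for d in signs),
        "n_zero": sum(d == 0 for d in signs),
    }
    return {"means": means, "differences": differences, "parallelism": summary}
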