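"""Selection-gradient estimation on standardized male traits.

The unit of analysis is the male strain mean (behavioural time budgets and
normalized CHC abundances), per female context.  Traits are z-standardized
(mean 0, SD 1, n−1 convention); fitness is copulation-latency based and
scaled to relative fitness w with mean 1.  The linear selection gradient β
for a trait is the slope of w on z fitted at the *median* (least absolute
deviations / τ = 0.5 quantile regression), which is robust to the outliers
small strain panels produce; its 95% CI comes from a seeded case-resampling
bootstrap (percentile interval).  Mating-success selection is estimated
separately as a binomial (logistic) regression of successes/trials on z.

Sign convention: with the default ``inverse_latency`` fitness, traits whose
larger values shorten copulation latency get β > 0 — positive coefficients
mean positive selection.  (The literal ``latency`` convention, w = t/mean t,
is also available; note it reverses every sign.)
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticsError, ValidationError

__all__ = [
    "GradientResult",
    "BinomialResult",
    "standardize",
    "relative_fitness",
    "median_regression",
    "binomial_success_regression",
    "variable_select",
    "pca_traits",
    "build_trait_table",
    "selection_table",
]


@dataclasses.dataclass
class GradientResult:
    """Median-regression selection gradient with bootstrap CI."""

    beta: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int | None
    method: str
    trait: str | None = None
    female_strain: str | None = None

    @property
    def excludes_zero(self) -> bool:
        return bool(self.ci_low > 0 or self.ci_high < 0)


@dataclasses.dataclass
class BinomialResult:
    """Logistic regression of mating success on a standardized trait."""

    coef: float
    intercept: float
    ci_low: float
    ci_high: float
    se: float
    separated: bool
    n: int
    trait: str | None = None
    female_strain: str | None = None

    @property
    def excludes_zero(self) -> bool:
        if self.separated:
            return False
        return bool(self.ci_low > 0 or self.ci_high < 0)


# ---------------------------------------------------------------------------
# standardization and fitness


def standardize(x: Sequence[float], name: str = "trait") -> np.ndarray:
    """z = (x − mean)/SD with the sample (n−1) SD; mean 0, SD 1 exactly."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValidationError(f"{name}: need ≥2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateStatisticsError(f"{name}: zero variance, cannot standardize")
    return (x - x.mean()) / sd


def relative_fitness(
    latencies: Sequence[float], convention: str = "inverse_latency"
) -> np.ndarray:
    """Scale latency-based fitness to mean 1.

    ``inverse_latency`` (default): w = (1/t) / mean(1/t) — faster copulation
    is higher fitness, so positive gradients are positive selection.
    ``latency``: w = t / mean(t) (the literal formula; signs flip).
    ``mating_index``: input values are mating indices (larger = worse, may
    be ``inf`` for never-mating combinations); w = (1/m) / mean(1/m).
    """
    t = np.asarray(latencies, dtype=float)
    if convention == "mating_index":
        if (t <= 0).any():
            raise ValidationError("mating indices must be positive")
        inv = np.where(np.isinf(t), 0.0, 1.0 / t)
        if inv.mean() == 0:
            raise DegenerateStatisticsError("all mating indices are infinite")
        return inv / inv.mean()
    if (t <= 0).any() or not np.isfinite(t).all():
        raise ValidationError("latencies must be positive and finite")
    if convention == "latency":
        return t / t.mean()
    if convention == "inverse_latency":
        inv = 1.0 / t
        return inv / inv.mean()
    raise ValueError(f"unknown fitness convention {convention!r}")


# ---------------------------------------------------------------------------
# median (L1 / tau = 0.5 quantile) regression


def _l1_fit_enumerate(z: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Exact LAD line: some optimum passes through two data points.

    Enumerates every line through a pair of points with distinct z and takes
    the one with minimal absolute loss (first minimum on ties).
    """
    n = len(z)
    i, j = np.triu_indices(n, 1)
    dz = z[j] - z[i]
    ok = np.abs(dz) > 1e-12
    if not ok.any():
        raise DegenerateStatisticsError("all trait values identical")
    i, j, dz = i[ok], j[ok], dz[ok]
    beta = (w[j] - w[i]) / dz
    alpha = w[i] - beta * z[i]
    loss = np.abs(w[None, :] - alpha[:, None] - beta[:, None] * z[None, :]).sum(axis=1)
    k = int(np.argmin(loss))
    return float(alpha[k]), float(beta[k]), float(loss[k])


def _l1_fit_lp(z: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """LAD line by linear programming (HiGHS): min Σ(u+v), w = a + βz + u − v."""
    from scipy.optimize import linprog

    n = len(z)
    c = np.concatenate([[0.0, 0.0], np.ones(2 * n)])
    A_eq = np.hstack([np.ones((n, 1)), z[:, None], np.eye(n), -np.eye(n)])
    bounds = [(None, None), (None, None)] + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=w, bounds=bounds, method="highs")
    if not res.success:
        raise DegenerateStatisticsError(f"L1 fit failed: {res.message}")
    a, b = float(res.x[0]), float(res.x[1])
    return a, b, float(np.abs(w - a - b * z).sum())


def _l1_fit(z, w, method="auto"):
    if method == "auto":
        method = "enumerate" if len(z) <= 60 else "linprog"
    if method == "enumerate":
        return _l1_fit_enumerate(z, w)
    if method == "linprog":
        return _l1_fit_lp(z, w)
    raise ValueError(f"unknown L1 method {method!r}")


def median_regression(
    z: Sequence[float],
    w: Sequence[float],
    n_boot: int = 2000,
    seed: int | None = 0,
    method: str = "auto",
    trait: str | None = None,
    female_strain: str | None = None,
) -> GradientResult:
    """Selection gradient: LAD slope of relative fitness on a standardized trait.

    The point fit is exact (pair enumeration for small n, LP otherwise).
    The 95% CI is a case-resampling bootstrap: rows (z, w) are resampled
    with replacement ``n_boot`` times with a seeded generator and the 2.5/
    97.5 percentiles of the refitted slopes are reported.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if len(z) != len(w):
        raise ValidationError("z and w must have equal length")
    if len(z) < 3:
        raise ValidationError("median regression needs n ≥ 3")
    if np.ptp(z) < 1e-12:
        raise DegenerateStatisticsError("all trait values identical")
    a, b, _ = _l1_fit(z, w, method)

    rng = np.random.default_rng(seed)
    n = len(z)
    betas = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        for _attempt in range(20):
            idx = rng.integers(0, n, n)
            if np.ptp(z[idx]) > 1e-12:
                break
        else:
            continue
        betas[kept] = _l1_fit(z[idx], w[idx], method)[1]
        kept += 1
    if kept == 0:
        raise DegenerateStatisticsError("bootstrap degenerate: no valid resamples")
    lo, hi = np.percentile(betas[:kept], [2.5, 97.5])
    return GradientResult(
        beta=b,
        intercept=a,
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        n_boot=kept,
        seed=seed,
        method=method,
        trait=trait,
        female_strain=female_strain,
    )


# ---------------------------------------------------------------------------
# binomial (logistic) regression of mating success

_SEPARATION_COEF = 15.0


def binomial_success_regression(
    z: Sequence[float],
    successes: Sequence[int],
    trials: Sequence[int],
    trait: str | None = None,
    female_strain: str | None = None,
) -> BinomialResult:
    """logit(p_i) = a + b·z_i fitted by IRLS to the binomial likelihood.

    Wald 95% CI.  Complete/quasi-complete separation is detected (diverging
    estimates) and reported as a flag instead of a finite coefficient.
    """
    import statsmodels.api as sm

    z = np.asarray(z, dtype=float)
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    if not (len(z) == len(s) == len(t)):
        raise ValidationError("z, successes, trials must have equal length")
    if len(z) < 3:
        raise ValidationError("binomial regression needs ≥3 strains")
    if (t < 1).any():
        raise ValidationError("every strain needs ≥1 trial")
    if ((s < 0) | (s > t)).any():
        raise ValidationError("successes must lie in [0, trials]")

    X = sm.add_constant(z)
    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(
                np.column_stack([s, t - s]), X, family=sm.families.Binomial()
            ).fit(maxiter=200)
            a, b = fit.params
            se_a, se_b = fit.bse
        except Exception:
            separated = True
            a = b = se_a = se_b = float("nan")
    if not separated and (
        abs(b) > _SEPARATION_COEF or not np.isfinite(se_b) or se_b > 50
    ):
        separated = True
    if separated:
        sign = 0.0
        if np.isfinite(b):
            sign = np.sign(b)
        return BinomialResult(
            coef=float(sign) * float("inf") if sign else float("nan"),
            intercept=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            se=float("inf"),
            separated=True,
            n=len(z),
            trait=trait,
            female_strain=female_strain,
        )
    return BinomialResult(
        coef=float(b),
        intercept=float(a),
        ci_low=float(b - 1.959963984540054 * se_b),
        ci_high=float(b + 1.959963984540054 * se_b),
        se=float(se_b),
        separated=False,
        n=len(z),
        trait=trait,
        female_strain=female_strain,
    )


# ---------------------------------------------------------------------------
# variable reduction (two-stage randomized-tree screening)


def variable_select(
    traits: pd.DataFrame,
    response: Sequence[float],
    seed: int = 0,
    n_fits: int = 50,
    n_trees: int = 100,
    refit_fits: int = 10,
) -> list[str]:
    """Two-stage random-forest variable reduction (thresholding then
    interpretation), in the spirit of the VSURF procedure.

    Stage 1 (*thresholding*): over ``n_fits`` seeded forest fits, each on a
    random half of the rows, permutation importance of every trait is
    measured on the held-out half.  Traits are ranked by mean importance;
    the noise floor is the mean importance-SD of the lower half of the
    ranking, and traits whose mean importance does not exceed it are
    dropped.

    Stage 2 (*interpretation*): surviving traits are forward-added in
    importance order; a trait is kept only if it lowers the out-of-bag MSE
    of the growing model by more than one SD of the current error estimate.

    Deterministic given ``seed``.  Returns trait names in importance order.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    y = np.asarray(response, dtype=float)
    if traits.shape[1] < 2 or traits.shape[0] < 4:
        raise ValidationError("variable_select needs ≥2 traits and ≥4 rows")
    if np.ptp(y) == 0:
        raise DegenerateStatisticsError("constant response: nothing to explain")
    X = traits.to_numpy(dtype=float)
    cols = list(traits.columns)
    n, p = X.shape
    rng = np.random.default_rng(seed)

    imps = np.zeros((n_fits, p))
    for r in range(n_fits):
        perm = rng.permutation(n)
        half = max(4, n // 2)
        tr, te = perm[:half], perm[half:]
        if len(te) < 2:
            tr = te = perm
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31)),
            max_features=max(1, p // 3),
        )
        rf.fit(X[tr], y[tr])
        pi = permutation_importance(
            rf, X[te], y[te], n_repeats=3, random_state=int(rng.integers(2**31))
        )
        imps[r] = pi.importances_mean
    mean_imp = imps.mean(axis=0)
    sd_imp = imps.std(axis=0, ddof=1)
    order = np.argsort(-mean_imp)
    lower = order[p // 2 :]
    threshold = float(sd_imp[lower].mean()) if len(lower) else 0.0
    kept = [cols[k] for k in order if mean_imp[k] > threshold]
    if not kept:
        return []

    def oob_mse(subset: list[str]) -> tuple[float, float]:
        Xi = traits[subset].to_numpy(dtype=float)
        errs = []
        for _ in range(refit_fits):
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31)),
                max_features=max(1, len(subset) // 3) if len(subset) > 1 else 1,
                bootstrap=True,
                oob_score=True,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rf.fit(Xi, y)
                pred = rf.oob_prediction_
            ok = np.isfinite(pred)
            errs.append(float(np.mean((pred[ok] - y[ok]) ** 2)))
        return float(np.mean(errs)), float(np.std(errs, ddof=1))

    selected = [kept[0]]
    best_mean, best_sd = oob_mse(selected)
    for trait in kept[1:]:
        cand_mean, cand_sd = oob_mse(selected + [trait])
        if cand_mean < best_mean - best_sd:
            selected.append(trait)
            best_mean, best_sd = cand_mean, cand_sd
    return selected


# ---------------------------------------------------------------------------
# PCA of combined trait means


def pca_traits(trait_matrix: pd.DataFrame) -> dict:
    """PCA on the trait correlation matrix (strains × traits).

    Columns are standardized internally, so the decomposition is of the
    correlation matrix.  Sign convention: within each component the loading
    of largest magnitude is made positive, so repeated runs are identical.
    Returns ``scores`` (strains × PCs), ``loadings`` (traits × PCs) and
    ``explained`` (variance fractions, summing to 1).
    """
    if trait_matrix.shape[0] < 3:
        raise ValidationError("PCA needs ≥3 strains")
    if trait_matrix.shape[1] < 2:
        raise ValidationError("PCA needs ≥2 traits")
    Z = np.column_stack(
        [standardize(trait_matrix[c], name=str(c)) for c in trait_matrix.columns]
    )
    C = (Z.T @ Z) / (Z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    ncomp = evecs.shape[1]
    names = [f"PC{i+1}" for i in range(ncomp)]
    return {
        "scores": pd.DataFrame(Z @ evecs, index=trait_matrix.index, columns=names),
        "loadings": pd.DataFrame(evecs, index=trait_matrix.columns, columns=names),
        "explained": pd.Series(evals / evals.sum(), index=names),
    }


# ---------------------------------------------------------------------------
# trait tables and the per-female selection analysis


def build_trait_table(
    summaries: pd.DataFrame,
    female_strain: str,
    chc_means: pd.DataFrame | None = None,
    behavior_traits: Sequence[str] = ("singing", "attempted_copulation"),
    fitness: str = "inverse_latency",
    drop_zero_success: bool = True,
) -> pd.DataFrame:
    """Per-male-strain trait table for one female context.

    Rows are male strains; behavioural traits are strain means of per-trial
    budgets (courting trials only), CHC traits are strain means of
    normalized abundances.  Adds standardized ``z_<trait>`` columns,
    ``successes``/``trials`` counts, mean successful latency and — unless
    the strain never mated and ``drop_zero_success`` — relative fitness
    ``w`` (mean 1 over the rows kept).
    """
    from .behavior import mating_index

    sub = summaries[summaries["female_strain"].astype(str) == str(female_strain)]
    if sub.empty:
        raise ValidationError(f"no trials for female strain {female_strain!r}")
    courting = sub[sub["initiation_index"].notna()]
    max_observed = sub.loc[~sub["censored"].astype(bool), "copulation_latency_s"].max()
    rows = []
    for strain, grp in sub.groupby("male_strain"):
        court = courting[courting["male_strain"] == strain]
        success = grp[~grp["censored"].astype(bool)]
        lat = success["copulation_latency_s"].dropna()
        row = {
            "male_strain": strain,
            "successes": int((~grp["censored"].astype(bool)).sum()),
            "trials": int(len(grp)),
            "latency_s": float(lat.mean()) if len(lat) else float("nan"),
        }
        if fitness == "mating_index" and np.isfinite(max_observed):
            per_trial = [
                float(r["copulation_latency_s"])
                if not bool(r["censored"]) and pd.notna(r["copulation_latency_s"])
                else None
                for _, r in grp.iterrows()
            ]
            row["mating_index"] = mating_index(
                per_trial, row["successes"], row["trials"], float(max_observed)
            )
        for tr in behavior_traits:
            row[tr] = float(court[tr].mean()) if tr in court and len(court) else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("male_strain").sort_index()
    if chc_means is not None:
        table = table.join(chc_means, how="left")
    if drop_zero_success:
        if fitness == "mating_index":
            # the mating index is defined for never-mating strains too
            # (failures set to the maximum observed time, weighted by the
            # mated proportion → w = 0 at zero successes), so they stay in
            if len(table) < 3:
                raise DegenerateStatisticsError(
                    f"female {female_strain}: fewer than 3 strains"
                )
            table["w"] = relative_fitness(
                table.pop("mating_index").to_numpy(), "mating_index"
            )
        else:
            # latency-based fitness needs a measurable latency: a strain
            # whose only successful bouts lack a scoreable initiation cannot
            # enter the gradient regression (it stays in the binomial tables)
            table = table[(table["successes"] > 0) & table["latency_s"].notna()]
            if len(table) < 3:
                raise DegenerateStatisticsError(
                    f"female {female_strain}: fewer than 3 strains with successful matings"
                )
            table["w"] = relative_fitness(table["latency_s"].to_numpy(), fitness)
    elif "mating_index" in table.columns:
        table = table.drop(columns=["mating_index"])
    trait_cols = [c for c in table.columns if c not in {"successes", "trials", "latency_s", "w"}]
    for c in trait_cols:
        vals = table[c].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError(f"trait {c}: missing strain means")
        table[f"z_{c}"] = standardize(vals, name=str(c))
    return table


def selection_table(
    tables: dict[str, pd.DataFrame],
    traits: Sequence[str],
    n_boot: int = 2000,
    seed: int = 0,
    binomial_tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Gradient + binomial coefficients per trait × female strain.

    ``tables`` maps female strain → trait table from
    :func:`build_trait_table` (zero-success strains dropped);
    ``binomial_tables`` optionally maps to tables retaining those strains
    for the mating-success regressions.
    """
    rows = []
    for fi, (female, table) in enumerate(sorted(tables.items())):
        btable = (binomial_tables or {}).get(female, table)
        for ti, trait in enumerate(traits):
            zcol = f"z_{trait}"
            if zcol not in table:
                raise ValidationError(f"trait {trait!r} missing from table for {female}")
            grad = median_regression(
                table[zcol].to_numpy(),
                table["w"].to_numpy(),
                n_boot=n_boot,
                seed=(seed or 0) + 1000 * fi + ti,
                trait=trait,
                female_strain=female,
            )
            bin_ = binomial_success_regression(
                btable[zcol].to_numpy(),
                btable["successes"].to_numpy(),
                btable["trials"].to_numpy(),
                trait=trait,
                female_strain=female,
            )
            rows.append(
                {
                    "trait": trait,
                    "female_strain": female,
                    "gradient": grad.beta,
                    "gradient_ci_low": grad.ci_low,
                    "gradient_ci_high": grad.ci_high,
                    "gradient_significant": grad.excludes_zero,
                    "binomial_coef": bin_.coef,
                    "binomial_ci_low": bin_.ci_low,
                    "binomial_ci_high": bin_.ci_high,
                    "binomial_significant": bin_.excludes_zero,
                    "binomial_separated": bin_.separated,
                    "n": grad.n,
                }
            )
    return pd.DataFrame(rows)
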