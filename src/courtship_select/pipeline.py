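"""End-to-end analysis driver: events + CHC tables in, result tables out.

`run_all` chains the full analysis — trial summaries, plasticity ANOVAs,
per-male-strain sequence homogeneity tests, selection gradients + binomial
regressions, and the trait PCA — and writes each stage as TSV plus a
provenance manifest (package version, config hash, seed).  Identical config
and data give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .behavior import compare_initiation_methods, summarize_panel
from .errors import ValidationError
from .io import (
    chc_profiles_to_frame,
    normalize_chc,
    read_event_log,
    write_results,
)
from .markov import homogeneity_by_male_strain
from .plasticity import art_anova_table
from .selection import build_trait_table, pca_traits, selection_table, variable_select
from .states import ACTIVE_STATES

__all__ = ["RunConfig", "run_all"]

DEFAULT_BEHAVIOR_TRAITS = ("engaging", "singing", "attempted_copulation", "circling", "scissoring")


@dataclasses.dataclass
class RunConfig:
    events: str
    outdir: str
    chc: str | None = None
    interval_s: float = 10.0
    initiation_method: str = "consecutive3"
    fitness: str = "inverse_latency"
    n_boot: int = 2000
    seed: int = 0
    alpha: float = 0.05
    homogeneity_statistic: str = "pearson"
    selection_behavior_traits: tuple[str, ...] = ("singing", "attempted_copulation")
    pca_female: str | None = None  # default: first female strain alphabetically
    variable_selection: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_boot < 100:
            raise ValidationError("n_boot must be ≥ 100")

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the result bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = read_event_log(config.events, interval_s=config.interval_s)
    summaries = summarize_panel(trials, config.initiation_method)
    diagnostics = compare_initiation_methods(trials)

    courting = summaries[summaries["initiation_index"].notna()]
    # ART needs a full factorial: keep male strains observed courting in
    # every female context (strains seen in one context only still appear in
    # reaction norms and selection tables)
    n_ctx = courting["female_strain"].nunique()
    seen = courting.groupby("male_strain")["female_strain"].nunique()
    complete = seen[seen == n_ctx].index
    courting_full = courting[courting["male_strain"].isin(complete)]
    plast_traits = [t for t in DEFAULT_BEHAVIOR_TRAITS if t in courting_full.columns]
    table1 = art_anova_table(courting_full, plast_traits)

    markov_table = homogeneity_by_male_strain(trials, statistic=config.homogeneity_statistic)

    results: dict = {
        "summaries": summaries,
        "initiation_diagnostics": diagnostics,
        "plasticity": table1,
        "markov": markov_table,
    }

    chc_means = None
    chc_trait_names: list[str] = []
    if config.chc:
        profiles = normalize_chc(config.chc)
        frame = chc_profiles_to_frame(profiles)
        males = frame[(frame["sex"] == "M") & (frame["treatment"] == "virgin")]
        chc_means = males.drop(columns=["individual", "sex", "treatment"]).groupby("strain").mean()
        chc_trait_names = list(chc_means.columns)

    females = sorted(summaries["female_strain"].astype(str).unique())
    traits = list(config.selection_behavior_traits) + chc_trait_names
    tables, btables = {}, {}
    for female in females:
        try:
            tables[female] = build_trait_table(
                summaries, female, chc_means,
                behavior_traits=config.selection_behavior_traits,
                fitness=config.fitness,
            )
            btables[female] = build_trait_table(
                summaries, female, chc_means,
                behavior_traits=config.selection_behavior_traits,
                fitness=config.fitness, drop_zero_success=False,
            )
        except ValidationError:
            continue
    if tables:
        if config.variable_selection:
            chosen: set[str] = set()
            for female, table in tables.items():
                picked = variable_select(
                    table[[f"z_{t}" for t in traits]].rename(
                        columns=lambda c: c[2:]
                    ),
                    table["w"].to_numpy(),
                    seed=config.seed,
                )
                chosen.update(picked)
            traits = [t for t in traits if t in chosen] or traits
        results["selection"] = selection_table(
            tables, traits, n_boot=config.n_boot, seed=config.seed,
            binomial_tables=btables,
        )
        pca_female = config.pca_female or females[0]
        if pca_female in tables:
            tmat = tables[pca_female][[f"z_{t}" for t in traits]]
            if tmat.shape[0] >= 3 and tmat.shape[1] >= 2:
                pca = pca_traits(tmat.rename(columns=lambda c: c[2:]))
                results["pca"] = pca
                results["pca_female"] = pca_female

    manifest = {
        "package": "courtship-select",
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_trials": len(trials),
        "initiation_diagnostics": diagnostics,
        "stages": sorted(k for k in results if k != "summaries"),
    }
    results["manifest"] = manifest

    write_results(summaries, outdir / "summaries.tsv")
    write_results(table1, outdir / "plasticity.tsv")
    if len(markov_table):
        write_results(markov_table, outdir / "markov.tsv")
    if "selection" in results:
        write_results(results["selection"], outdir / "selection.tsv")
    if "pca" in results:
        write_results(
            results["pca"]["loadings"].reset_index(names="trait"), outdir / "pca_loadings.tsv"
        )
        write_results(
            results["pca"]["scores"].reset_index(names="male_strain"), outdir / "pca_scores.tsv"
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return results
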