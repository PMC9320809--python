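"""Synthetic courtship panels with known ground truth.

The generator emulates the structure the analysis assumes, so every
estimator downstream can be checked against known truth:

* eight-state courtship sequences on a 10-s grid, up to 30 min, with
  ``copulating`` absorbing;
* per-(male strain × female context) transition matrices — a baseline
  courtship chain tilted by each strain's singing propensity and by the
  female context (more singing with M-like females, more
  singing→attempted-copulation with Z-like females);
* trait-linked copulation latency: log-latency is linear in the strain's
  standardized latent traits with context-specific gradients, plus
  log-normal noise.  The chain is coupled to the drawn latency by a uniform
  per-step absorption hazard 1/latency once courtship has initiated, so
  sequence structure and fitness structure stay independently controllable;
* mating success: logit(p) linear in the same latent traits;
* per-strain CHC profiles: log-normal abundances whose strain means track
  latent trait values;
* asymmetric isolation: configured strain × female combinations never mate
  (and may never even court — an all-``separate`` trial with a small escape
  probability — to exercise the exclusion rules).

Reproducibility: one master seed; every trial and every strain's CHC draw
uses its own counter-derived substream, so panels are byte-identical across
runs and stable under partial regeneration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CHCProfile, EthogramTrial, trials_to_events
from .states import BEHAVIOR_STATES, COPULATING, SEPARATE, STATE_INDEX

__all__ = [
    "BASELINE_MATRIX",
    "SimulationConfig",
    "SimulatedPanel",
    "default_config",
    "transition_matrix_for",
    "simulate_trial",
    "simulate_panel",
    "simulate_transition_stream",
    "write_panel",
]

_K = len(BEHAVIOR_STATES)
_COP = STATE_INDEX[COPULATING]
_SEP = STATE_INDEX[SEPARATE]
_SINGING = STATE_INDEX["singing"]
_ATTEMPT = STATE_INDEX["attempted_copulation"]

#: Baseline courting chain over the 7 active states (structured support:
#: courtship moves through engaging → singing → escalation, with dwell-time
#: self-loops; ``copulating`` is entered only through the absorption hazard).
BASELINE_MATRIX = np.array(
    [
        # sep   eng   sing  sing2 sciss circ  att   cop
        [0.55, 0.35, 0.10, 0.00, 0.00, 0.00, 0.00, 0.0],
        [0.15, 0.40, 0.35, 0.00, 0.05, 0.05, 0.00, 0.0],
        [0.00, 0.15, 0.45, 0.12, 0.08, 0.05, 0.15, 0.0],
        [0.00, 0.00, 0.35, 0.45, 0.10, 0.00, 0.10, 0.0],
        [0.00, 0.10, 0.30, 0.00, 0.45, 0.10, 0.05, 0.0],
        [0.00, 0.00, 0.30, 0.00, 0.10, 0.45, 0.15, 0.0],
        [0.10, 0.10, 0.35, 0.00, 0.00, 0.00, 0.45, 0.0],
        [0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00, 1.0],
    ]
)


@dataclasses.dataclass
class SimulationConfig:
    male_strains: list[str]
    female_strains: tuple[str, str] = ("Zlike", "Mlike")
    interval_s: float = 10.0
    max_timepoints: int = 180  # 30 min at 10 s
    trials_per_pair: int = 5
    #: strains × latent traits (z-scale); "singing" tilts the chain, the CHC
    #: columns drive profiles, and the gradient/success models read any column
    latent: pd.DataFrame | None = None
    chc_compounds: tuple[str, ...] = ("cVA", "7-C25", "7-C23", "n-C21", "n-C22", "5-C25")
    gradients: dict = dataclasses.field(default_factory=dict)  # female -> {trait: γ}
    success_coefs: dict = dataclasses.field(default_factory=dict)
    success_base: float = 1.0  # logit of baseline mating probability
    base_latency_timepoints: float = 30.0  # 300 s median courting time
    latency_sigma: float = 0.35  # lognormal SD of log-latency
    singing_tilt_strain: float = 0.30  # per latent-z log-tilt of singing mass
    singing_tilt_context: dict = dataclasses.field(default_factory=dict)
    attempt_tilt_context: dict = dataclasses.field(default_factory=dict)
    chc_log_base: float = 0.0
    chc_log_strain_sd: float = 0.40
    chc_log_noise_sd: float = 0.15
    chc_individuals_per_strain: int = 3
    never_mate: dict = dataclasses.field(default_factory=dict)  # male -> female
    noncourt_pairs: dict = dataclasses.field(default_factory=dict)  # male -> female
    noncourt_escape: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.trials_per_pair < 1:
            raise ValidationError("trials_per_pair must be ≥ 1")
        if self.latency_sigma <= 0 or self.chc_log_strain_sd <= 0:
            raise ValidationError("variance parameters must be > 0")
        if self.latent is None or self.latent.empty:
            raise ValidationError("config.latent strain-trait table is required")
        missing = [m for m in self.male_strains if m not in self.latent.index]
        if missing:
            raise ValidationError(f"strains missing from latent table: {missing}")
        for female in self.female_strains:
            P = transition_matrix_for(self, self.male_strains[0], female)
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
                raise ValidationError("transition-matrix rows must sum to 1")
            if P[_COP, _COP] != 1.0:
                raise ValidationError("'copulating' must be absorbing")


@dataclasses.dataclass
class SimulatedPanel:
    trials: list[EthogramTrial]
    chc_profiles: list[CHCProfile]
    truth: dict
    config: SimulationConfig


def default_config(
    seed: int = 0, n_strains: int = 12, trials_per_pair: int = 5
) -> SimulationConfig:
    """The default study scenario with one divergently selected trait.

    12 male strains × 2 female contexts ("Zlike" ~ a southern-African
    genotype, "Mlike" ~ a cosmopolitan lab genotype).  Singing is plastic
    (more singing in the M-like context).  The CHC "cVA" is under divergent
    selection — positive in the M-like context, negative in the Z-like —
    and "7-C25" is beneficial only with Z-like females; all other traits
    are selectively neutral.  The first strain never courts Z-like females
    and the second courts but never mates with M-like females.
    """
    rng = np.random.default_rng(seed)
    strains = [f"S{i+1:02d}" for i in range(n_strains)]
    compounds = ("cVA", "7-C25", "7-C23", "n-C21", "n-C22", "5-C25")
    latent = pd.DataFrame(
        rng.standard_normal((n_strains, 1 + len(compounds))),
        index=strains,
        columns=["singing", *compounds],
    )
    cfg = SimulationConfig(
        male_strains=strains,
        trials_per_pair=trials_per_pair,
        latent=latent,
        chc_compounds=compounds,
        gradients={
            "Zlike": {"cVA": -0.3, "7-C25": 0.3},
            "Mlike": {"cVA": 0.3},
        },
        success_coefs={
            "Zlike": {"cVA": -0.8, "7-C25": 0.8},
            "Mlike": {"cVA": 0.8},
        },
        singing_tilt_context={"Zlike": -0.35, "Mlike": 0.35},
        attempt_tilt_context={"Zlike": 0.30, "Mlike": -0.30},
        never_mate={strains[0]: "Zlike", strains[1]: "Mlike"},
        noncourt_pairs={strains[0]: "Zlike"},
        seed=seed,
    )
    cfg.validate()
    return cfg


def _expected_latency_timepoints(cfg: SimulationConfig, male: str, female: str) -> float:
    mu = np.log(cfg.base_latency_timepoints)
    for trait, gamma in cfg.gradients.get(female, {}).items():
        mu -= gamma * float(cfg.latent.loc[male, trait])
    return float(np.exp(mu))


def transition_matrix_for(cfg: SimulationConfig, male: str, female: str) -> np.ndarray:
    """The pair's 8×8 row-stochastic matrix, absorption hazard included.

    The active block is the baseline chain with the singing column tilted by
    ``exp(strain tilt + context tilt)`` and the attempted-copulation column
    by ``exp(context tilt)``, rows renormalized.  The absorption hazard
    1/E[latency] is spread uniformly over the active rows.
    """
    P = BASELINE_MATRIX.copy()
    z_sing = float(cfg.latent.loc[male, "singing"]) if "singing" in cfg.latent else 0.0
    tilt_sing = np.exp(
        cfg.singing_tilt_strain * z_sing + cfg.singing_tilt_context.get(female, 0.0)
    )
    tilt_att = np.exp(cfg.attempt_tilt_context.get(female, 0.0))
    for i in range(_K - 1):
        row = P[i].copy()
        row[_SINGING] *= tilt_sing
        row[_ATTEMPT] *= tilt_att
        P[i] = row / row.sum()
    if cfg.never_mate.get(male) == female:
        hazard = 0.0
    else:
        hazard = min(0.5, 1.0 / _expected_latency_timepoints(cfg, male, female))
    for i in range(_K - 1):
        P[i, :_COP] *= 1.0 - hazard
        P[i, _COP] = hazard
    if cfg.noncourt_pairs.get(male) == female:
        P[:_COP] = 0.0
        P[:_COP, _SEP] = 1.0 - cfg.noncourt_escape
        P[: _COP, STATE_INDEX["engaging"]] = cfg.noncourt_escape
    return P


def simulate_trial(
    cfg: SimulationConfig,
    male: str,
    female: str,
    rng: np.random.Generator,
    trial_id: str = "T1",
) -> EthogramTrial:
    """One courtship bout from the pair's chain.

    The chain starts in ``separate``.  Once courtship has initiated (first
    non-separate state), each step absorbs into ``copulating`` with hazard
    1/L, where L is the trial's drawn latency — unless the trial is fated
    not to mate (success model, or a never-mate pair), in which case the
    hazard is zero and the trial runs to the 30-min cap (censored).
    """
    never = cfg.never_mate.get(male) == female
    noncourt = cfg.noncourt_pairs.get(male) == female

    mu = np.log(cfg.base_latency_timepoints)
    eta = cfg.success_base
    for trait, gamma in cfg.gradients.get(female, {}).items():
        mu -= gamma * float(cfg.latent.loc[male, trait])
    for trait, bcoef in cfg.success_coefs.get(female, {}).items():
        eta += bcoef * float(cfg.latent.loc[male, trait])
    L = float(np.clip(np.exp(rng.normal(mu, cfg.latency_sigma)), 4.0, 4.0 * cfg.max_timepoints))
    p_mate = 1.0 / (1.0 + np.exp(-eta))
    will_mate = (not never) and (not noncourt) and (rng.random() < p_mate)
    hazard = (1.0 / L) if will_mate else 0.0

    if noncourt:
        active = np.zeros((_K - 1, _K - 1))
        active[:, _SEP] = 1.0 - cfg.noncourt_escape
        active[:, STATE_INDEX["engaging"]] = cfg.noncourt_escape
    else:
        P = transition_matrix_for(cfg, male, female)
        block = P[: _K - 1, : _K - 1]
        # conditional chain given no absorption this step
        active = block / block.sum(axis=1, keepdims=True)
    cum = active.cumsum(axis=1)

    s = _SEP
    states = [SEPARATE]
    initiated = False
    for _ in range(cfg.max_timepoints):
        if initiated and hazard > 0 and rng.random() < hazard:
            states.append(COPULATING)
            break
        s = int(np.searchsorted(cum[s], rng.random(), side="right"))
        states.append(BEHAVIOR_STATES[s])
        if s != _SEP:
            initiated = True
    return EthogramTrial(
        trial_id=trial_id,
        states=states,
        male_strain=male,
        female_strain=female,
        interval_s=cfg.interval_s,
    )


def _trial_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def simulate_chc_profiles(cfg: SimulationConfig) -> list[CHCProfile]:
    profiles = []
    for si, strain in enumerate(cfg.male_strains):
        rng = _trial_rng(cfg.seed, 10_000, si)
        for ind in range(cfg.chc_individuals_per_strain):
            amounts = {}
            for c in cfg.chc_compounds:
                z = float(cfg.latent.loc[strain, c])
                amounts[c] = float(
                    np.exp(
                        cfg.chc_log_base
                        + cfg.chc_log_strain_sd * z
                        + rng.normal(0.0, cfg.chc_log_noise_sd)
                    )
                )
            profiles.append(
                CHCProfile(
                    individual_id=f"{strain}-M{ind+1}",
                    strain=strain,
                    sex="M",
                    treatment="virgin",
                    amounts=amounts,
                )
            )
    return profiles


def simulate_panel(cfg: SimulationConfig) -> SimulatedPanel:
    """Full factorial male × female panel plus CHC profiles and ground truth."""
    cfg.validate()
    trials = []
    pair_idx = 0
    for male in cfg.male_strains:
        for female in cfg.female_strains:
            for k in range(cfg.trials_per_pair):
                rng = _trial_rng(cfg.seed, pair_idx, k)
                trials.append(
                    simulate_trial(
                        cfg, male, female, rng, trial_id=f"{male}.{female}.{k+1}"
                    )
                )
            pair_idx += 1
    profiles = simulate_chc_profiles(cfg)

    divergent = []
    for trait in set().union(*(set(g) for g in cfg.gradients.values())) if cfg.gradients else set():
        signs = {np.sign(cfg.gradients.get(f, {}).get(trait, 0.0)) for f in cfg.female_strains}
        if 1.0 in signs and -1.0 in signs:
            divergent.append(trait)
    truth = {
        "gradients": cfg.gradients,
        "success_coefs": cfg.success_coefs,
        "plastic_traits": ["singing"],
        "singing_tilt_context": cfg.singing_tilt_context,
        "attempt_tilt_context": cfg.attempt_tilt_context,
        "divergent_traits": sorted(divergent),
        "never_mate": cfg.never_mate,
        "noncourt_pairs": cfg.noncourt_pairs,
        "matrices": {
            f"{m}|{f}": transition_matrix_for(cfg, m, f).tolist()
            for m in cfg.male_strains
            for f in cfg.female_strains
        },
        "latent": cfg.latent.to_dict(orient="index"),
        "seed": cfg.seed,
    }
    return SimulatedPanel(trials=trials, chc_profiles=profiles, truth=truth, config=cfg)


def simulate_transition_stream(
    P: np.ndarray, n_steps: int, rng: np.random.Generator, start: int = _SEP
) -> np.ndarray:
    """Count matrix from ``n_steps`` one-step transitions of a chain.

    On absorption the chain restarts in ``start`` (a new bout), so streams
    of arbitrary length can be drawn from matrices with an absorbing state.
    """
    counts = np.zeros((P.shape[0], P.shape[0]), dtype=np.int64)
    cum = P.cumsum(axis=1)
    u = rng.random(n_steps)
    s = start
    for t in range(n_steps):
        nxt = int(np.searchsorted(cum[s], u[t], side="right"))
        counts[s, nxt] += 1
        s = start if nxt == _COP else nxt
    return counts


def write_panel(panel: SimulatedPanel, outdir, standard_area: float = 100.0) -> dict:
    """Write events.csv, chc.csv (raw peak areas incl. the n-C26 internal
    standard) and truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = trials_to_events(panel.trials)
    events_path = outdir / "events.csv"
    events.to_csv(events_path, index=False)

    rows = []
    for p in panel.chc_profiles:
        for c, amount in p.amounts.items():
            rows.append(
                {
                    "individual": p.individual_id,
                    "strain": p.strain,
                    "sex": p.sex,
                    "treatment": p.treatment,
                    "compound": c,
                    "area": amount * standard_area,
                }
            )
        rows.append(
            {
                "individual": p.individual_id,
                "strain": p.strain,
                "sex": p.sex,
                "treatment": p.treatment,
                "compound": "n-C26",
                "area": standard_area,
            }
        )
    chc_path = outdir / "chc.csv"
    pd.DataFrame(rows).to_csv(chc_path, index=False)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(panel.truth, indent=1))
    return {"events": events_path, "chc": chc_path, "truth": truth_path}
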