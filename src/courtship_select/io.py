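"""Reading and writing the pipeline's tabular formats.

Three kinds of input are handled:

* **Event logs** from manual video scoring (BORIS-style exports): one row per
  scored timepoint ``(trial id, time in s, behavior label)``, optionally with
  strain metadata columns.  :func:`read_event_log` converts each trial to a
  fixed-interval state series (:class:`EthogramTrial`), snapping off-grid
  event times onto the grid.
* **CHC peak tables** from GC quantification: long-format rows
  ``(individual, strain, sex, treatment, compound, area)`` including a
  hexacosane (n-C26) internal standard.  :func:`normalize_chc` divides every
  peak area by the individual's internal-standard area.
* **Result tables**, written as TSV or JSON with full round-trip precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .states import BEHAVIOR_STATES, COPULATING, SEPARATE, canonical_state

__all__ = [
    "EthogramTrial",
    "CHCProfile",
    "read_event_log",
    "trials_to_events",
    "normalize_chc",
    "canonical_compound",
    "write_results",
    "read_results",
]

DEFAULT_INTERVAL_S = 10.0
DEFAULT_MAX_SPAN_S = 1800.0  # 30-min recordings


@dataclasses.dataclass
class EthogramTrial:
    """One courtship bout: state sequence on a fixed grid plus metadata.

    ``states[i]`` is the behaviour scored at grid time ``i * interval_s`` and
    represents the half-open interval ``[t, t + interval_s)``.
    """

    trial_id: str
    states: list[str]
    male_strain: str = ""
    female_strain: str = ""
    interval_s: float = DEFAULT_INTERVAL_S
    block_id: str | None = None
    max_span_s: float = DEFAULT_MAX_SPAN_S

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError(f"trial {self.trial_id}: empty state sequence")
        self.states = [canonical_state(s) for s in self.states]
        if self.interval_s <= 0:
            raise ValidationError(f"trial {self.trial_id}: interval_s must be > 0")
        # one grid point may sit at the recording-span boundary (the
        # copulation point of a full-length trial)
        if (len(self.states) - 1) * self.interval_s > self.max_span_s:
            raise ValidationError(
                f"trial {self.trial_id}: {len(self.states)} states at "
                f"{self.interval_s} s exceed the {self.max_span_s} s recording span"
            )
        n_cop = self.states.count(COPULATING)
        if n_cop > 1 or (n_cop == 1 and self.states[-1] != COPULATING):
            raise ValidationError(
                f"trial {self.trial_id}: 'copulating' is absorbing and may only "
                "appear once, as the final state"
            )

    @property
    def copulated(self) -> bool:
        return self.states[-1] == COPULATING

    @property
    def n_timepoints(self) -> int:
        return len(self.states)

    def times(self) -> list[float]:
        return [i * self.interval_s for i in range(len(self.states))]


@dataclasses.dataclass
class CHCProfile:
    """Internal-standard-normalized cuticular hydrocarbon profile.

    ``amounts`` maps compound name to peak area divided by the hexacosane
    internal-standard area (dimensionless); the standard itself is excluded.
    """

    individual_id: str
    strain: str
    sex: str = "M"
    treatment: str = "virgin"
    amounts: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for compound, value in self.amounts.items():
            if value < 0:
                raise ValidationError(
                    f"individual {self.individual_id}: negative normalized "
                    f"abundance for {compound}"
                )


# ---------------------------------------------------------------------------
# event logs


_TRIAL_COLS = ("trial_id", "trial", "observation_id", "observation")
_TIME_COLS = ("time_s", "time", "t", "start_s")
_STATE_COLS = ("behavior", "behaviour", "state", "label")
_META_COLS = {
    "male_strain": ("male_strain", "male", "subject"),
    "female_strain": ("female_strain", "female"),
    "block_id": ("block_id", "block", "session"),
}


def _find_column(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise FormatError(
        f"event log is missing a {what} column (looked for one of: "
        f"{', '.join(candidates)})"
    )


def read_event_log(
    path,
    interval_s: float = DEFAULT_INTERVAL_S,
    dialect: str = "auto",
    max_span_s: float = DEFAULT_MAX_SPAN_S,
) -> list[EthogramTrial]:
    """Parse a delimited event log into fixed-grid :class:`EthogramTrial` s.

    Parameters
    ----------
    path
        CSV/TSV file (delimiter sniffed from the extension; ``.tsv`` → tab)
        or an already-loaded :class:`pandas.DataFrame`.
    interval_s
        Grid spacing in seconds (the scoring protocol used 10 s).
    dialect
        ``"gridded"`` — rows already sit on the grid (one row per scored
        timepoint); ``"events"`` — rows are state-onset events with arbitrary
        times; ``"auto"`` — per-trial detection: if every time is an exact
        multiple of ``interval_s`` the log is treated as gridded.

    The snapping rule for event dialects: the state at grid point *t* is the
    last recorded state with time ≤ *t*.  A state recorded *after* a grid
    point never snaps backwards onto it.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        p = Path(path)
        sep = "\t" if p.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(p, sep=sep)
    if dialect not in {"auto", "gridded", "events"}:
        raise ValueError(f"unknown dialect {dialect!r}")

    tcol = _find_column(df, _TRIAL_COLS, "trial id")
    timecol = _find_column(df, _TIME_COLS, "time")
    scol = _find_column(df, _STATE_COLS, "behavior label")
    meta_found = {}
    for field, cands in _META_COLS.items():
        lower = {c.lower(): c for c in df.columns}
        for cand in cands:
            if cand in lower:
                meta_found[field] = lower[cand]
                break

    bad_rows = []
    for idx, label in df[scol].items():
        try:
            canonical_state(label)
        except ValidationError:
            bad_rows.append((int(idx), label))
    if bad_rows:
        shown = ", ".join(f"row {i}: {lab!r}" for i, lab in bad_rows[:10])
        raise ValidationError(
            f"{len(bad_rows)} rows carry behavior labels outside the "
            f"eight-state catalogue ({shown})"
        )

    times = pd.to_numeric(df[timecol], errors="coerce")
    if times.isna().any():
        raise FormatError(f"non-numeric times in column {timecol!r}")
    if (times < 0).any():
        raise ValidationError("negative event times")
    df = df.assign(_t=times)

    trials: list[EthogramTrial] = []
    for trial_id, sub in df.groupby(tcol, sort=False):
        t = sub["_t"].to_numpy(dtype=float)
        if (t[1:] < t[:-1]).any():
            raise ValidationError(f"trial {trial_id}: times are not non-decreasing")
        labels = [canonical_state(s) for s in sub[scol]]
        if dialect == "gridded":
            on_grid = True
        elif dialect == "events":
            on_grid = False
        else:
            on_grid = all(abs(x / interval_s - round(x / interval_s)) < 1e-9 for x in t)
        if on_grid and len(set(t.tolist())) == len(t):
            states = labels
        else:
            states = _snap_to_grid(t, labels, interval_s)
        if COPULATING in states:
            cut = states.index(COPULATING)
            if any(s != COPULATING for s in states[cut + 1 :]):
                raise ValidationError(
                    f"trial {trial_id}: states recorded after 'copulating'"
                )
            states = states[: cut + 1]
        meta = {
            field: str(sub[col].iloc[0]) for field, col in meta_found.items()
        }
        trials.append(
            EthogramTrial(
                trial_id=str(trial_id),
                states=states,
                interval_s=interval_s,
                max_span_s=max_span_s,
                male_strain=meta.get("male_strain", ""),
                female_strain=meta.get("female_strain", ""),
                block_id=meta.get("block_id"),
            )
        )
    if not trials:
        raise ValidationError("event log contains no trials")
    return trials


def _snap_to_grid(t, labels: list[str], interval_s: float) -> list[str]:
    """State at grid point g = last recorded state with time ≤ g."""
    import math

    n_grid = int(math.floor(t[-1] / interval_s)) + 1
    states = []
    j = 0
    current = None
    for g in range(n_grid):
        gt = g * interval_s
        while j < len(t) and t[j] <= gt + 1e-9:
            current = labels[j]
            j += 1
        states.append(current if current is not None else SEPARATE)
    return states


def trials_to_events(trials: Iterable[EthogramTrial]) -> pd.DataFrame:
    """Inverse of :func:`read_event_log` for gridded logs (round-trip aid)."""
    rows = []
    for tr in trials:
        for i, s in enumerate(tr.states):
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "time_s": i * tr.interval_s,
                    "behavior": s,
                    "male_strain": tr.male_strain,
                    "female_strain": tr.female_strain,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CHC tables

INTERNAL_STANDARD = "n-C26"

#: Canonical trait names with case-insensitive synonyms (the literature mixes
#: positional shorthand like "7-C23" with systematic names like
#: "7-tricosene").
_COMPOUND_SYNONYMS: Mapping[str, str] = {}


def _build_synonyms() -> dict[str, str]:
    table = {
        "n-C26": ["n-c26", "c26", "nc26", "hexacosane"],
        "cVA": ["cva", "cis-vaccenyl acetate", "11-cis-vaccenyl acetate"],
        "7-C23": ["7-c23", "7-tricosene"],
        "7-C25": ["7-c25", "7-pentacosene"],
        "5-C25": ["5-c25", "5-pentacosene"],
        "9-C25": ["9-c25", "9-pentacosene"],
        "2-Me-C30": ["2-me-c30", "2-methyltriacontane", "2-methyl-triacontane"],
        "2-Me-C26": ["2-me-c26", "2-methylhexacosane", "2-methyl-hexacosane"],
        "n-C21": ["n-c21", "nc21", "heneicosane"],
        "n-C22": ["n-c22", "nc22", "docosane"],
        "n-C24": ["n-c24", "nc24", "tetracosane"],
    }
    out = {}
    for canon, names in table.items():
        out[canon.lower()] = canon
        for n in names:
            out[n.lower()] = canon
    return out


_COMPOUND_SYNONYMS = _build_synonyms()


def canonical_compound(name: str) -> str:
    """Map a compound name onto its canonical form; unknown names pass through."""
    return _COMPOUND_SYNONYMS.get(str(name).strip().lower(), str(name).strip())


def normalize_chc(
    peak_table,
    internal_standard: str = INTERNAL_STANDARD,
) -> list[CHCProfile]:
    """Normalize GC peak areas by the internal standard, per individual.

    ``peak_table`` is a long-format CSV path or DataFrame with columns
    ``individual, strain, sex, treatment, compound, area``.  Output amounts
    are ``area[compound] / area[internal standard]``; the standard itself is
    removed.  Every individual must carry a strictly positive
    internal-standard area.
    """
    if isinstance(peak_table, pd.DataFrame):
        df = peak_table.copy()
    else:
        p = Path(peak_table)
        sep = "\t" if p.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(p, sep=sep)
    lower = {c.lower(): c for c in df.columns}
    required = ["individual", "compound", "area"]
    missing = [c for c in required if c not in lower]
    if missing:
        raise FormatError(f"CHC peak table is missing columns: {', '.join(missing)}")
    std = canonical_compound(internal_standard)

    if (pd.to_numeric(df[lower["area"]], errors="coerce") < 0).any():
        raise ValidationError("negative peak areas in CHC table")

    profiles = []
    for ind, sub in df.groupby(lower["individual"], sort=False):
        amounts_raw: dict[str, float] = {}
        for _, row in sub.iterrows():
            amounts_raw[canonical_compound(row[lower["compound"]])] = float(
                row[lower["area"]]
            )
        std_area = amounts_raw.get(std, 0.0)
        if std_area <= 0:
            raise ValidationError(
                f"individual {ind}: internal standard {std} area is zero or absent"
            )
        amounts = {
            c: a / std_area for c, a in amounts_raw.items() if c != std
        }
        profiles.append(
            CHCProfile(
                individual_id=str(ind),
                strain=str(sub[lower["strain"]].iloc[0]) if "strain" in lower else "",
                sex=str(sub[lower["sex"]].iloc[0]) if "sex" in lower else "M",
                treatment=(
                    str(sub[lower["treatment"]].iloc[0])
                    if "treatment" in lower
                    else "virgin"
                ),
                amounts=amounts,
            )
        )
    if not profiles:
        raise ValidationError("CHC peak table contains no individuals")
    return profiles


def chc_profiles_to_frame(profiles: Iterable[CHCProfile]) -> pd.DataFrame:
    """Wide per-individual DataFrame (one column per compound)."""
    rows = []
    for p in profiles:
        row = {
            "individual": p.individual_id,
            "strain": p.strain,
            "sex": p.sex,
            "treatment": p.treatment,
        }
        row.update(p.amounts)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# result tables


def write_results(results: pd.DataFrame, path, format: str | None = None) -> Path:
    """Write a result table as TSV or JSON with round-trip precision.

    ``format`` defaults from the file extension.  Floats are written with
    shortest round-trip representation, so ``read_results`` reproduces the
    stored values exactly.
    """
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty result table")
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt not in {"tsv", "json"}:
        raise ValueError(f"unknown format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        results.to_csv(path, sep="\t", index=False)
    else:
        path.write_text(
            json.dumps(results.to_dict(orient="records"), indent=1, default=str)
        )
    return path


def read_results(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    return pd.DataFrame(json.loads(path.read_text()))
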