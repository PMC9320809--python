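"""The eight-state courtship ethogram.

State behaviours are scored on a fixed grid (10 s by default): at each grid
point the male is in exactly one of eight states.  ``copulating`` is
absorbing — once a pair copulates the trial ends, so no state may follow it.

The canonical ordering below is used for all transition matrices.
"""

from __future__ import annotations

from .errors import ValidationError

SEPARATE = "separate"
ENGAGING = "engaging"
SINGING = "singing"
SINGING2 = "singing2"
SCISSORING = "scissoring"
CIRCLING = "circling"
ATTEMPTED_COPULATION = "attempted_copulation"
COPULATING = "copulating"

#: Canonical state order; index positions define transition-matrix axes.
BEHAVIOR_STATES: tuple[str, ...] = (
    SEPARATE,
    ENGAGING,
    SINGING,
    SINGING2,
    SCISSORING,
    CIRCLING,
    ATTEMPTED_COPULATION,
    COPULATING,
)

#: Active (non-separate, non-copulating) courtship behaviours.
ACTIVE_STATES: tuple[str, ...] = BEHAVIOR_STATES[1:-1]

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(BEHAVIOR_STATES)}

_ALIASES = {
    "singing-2": SINGING2,
    "singing_2": SINGING2,
    "attempted-copulation": ATTEMPTED_COPULATION,
    "attempted copulation": ATTEMPTED_COPULATION,
    "copulation": COPULATING,
}


def canonical_state(label: str) -> str:
    """Return the canonical state label, or raise :class:`ValidationError`.

    Accepts minor formatting variants (hyphen/space in ``singing-2`` and
    ``attempted-copulation``); anything outside the eight-state catalogue is
    an error, never silently kept.
    """
    key = str(label).strip().lower()
    if key in STATE_INDEX:
        return key
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValidationError(
        f"unknown behavior label {label!r}; admissible states are "
        f"{', '.join(BEHAVIOR_STATES)}"
    )
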