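"""Behavioural repertoire of the study herd and its activity coding.

Fourteen mutually exclusive behaviour categories recorded by instantaneous
scan sampling, each coded into a dichotomous activity class: the three
lying-down (Resting) variants are ``Inactive``, everything else is
``Active``.  Canonical machine labels use hyphenated variants
(``Resting-vigilant``); the parser also accepts the parenthesised field
spellings (``Resting (vigilant)``) and is case-insensitive.
"""

from __future__ import annotations

import enum
import re
from typing import Mapping

__all__ = [
    "ActivityClass",
    "Behaviour",
    "UnknownBehaviourError",
    "parse_behaviour",
    "classify_dichotomous",
    "vocabulary",
    "ACTIVE_BEHAVIOURS",
    "INACTIVE_BEHAVIOURS",
]


class ActivityClass(enum.Enum):
    """Dichotomous activity descriptor: lying down vs everything else."""

    ACTIVE = "Active"
    INACTIVE = "Inactive"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Behaviour(enum.Enum):
    """One of the fourteen scan-sample behaviour categories."""

    DRINKING = "Drinking"
    GRAZING = "Grazing"
    INTERACTING = "Interacting"
    LICKING = "Licking"
    NURSING = "Nursing"
    RESTING = "Resting"
    RESTING_VIGILANT = "Resting-vigilant"
    RESTING_CHEWING = "Resting-chewing"
    RUNNING = "Running"
    SCRATCHING = "Scratching"
    STANDING_VIGILANT = "Standing-vigilant"
    STANDING_CHEWING = "Standing-chewing"
    SUCKLING = "Suckling"
    WALKING = "Walking"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: description and activity coding for every behaviour
_ETHOGRAM: Mapping[Behaviour, tuple[str, ActivityClass]] = {
    Behaviour.DRINKING: ("Consuming water or other liquids", ActivityClass.ACTIVE),
    Behaviour.GRAZING: (
        "Eating with the head to the ground, standing or walking",
        ActivityClass.ACTIVE,
    ),
    Behaviour.INTERACTING: (
        "Physical contact with one or more other individuals "
        "(grooming, fighting, intercourse)",
        ActivityClass.ACTIVE,
    ),
    Behaviour.LICKING: ("Licking its own body surface", ActivityClass.ACTIVE),
    Behaviour.NURSING: ("Feeding a calf from the teat", ActivityClass.ACTIVE),
    Behaviour.RESTING: ("Lying down with the head down", ActivityClass.INACTIVE),
    Behaviour.RESTING_VIGILANT: (
        "Lying down with the head raised off the ground",
        ActivityClass.INACTIVE,
    ),
    Behaviour.RESTING_CHEWING: (
        "Lying down with the head up, chewing",
        ActivityClass.INACTIVE,
    ),
    Behaviour.RUNNING: ("Moving at a fast pace", ActivityClass.ACTIVE),
    Behaviour.SCRATCHING: (
        "Scratching itself with a foot or the head",
        ActivityClass.ACTIVE,
    ),
    Behaviour.STANDING_VIGILANT: (
        "Standing still with the head up, alert",
        ActivityClass.ACTIVE,
    ),
    Behaviour.STANDING_CHEWING: (
        "Standing still with the head up, chewing",
        ActivityClass.ACTIVE,
    ),
    Behaviour.SUCKLING: ("Sucking on the teat of an adult", ActivityClass.ACTIVE),
    Behaviour.WALKING: ("Moving at a regular slow pace", ActivityClass.ACTIVE),
}

ACTIVE_BEHAVIOURS: frozenset[Behaviour] = frozenset(
    b for b, (_, c) in _ETHOGRAM.items() if c is ActivityClass.ACTIVE
)
INACTIVE_BEHAVIOURS: frozenset[Behaviour] = frozenset(
    b for b, (_, c) in _ETHOGRAM.items() if c is ActivityClass.INACTIVE
)

# normalised-label -> Behaviour lookup, built once
_CANONICAL: dict[str, Behaviour] = {}


def _normalise(label: str) -> str:
    # "Resting (vigilant)" / "resting_vigilant" / "Resting-Vigilant" -> "resting-vigilant"
    s = re.sub(r"[()\s_]+", "-", label.strip().lower())
    return re.sub(r"-+", "-", s).strip("-")


for _b in Behaviour:
    _CANONICAL[_normalise(_b.value)] = _b


class UnknownBehaviourError(ValueError):
    """Raised when a label does not match any ethogram category."""

    def __init__(self, label: str, session=None, scan=None):
        self.label = label
        self.session = session
        self.scan = scan
        where = ""
        if session is not None or scan is not None:
            where = f" (session={session!r}, scan={scan!r})"
        super().__init__(
            f"unknown behaviour label {label!r}{where}; expected one of: "
            + ", ".join(sorted(b.value for b in Behaviour))
        )


def parse_behaviour(label: str, *, session=None, scan=None) -> Behaviour:
    """Parse a behaviour label into its canonical :class:`Behaviour`.

    Matching is case-insensitive and tolerant of parenthesised variants, so
    ``"resting (chewing)"`` parses to ``Behaviour.RESTING_CHEWING``.

    Parameters
    ----------
    label : str
        The recorded behaviour label.
    session, scan : optional
        Context identifiers included in the error message when the label is
        not recognised; unknown labels are hard errors, never dropped,
        because synchrony counts are sensitive to missingness.
    """
    if not isinstance(label, str) or not label.strip():
        raise UnknownBehaviourError(str(label), session=session, scan=scan)
    try:
        return _CANONICAL[_normalise(label)]
    except KeyError:
        raise UnknownBehaviourError(label, session=session, scan=scan) from None


def classify_dichotomous(behaviour: Behaviour) -> ActivityClass:
    """Map a behaviour to its Active/Inactive class (total, deterministic)."""
    return _ETHOGRAM[behaviour][1]


def vocabulary():
    """The ethogram as a machine-readable table.

    Returns
    -------
    pandas.DataFrame
        Columns ``label`` (canonical machine label), ``description`` and
        ``coding`` (``Active``/``Inactive``), one row per behaviour.
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [b.value for b in Behaviour],
            "description": [_ETHOGRAM[b][0] for b in Behaviour],
            "coding": [_ETHOGRAM[b][1].value for b in Behaviour],
        }
    )
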