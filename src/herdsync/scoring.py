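"""Synchrony scoring of scan-sample records.

Each observation session pairs a focal animal with its three nearest
neighbours (re-ranked at every scan) and a freshly randomised control.  For
every session and comparison role this module counts the scans at which the
comparison animal matched the focal — either on the exact behaviour label
("strict") or on the Active/Inactive class ("dichotomous") — and derives the
pooled activity proportion ``a`` and the independence expectation
``a**2 + (1 - a)**2``, the probability that two independently behaving
individuals share an activity class.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .ethogram import (
    ActivityClass,
    Behaviour,
    classify_dichotomous,
    parse_behaviour,
)

__all__ = [
    "Role",
    "COMPARISON_ROLES",
    "ScanRecord",
    "SyncMatrix",
    "ValidationError",
    "records_to_frame",
    "validate_scan_frame",
    "score_sessions",
    "pooled_activity_proportion",
    "expected_independent_sync",
    "sync_proportions",
]


class Role(enum.Enum):
    """Who a record describes within one (session, scan) observation."""

    FOCAL = "focal"
    NEIGHBOUR1 = "neighbour1"
    NEIGHBOUR2 = "neighbour2"
    NEIGHBOUR3 = "neighbour3"
    CONTROL = "control"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: comparison roles in rank order; column order of every SyncMatrix
COMPARISON_ROLES: tuple[Role, ...] = (
    Role.NEIGHBOUR1,
    Role.NEIGHBOUR2,
    Role.NEIGHBOUR3,
    Role.CONTROL,
)

_ROLE_LOOKUP = {r.value: r for r in Role}


def parse_role(label: str) -> Role:
    """Parse a role label; accepts e.g. ``Neighbour-1``/``neighbour_1``."""
    if not isinstance(label, str):
        raise ValidationError(f"invalid role {label!r}")
    s = re.sub(r"[\s_-]+", "", label.strip().lower())
    try:
        return _ROLE_LOOKUP[s]
    except KeyError:
        raise ValidationError(
            f"unknown role {label!r}; expected one of "
            + ", ".join(r.value for r in Role)
        ) from None


@dataclasses.dataclass(frozen=True)
class ScanRecord:
    """One behaviour observation for one role at one scan."""

    session: str
    scan: int
    role: Role
    behaviour: Behaviour


class ValidationError(ValueError):
    """Raised when scan records violate the protocol structure."""


@dataclasses.dataclass
class SyncMatrix:
    """Sessions x comparison-roles table of within-session synchrony counts.

    Attributes
    ----------
    data : pandas.DataFrame
        Integer match counts, index = session ids, columns
        ``neighbour1, neighbour2, neighbour3, control``.
    mode : str
        ``"strict"`` (exact behaviour match) or ``"dichotomous"``
        (activity-class match).
    scans_per_session : int
        Number of scans per session; every count lies in
        ``[0, scans_per_session]``.
    """

    data: pd.DataFrame
    mode: str
    scans_per_session: int

    def __post_init__(self):
        expected = [r.value for r in COMPARISON_ROLES]
        if list(self.data.columns) != expected:
            raise ValidationError(
                f"SyncMatrix columns must be {expected}, got {list(self.data.columns)}"
            )
        if self.mode not in ("strict", "dichotomous"):
            raise ValidationError(f"mode must be strict|dichotomous, got {self.mode!r}")
        vals = self.data.to_numpy()
        if vals.size and ((vals < 0) | (vals > self.scans_per_session)).any():
            raise ValidationError(
                f"counts must lie in [0, {self.scans_per_session}]"
            )

    @property
    def n_sessions(self) -> int:
        return len(self.data)

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def proportions(self) -> pd.DataFrame:
        """Counts divided by scans per session (the plottable summary)."""
        return self.data / float(self.scans_per_session)

    def median_proportions(self) -> pd.Series:
        """Per-role median synchrony proportion across sessions."""
        return self.proportions().median(axis=0)

    def subset(self, rows: Sequence[int]) -> "SyncMatrix":
        """A new matrix containing the given session rows (by position)."""
        return SyncMatrix(
            data=self.data.iloc[list(rows)],
            mode=self.mode,
            scans_per_session=self.scans_per_session,
        )

    def to_csv(self, path) -> None:
        """Write the matrix with a metadata header comment line."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# herdsync sync-matrix mode={self.mode} "
                f"scans_per_session={self.scans_per_session}\n"
            )
            self.data.rename_axis("session").to_csv(fh)

    @classmethod
    def from_csv(cls, path, mode: str | None = None,
                 scans_per_session: int | None = None) -> "SyncMatrix":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                m = re.search(r"mode=(\w+)", first)
                s = re.search(r"scans_per_session=(\d+)", first)
                mode = mode or (m.group(1) if m else None)
                scans_per_session = scans_per_session or (
                    int(s.group(1)) if s else None
                )
            else:
                fh.seek(0)
            df = pd.read_csv(fh, index_col="session")
        if mode is None or scans_per_session is None:
            raise ValidationError(
                "mode and scans_per_session must be given or present in the header"
            )
        return cls(data=df.astype(int), mode=mode,
                   scans_per_session=int(scans_per_session))


def records_to_frame(records) -> pd.DataFrame:
    """Normalise ScanRecords / dicts / a DataFrame to a canonical frame.

    The result has columns ``session`` (str), ``scan`` (int), ``role``
    (canonical role string) and ``behaviour`` (canonical label string).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if isinstance(r, ScanRecord):
                rows.append(
                    (r.session, r.scan, r.role.value, r.behaviour.value)
                )
            else:
                rows.append((r["session"], r["scan"], r["role"], r["behaviour"]))
        df = pd.DataFrame(rows, columns=["session", "scan", "role", "behaviour"])
    missing = {"session", "scan", "role", "behaviour"} - set(df.columns)
    if missing:
        raise ValidationError(f"records are missing columns: {sorted(missing)}")
    df = df[["session", "scan", "role", "behaviour"]].copy()
    df["session"] = df["session"].astype(str)
    try:
        df["scan"] = df["scan"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer scan index: {exc}") from None
    df["role"] = [parse_role(x).value for x in df["role"]]
    df["behaviour"] = [
        parse_behaviour(b, session=s, scan=sc).value
        for b, s, sc in zip(df["behaviour"], df["session"], df["scan"])
    ]
    return df


def validate_scan_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check protocol structure: role completeness and consecutive scans.

    Within every (session, scan) each of the five roles must appear exactly
    once; scans within a session must be consecutive integers; all sessions
    must have the same number of scans.
    """
    if len(df) == 0:
        raise ValidationError("empty record set")
    dup = df.duplicated(subset=["session", "scan", "role"])
    if dup.any():
        s, sc, ro = df.loc[dup.idxmax(), ["session", "scan", "role"]]
        raise ValidationError(
            f"duplicate record for (session={s!r}, scan={sc}, role={ro!r})"
        )
    counts = df.groupby(["session", "scan"], sort=False)["role"].agg(list)
    all_roles = {r.value for r in Role}
    for (s, sc), roles in counts.items():
        missing = all_roles - set(roles)
        if missing:
            raise ValidationError(
                f"missing role(s) {sorted(missing)} at (session={s!r}, scan={sc})"
            )
    scans_by_session = df.groupby("session")["scan"].agg(["min", "max", "nunique"])
    n_scans = scans_by_session["nunique"].iloc[0]
    for s, row in scans_by_session.iterrows():
        if row["max"] - row["min"] + 1 != row["nunique"]:
            raise ValidationError(f"scans not consecutive in session {s!r}")
        if row["nunique"] != n_scans:
            raise ValidationError(
                f"session {s!r} has {row['nunique']} scans, expected {n_scans}"
            )
    return df


_ACTIVE_LABELS = frozenset(
    b.value for b in Behaviour if classify_dichotomous(b) is ActivityClass.ACTIVE
)


def _activity_codes(labels: pd.Series) -> np.ndarray:
    """1 where the canonical behaviour label is Active, else 0."""
    return labels.isin(_ACTIVE_LABELS).to_numpy(dtype=np.int8)


def score_sessions(records, mode: str = "strict") -> SyncMatrix:
    """Count, per session and comparison role, scans matching the focal.

    Parameters
    ----------
    records : DataFrame or iterable of ScanRecord
        Validated scan records (five roles per scan).
    mode : {"strict", "dichotomous"}
        ``strict`` requires exact behaviour-label equality with the focal at
        the same scan; ``dichotomous`` requires only equal Active/Inactive
        class.  A strict match implies a dichotomous match, so for the same
        data the dichotomous count is cell-wise >= the strict count.

    Returns
    -------
    SyncMatrix
    """
    if mode not in ("strict", "dichotomous"):
        raise ValidationError(f"mode must be strict|dichotomous, got {mode!r}")
    df = validate_scan_frame(records_to_frame(records))
    if mode == "strict":
        values = df["behaviour"]
    else:
        values = pd.Series(_activity_codes(df["behaviour"]), index=df.index)
    wide = (
        df.assign(value=values)
        .pivot(index=["session", "scan"], columns="role", values="value")
    )
    focal = wide[Role.FOCAL.value]
    matches = pd.DataFrame(
        {r.value: (wide[r.value] == focal).astype(int) for r in COMPARISON_ROLES}
    )
    counts = matches.groupby(level="session", sort=True).sum()
    counts.index.name = "session"
    scans_per_session = int(df.groupby("session")["scan"].nunique().iloc[0])
    return SyncMatrix(
        data=counts[[r.value for r in COMPARISON_ROLES]].astype(int),
        mode=mode,
        scans_per_session=scans_per_session,
    )


def pooled_activity_proportion(records) -> float:
    """Proportion of all records (all five roles pooled) that are Active.

    This is the activity proportion ``a`` that feeds the independence
    expectation; with the study protocol of 30 sessions x 15 scans x 5
    roles it pools 2250 observations.
    """
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValidationError("empty record set")
    return float(_activity_codes(df["behaviour"]).mean())


def expected_independent_sync(a: float) -> float:
    """Same-activity-class probability for two independent individuals.

    If each individual is active with probability ``a`` independently of the
    other, the pair is either active together or inactive together with
    probability ``a**2 + (1 - a)**2``.
    """
    a = float(a)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activity proportion must be in [0, 1], got {a}")
    return a * a + (1.0 - a) * (1.0 - a)


def sync_proportions(matrix: SyncMatrix) -> pd.DataFrame:
    """Per-session synchrony proportions (counts / scans per session)."""
    return matrix.proportions()
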