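"""Reading and writing scan-record CSV files.

The canonical on-disk schema is a UTF-8 CSV with header
``session,scan,role,behaviour`` and one row per role per scan.  Reading is
schema-validating: malformed rows are rejected with their line number, and
the protocol structure (five roles per scan, consecutive scans) is enforced
before any analysis runs.
"""

from __future__ import annotations

import pandas as pd

from .ethogram import UnknownBehaviourError, parse_behaviour
from .scoring import ValidationError, parse_role, validate_scan_frame

__all__ = ["read_scan_records", "write_scan_records"]

_REQUIRED = ["session", "scan", "role", "behaviour"]


def read_scan_records(path) -> pd.DataFrame:
    """Read and validate a scan-record CSV.

    Returns the canonical record frame (session, scan, role, behaviour with
    canonical labels).  Raises :class:`~herdsync.scoring.ValidationError`
    naming the offending line for malformed rows, unknown roles or
    behaviours, duplicate (session, scan, role) triples, or incomplete role
    sets.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; "
            f"header must contain {_REQUIRED}"
        )
    df = df[_REQUIRED].copy()
    # header is line 1, first data row line 2
    scans, roles, behaviours = [], [], []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            scans.append(int(row.scan))
        except ValueError:
            raise ValidationError(
                f"{path}:{idx}: non-integer scan index {row.scan!r}"
            ) from None
        try:
            roles.append(parse_role(row.role).value)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{idx}: {exc}") from None
        try:
            behaviours.append(
                parse_behaviour(row.behaviour, session=row.session,
                                scan=row.scan).value
            )
        except UnknownBehaviourError as exc:
            raise ValidationError(f"{path}:{idx}: {exc}") from None
    out = pd.DataFrame(
        {
            "session": df["session"].astype(str),
            "scan": scans,
            "role": roles,
            "behaviour": behaviours,
        }
    )
    return validate_scan_frame(out)


def write_scan_records(records, path) -> None:
    """Write a canonical record frame to CSV (header, UTF-8, no index)."""
    from .scoring import records_to_frame

    records_to_frame(records).to_csv(path, index=False)
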