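import numpy as np
import pandas as pd
import pytest

import herdsync as hs

ROLES = ["focal", "neighbour1", "neighbour2", "neighbour3", "control"]


def make_records(session_behaviours):
    """Build a canonical record frame from per-session role->labels lists.

    ``session_behaviours`` maps session id -> {role: [label per scan]}.
    """
    rows = []
    for session, by_role in session_behaviours.items():
        n_scans = len(next(iter(by_role.values())))
        for scan in range(n_scans):
            for role in ROLES:
                rows.append((session, scan, role, by_role[role][scan]))
    return pd.DataFrame(rows, columns=["session", "scan", "role", "behaviour"])


def random_records(rng, n_sessions=5, n_scans=6, p_active=0.5):
    """Independent random records: each observation i.i.d. over the ethogram."""
    labels = [b.value for b in hs.Behaviour]
    active = [b.value for b in hs.Behaviour
              if hs.classify_dichotomous(b) is hs.ActivityClass.ACTIVE]
    inactive = [b.value for b in hs.Behaviour
                if hs.classify_dichotomous(b) is hs.ActivityClass.INACTIVE]
    rows = []
    for s in range(n_sessions):
        for scan in range(n_scans):
            for role in ROLES:
                if rng.random() < p_active:
                    lab = active[rng.integers(len(active))]
                else:
                    lab = inactive[rng.integers(len(inactive))]
                rows.append((f"S{s}", scan, role, lab))
    return pd.DataFrame(rows, columns=["session", "scan", "role", "behaviour"])


@pytest.fixture(scope="session")
def strong_copy_records_full():
    """The full strong-coupling demonstration dataset (300 x 30)."""
    herd, dyn, schedule = hs.strong_copy_scenario()
    return hs.simulate_study(herd, dyn, schedule, seed=2024)


@pytest.fixture(scope="session")
def strong_copy_records_30():
    """A protocol-sized (30 x 15) strongly coupled simulated dataset."""
    herd, dyn, _ = hs.strong_copy_scenario()
    schedule = hs.ProtocolSchedule(n_sessions=30, scans_per_session=15)
    return hs.simulate_study(herd, dyn, schedule, seed=20240)


@pytest.fixture(scope="session")
def null_records():
    """A protocol-sized dataset with fully independent behaviour."""
    return hs.simulate_study(seed=4242)
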