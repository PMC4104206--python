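"""Shared fixtures: hand-built micro-villages and a small simulated study."""

import numpy as np
import pytest

from dyadrecip.io_model import FamilyRecord, PedigreeEntry, Village
from dyadrecip.synthetic_data import SimParams, simulate_study


def make_toy_village(n_families=4, study_days=6, members_per_family=1):
    """Unrelated founder families on a small grid; deterministic."""
    families, individuals = [], []
    for k in range(n_families):
        members = tuple(f"P{k}_{m}" for m in range(members_per_family))
        families.append(
            FamilyRecord(
                family_id=f"F{k}",
                member_ids=members,
                head_ages=(30.0 + k,),
                location=(-14.9 + 0.002 * k, -66.9 + 0.001 * k),
            )
        )
        for m in members:
            individuals.append(PedigreeEntry(m, None, None, family_id=f"F{k}"))
    return Village(families=families, individuals=individuals, study_days=study_days)


@pytest.fixture
def toy_village():
    return make_toy_village()


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study reused across tests (12 families, 8 weeks)."""
    params = SimParams(n_families=12, n_days=56, seed=42)
    return simulate_study(params), params


@pytest.fixture(scope="session")
def study_scale():
    """One full-scale simulated study (35 families, 112 days)."""
    params = SimParams(seed=7)
    return simulate_study(params), params


def random_small_panel(rng, n_families=3, n_days=8, p_o=0.6, p_h=0.4):
    """Random panel respecting h <= o, zero diagonal."""
    from dyadrecip.io_model import EventPanel

    o = (rng.random((n_families, n_families, n_days)) < p_o)
    h = (rng.random((n_families, n_families, n_days)) < p_h) & o
    idx = np.arange(n_families)
    o[idx, idx] = False
    h[idx, idx] = False
    go = (rng.random((n_families, n_families, n_days)) < 0.3) & o
    return EventPanel(
        family_ids=[f"F{k}" for k in range(n_families)],
        h=h.astype(np.uint8), o=o.astype(np.uint8), guest_only=go.astype(np.uint8),
    )
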