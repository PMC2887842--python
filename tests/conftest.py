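"""Shared fixtures: one desk-scale modelling session reused across the suite.

Field solves dominate the runtime, so the session (anatomy + solved-field
cache), the 8-configuration x 7-depth sweep and the 50-trial branch
Monte-Carlo are computed once per test run.
"""

import numpy as np
import pytest

import iesim


@pytest.fixture(scope="session")
def session() -> iesim.Session:
    return iesim.Session()


@pytest.fixture(scope="session")
def sweep_table(session) -> iesim.SweepTable:
    return iesim.run_sweep(session)


@pytest.fixture(scope="session")
def branch_mc(session, sweep_table) -> iesim.BranchTrialTable:
    # the sweep has already cached the 8 common fields at 2 cm
    return iesim.run_branch_mc(session, seed=1)


@pytest.fixture(scope="session")
def trunk_paths():
    return iesim.build_trunk_paths()


@pytest.fixture(scope="session")
def ring_field(session) -> iesim.PotentialField:
    return session.field("ring-1mm", 2.0)
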