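"""Shared fixtures.

The expensive artefacts — the tuned cardiogenic-shock patient, its
converged baseline beat, and the full 13-condition study report — are built
once per session and shared across test modules.
"""

from __future__ import annotations

import pytest

import cardioloop as cl


@pytest.fixture(scope="session")
def healthy_patient():
    return cl.make_healthy_patient()


@pytest.fixture(scope="session")
def cs_patient():
    return cl.make_cs_patient()


@pytest.fixture(scope="session")
def cs_beat(cs_patient):
    """Converged unassisted (pathological) beat of the CS patient."""
    return cl.run_to_steady_state(cs_patient)


@pytest.fixture(scope="session")
def study_report(cs_patient):
    """Full 13-condition study with beat series retained per condition."""
    return cl.run_full_matrix(cs_patient, keep_beats=True)
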