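"""Shared fixtures for the pgslit test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pgslit import (
    BackgroundModel,
    RunMatrixConfig,
    beam_target_model,
    default_kes_setup,
    default_mps_setup,
    expected_profile,
    run_comparison,
)


@pytest.fixture(scope="session")
def kes_setup():
    return default_kes_setup()


@pytest.fixture(scope="session")
def mps_setup():
    return default_mps_setup()


@pytest.fixture(scope="session")
def beam_160():
    return beam_target_model(160.0)


@pytest.fixture(scope="session")
def ref_kes_160_bragg():
    """High-statistics expected reference: 160 MeV, Bragg-peak aligned KES,
    full camera."""
    from pgslit.pipeline import build_setup

    setup = build_setup("kes", "bragg_peak", 160.0, n_rows=2)
    return expected_profile(
        setup, beam_target_model(160.0), bg=BackgroundModel(),
        alignment="bragg_peak", n_protons=1e11,
    )


@pytest.fixture(scope="session")
def report_full():
    """The shipped default full-camera comparison matrix (deterministic)."""
    return run_comparison(RunMatrixConfig())


@pytest.fixture(scope="session")
def report_half():
    from dataclasses import replace

    return run_comparison(replace(RunMatrixConfig(), camera_mode="half"))
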