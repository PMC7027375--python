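"""Shared fixtures: the synthetic fixture suite is built once per session."""

from __future__ import annotations

import warnings

import pytest

from pepgroove import (
    EnsembleSpec,
    GrooveSpec,
    build_ensemble,
    build_groove,
    fixture_suite,
    parse_structure,
)

SUITE_SEED = 7


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return fixture_suite(SUITE_SEED, out)


@pytest.fixture(scope="session")
def pgr_model(fixture_paths):
    """Groove-like complex: NC mode, A/B at 70:30, planted contacts."""
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        return parse_structure(fixture_paths["pgr_like"]).single()


@pytest.fixture(scope="session")
def cc_model(fixture_paths):
    return parse_structure(fixture_paths["cc_like"]).single()


@pytest.fixture(scope="session")
def stiff_ensemble(fixture_paths):
    return parse_structure(fixture_paths["stiff"])


@pytest.fixture(scope="session")
def floppy_ensemble(fixture_paths):
    return parse_structure(fixture_paths["floppy"])


@pytest.fixture(scope="session")
def regional_ensemble(fixture_paths):
    return parse_structure(fixture_paths["regional"])


@pytest.fixture(scope="session")
def base_groove():
    """Single-conformer NC groove used as an ensemble base."""
    phi_psi = [(-120.0, 130.0)] * 9
    phi_psi[5] = (-60.0, -45.0)
    return build_groove(GrooveSpec(phi_psi=phi_psi, seed=11))


@pytest.fixture(scope="session")
def halfsigma_ensemble(base_groove):
    """200 models with peptide jitter sd 0.5 Å (rigid frame)."""
    return build_ensemble(
        EnsembleSpec(base=base_groove, n_models=200, peptide_sigma=0.5, seed=12)
    )
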