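"""Shared fixtures: one full-scale default synthetic run reused across tests."""

from __future__ import annotations

import pytest

from reefmpa import counterfactual as cf
from reefmpa import effects as ef
from reefmpa import survey_processing as sp
from reefmpa import synthetic_data as sd

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_run():
    """Default-configuration end-to-end run (1000 sites, seed 1).

    Expensive (tens of seconds), so computed once per session and shared by
    the planted-effect recovery, counterfactual-quality and effects tests.
    """
    cfg = sd.GeneratorConfig(seed=DEFAULT_SEED)
    data = sd.generate_dataset(cfg)
    observed = sp.process_fish(data["fish"], data["species"])
    ratios, bench = cf.run_counterfactual(
        data["sites"], observed, cf.RFSettings(seed=DEFAULT_SEED)
    )
    summary = ef.summarize_by_protection(ratios)
    return {
        "config": cfg,
        "data": data,
        "observed": observed,
        "ratios": ratios,
        "bench": bench,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset for structural checks (fast)."""
    cfg = sd.GeneratorConfig(n_sites=120, n_species=15, seed=7)
    return sd.generate_dataset(cfg)
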