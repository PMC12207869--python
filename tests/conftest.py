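"""Shared fixtures: simulated studies at several noise settings, and the
20-replicate parameter-recovery suite (computed once per session)."""

from __future__ import annotations

import logging

import pytest

import heterotherm as ht

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def paper_cfg() -> ht.ScenarioConfig:
    return ht.paper_winter(1)


@pytest.fixture(scope="session")
def dataset(paper_cfg):
    return ht.simulate_dataset(paper_cfg)


@pytest.fixture(scope="session")
def loaded(dataset):
    return ht.from_dataset(dataset)


@pytest.fixture(scope="session")
def result(loaded):
    return ht.analyze(loaded)


@pytest.fixture(scope="session")
def clean_cfg(paper_cfg):
    """No measurement noise, no missingness: construction identities exact."""
    return paper_cfg.replace(
        measurement_noise_sd=0.0,
        daytime_missing_prob=0.0,
        nighttime_missing_prob=0.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_cfg):
    return ht.simulate_dataset(clean_cfg)


@pytest.fixture(scope="session")
def clean_result(clean_dataset):
    return ht.analyze(ht.from_dataset(clean_dataset))


@pytest.fixture(scope="session")
def recovery():
    """20-replicate recovery of the default winter scenario."""
    report, per_seed = ht.recovery_suite("paper-winter", n_seeds=20,
                                         master_seed=1)
    return report, per_seed


def recovered(report, quantity: str) -> float:
    row = report[report["quantity"] == quantity]
    return float(row["recovered_mean"].iloc[0])
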