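"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

import esipred as ep


@pytest.fixture(scope="session")
def small_world() -> ep.World:
    """A compact strong-signal world for fast unit tests."""
    cfg = ep.WorldConfig(
        n_e3=15,
        n_proteins=120,
        n_gsp=60,
        n_gsn=150,
        ppi_density=0.15,
        seed=42,
    )
    return ep.generate_world(cfg)


@pytest.fixture(scope="session")
def small_model(small_world: ep.World) -> ep.TrainedModel:
    return ep.train_model(small_world.gold, small_world.inputs(), seed=42)


@pytest.fixture()
def toy_gold() -> ep.GoldStandard:
    pos = frozenset({ep.ESIPair("E1", "S1"), ep.ESIPair("E2", "S2")})
    neg = frozenset({ep.ESIPair("E1", "S2"), ep.ESIPair("E2", "S1")})
    return ep.GoldStandard(pos, neg)


@pytest.fixture()
def toy_domains() -> ep.AnnotationMap:
    return ep.AnnotationMap(
        "domain",
        {
            "E1": frozenset({"A", "C"}),
            "E2": frozenset({"C"}),
            "S1": frozenset({"B", "D"}),
            "S2": frozenset({"D"}),
        },
    )
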