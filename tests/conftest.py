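"""Shared fixtures: one default synthetic bundle generated per session."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

import mirnetkit as mk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@dataclass
class Bundle:
    config: mk.FixtureConfig
    raw: "object"
    truth: mk.PlantedTruth
    differential: "object"
    sources: dict
    pairs: "object"
    net: mk.BipartiteNetwork
    sets: mk.GeneSetCollection


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    """Default study-condition fixture (seed 42) run through the pipeline."""
    config = mk.FixtureConfig()
    raw, truth = mk.generate_expression_fixture(config)
    differential = mk.screen(raw, mk.CELL_LINES)
    sources = mk.generate_interaction_db(config, truth)
    pairs = mk.unify_interactions(list(sources.values()))
    net = mk.build_network(pairs, differential)
    sets = mk.generate_genesets(config, truth)
    return Bundle(config, raw, truth, differential, sources, pairs, net, sets)


@pytest.fixture()
def canonical() -> mk.CanonicalEdgeList:
    return mk.canonical_pancreatic_edge_list()
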