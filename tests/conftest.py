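"""Shared fixtures: tiny hand-built networks and a small synthetic study."""

import numpy as np
import pandas as pd
import pytest

import drivernet as dn


@pytest.fixture
def toy_net() -> dn.NetworkSpace:
    """A -- B (ppi), C -> A (tf), B -> D (signalling), E -- B (ppi)."""
    return dn.NetworkSpace([
        dn.InteractionEdge("A", "B", False, "ppi"),
        dn.InteractionEdge("C", "A", True, "tf"),
        dn.InteractionEdge("B", "D", True, "signalling"),
        dn.InteractionEdge("E", "B", False, "ppi"),
    ])


def tiny_cohort(expr_rows: dict, cna_rows: dict, labels: dict,
                probe_map: dict | None = None, is_discrete: bool = True) -> dn.OmicsCohort:
    """Build a cohort from plain dicts (rows keyed by probe / gene id)."""
    samples = list(labels)
    expr = pd.DataFrame(expr_rows, index=samples).T.astype(float)
    cna = pd.DataFrame(cna_rows, index=samples).T.astype(float)
    pm = pd.Series(probe_map) if probe_map is not None else pd.Series(
        {p: p.split("_")[0] for p in expr.index})
    return dn.OmicsCohort(
        expression=expr,
        probe_map=pm,
        cna=dn.CNAMatrix(cna, is_discrete=is_discrete),
        labels=pd.Series(labels),
    )


@pytest.fixture(scope="session")
def small_study():
    """400-gene synthetic study with a planted module (shared across tests)."""
    net = dn.generate_network(400, 4, rng_seed=5)
    cfg = dn.GeneratorConfig(n_genes=400, rng_seed=5)
    cohort, truth = dn.generate_cohort(net, cfg)
    return net, cfg, cohort, truth


@pytest.fixture(scope="session")
def small_study_pair():
    """Two 400-gene cohorts sharing one planted truth."""
    net = dn.generate_network(400, 4, rng_seed=9)
    cfg = dn.GeneratorConfig(n_genes=400, rng_seed=9)
    a, b, truth = dn.generate_cohort_pair(net, cfg)
    return net, cfg, a, b, truth
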