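"""Shared fixtures: a small synthetic template/cohort used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from surfgcn.datasets import prepare_dataset
from surfgcn.graph_hierarchy import coarsen
from surfgcn.synthetic_data import SyntheticSpec, generate_cohort, generate_template


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    """Depth-1 hemispheres (42 vertices), depth-0 subcorticals (12), 10 subjects."""
    return SyntheticSpec(
        cortex_subdivisions=1,
        subcortical_subdivisions=0,
        n_subjects=10,
        effect_geodesic_radius=30.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_template(tiny_spec):
    return generate_template(tiny_spec)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, tiny_template):
    meshes, graph = tiny_template
    subjects, truth = generate_cohort(meshes, tiny_spec)
    return subjects, truth


@pytest.fixture(scope="session")
def tiny_hierarchy(tiny_template):
    _, graph = tiny_template
    return coarsen(graph, num_levels=2, seed=0)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_template, tiny_cohort, tiny_hierarchy):
    from surfgcn.training import quantile_normalize

    meshes, graph = tiny_template
    subjects, _ = tiny_cohort
    normed = quantile_normalize([s.raw_score for s in subjects])
    for s, v in zip(subjects, normed):
        s.normalized_score = float(v)
    return prepare_dataset(subjects, graph, "combined", tiny_hierarchy)


def random_adjacency(n: int, rng: np.random.Generator, p: float = 0.25):
    """Random symmetric unweighted adjacency (possibly disconnected)."""
    import scipy.sparse as sp

    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    return sp.csr_matrix(a)
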