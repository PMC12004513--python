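"""Shared fixtures: synthetic datasets and one trained classifier.

The expensive objects (a 2000-molecule planted-rule dataset, its
cluster-singleton split and a trained graph model) are session-scoped and
shared across test modules; training uses a reduced architecture so the
whole suite stays fast on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from pbtscreen import dmpnn, simgen, splitkit
from pbtscreen.featurize import mol_to_graph


@pytest.fixture(scope="session")
def planted():
    """2000 molecules with the default planted halogen/tricyclic/logP rule."""
    records, truth = simgen.generate_dataset(
        simgen.GeneratorConfig(n_molecules=2000, seed=42)
    )
    return records, truth


@pytest.fixture(scope="session")
def planted_graphs(planted):
    records, _ = planted
    return {r.id: mol_to_graph(r) for r in records}


@pytest.fixture(scope="session")
def singleton_split(planted):
    records, _ = planted
    return splitkit.split_cluster_singletons(records, cutoff=0.4)


@pytest.fixture(scope="session")
def trained_model(planted, planted_graphs, singleton_split):
    """Graph-only classifier trained on the planted rule; returns the model,
    its held-out test records and their predicted probabilities."""
    records, _ = planted
    cfg = dmpnn.ModelConfig(
        hidden_size=64, depth=2, epochs=15, ffn_hidden_size=64,
        use_global_descriptors=False, seed=42, max_lr=2e-3,
    )
    model = dmpnn.train(records, singleton_split, cfg, graphs=planted_graphs)
    by_id = {r.id: r for r in records}
    test_records = [by_id[i] for i in singleton_split.test_ids]
    probs = model.predict_proba(
        test_records, graphs=[planted_graphs[r.id] for r in test_records]
    )
    return {"model": model, "test_records": test_records, "probs": probs}


@pytest.fixture(scope="session")
def cluster_fixture():
    """3 scaffold families of 5 plus 4 designated singletons."""
    return simgen.plant_cluster_structure(
        simgen.ClusterPlantConfig(n_families=3, family_size=5, n_singletons=4, seed=0)
    )
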