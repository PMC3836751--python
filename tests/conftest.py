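"""Shared fixtures: a study-shaped synthetic dataset and its pipeline run.

The dataset and the full pipeline result are session-scoped because the
end-to-end run (clustering through bootstrapped species trees and
saturation reports) backs several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from seedcoal.pipeline import PipelineConfig, run_full_pipeline
from seedcoal.simulate import (MSCModel, make_fixture_dataset,
                               make_species_tree, simulate_msc_gene_trees)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    return make_fixture_dataset(str(out), seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(outgroup="out", n_bootstrap=100, master_seed=1,
                          critical_kwargs={"n_sim": 12})


@pytest.fixture(scope="session")
def pipeline_result(fixture_dataset, pipeline_config):
    return run_full_pipeline(fixture_dataset.out_dir, pipeline_config)


def random_gene_trees(n_trees: int, n_species: int, seed: int,
                      internal_len: float = 1.0, tip_len: float = 1.0):
    """MSC gene trees on a random species tree; used as generic random
    rooted trees in property tests."""
    sp = make_species_tree(n_species, "out", seed=seed,
                           internal_len=internal_len, tip_len=tip_len,
                           outgroup_stem=internal_len)
    return sp, simulate_msc_gene_trees(MSCModel(sp), n_trees, seed=seed + 1)


def random_paralog_tree(rng: np.random.Generator, max_tips: int = 8):
    """Random small rooted tree that may carry several tips per species."""
    n_species = int(rng.integers(2, 5))
    samples = int(rng.integers(1, 4))
    while n_species * samples > max_tips:
        samples -= 1
    sp = make_species_tree(n_species + 1, "out",
                           seed=int(rng.integers(0, 2**31)),
                           internal_len=1.0, tip_len=1.0, outgroup_stem=1.0)
    model = MSCModel(sp, samples_per_species=max(samples, 1))
    tree = simulate_msc_gene_trees(model, 1,
                                   seed=int(rng.integers(0, 2**31)))[0]
    return tree
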