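import numpy as np
import pytest

from graphimg.classifier import CNNConfig
from graphimg.embedding import SkipGramConfig, WalkConfig, node2vec
from graphimg.pipeline import PipelineConfig, run_pipeline
from graphimg.synthetic import default_cohort_spec, simulate_modular_graph, simulate_two_class_cohort


@pytest.fixture(scope="session")
def two_block_graph():
    """Planted 30-node, 2-block weighted graph (blocks 0-14 and 15-29)."""
    rng = np.random.default_rng(2024)
    return simulate_modular_graph(30, 2, w_in=0.9, w_out=0.1, jitter=0.05, rng=rng)


@pytest.fixture(scope="session")
def two_block_embedding(two_block_graph):
    return node2vec(
        two_block_graph,
        WalkConfig(iterations=10, walk_length=40, seed=11),
        SkipGramConfig(window=5, dim=8, epochs=5, seed=11),
    )


@pytest.fixture(scope="session")
def cohort_result(tmp_path_factory):
    """Full pipeline on a 40-subject, 40-channel synthetic two-class cohort.

    Session-scoped because the run (signals -> PLI -> embeddings ->
    images -> 4-fold CV) takes about a minute; several end-to-end tests
    share it.
    """
    out = tmp_path_factory.mktemp("cohort")
    spec = default_cohort_spec(n_channels=40, n_per_class=20, seed=7)
    recordings, labels, sids = simulate_two_class_cohort(spec, n_samples=3000)
    cfg = PipelineConfig(seed=7, cv_folds=4, cv_iterations=1)
    result = run_pipeline(cfg, labels, sids, out, recordings=recordings)
    return {"result": result, "out_dir": out, "labels": labels, "subject_ids": sids}


@pytest.fixture
def tiny_cnn_cfg():
    """Small-input CNN config for fast training tests (6x6x1 images)."""
    return CNNConfig(input_shape=(6, 6, 1), conv1_maps=4, conv2_maps=8,
                     fc1_units=8, fc2_units=4, max_epochs=60,
                     early_stop_patience=20, seed=5)
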