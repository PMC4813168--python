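import numpy as np
import pytest

from ppinpipe import (
    assemble_candidate_network,
    generate_identifiable_truth,
    generate_truth,
    simulate_expression,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """Generic closed-loop ground truth: 12 proteins, degree 2, decoys."""
    return generate_truth(12, 2, 1.0, seed=3)


@pytest.fixture(scope="session")
def layered_instance():
    """Layered identifiable truth with noiseless expression and candidates."""
    truth = generate_identifiable_truth(30, 2, 0.0, seed=11)
    expr = simulate_expression(truth, 100, seed=5)
    cand = assemble_candidate_network(truth.candidate_edges, truth.protein_ids)
    return truth, expr, cand
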