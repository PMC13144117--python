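import numpy as np
import pandas as pd
import pytest

from panselect import LabeledPangenome, SyntheticSpec, generate_pangenome


@pytest.fixture
def small_separable():
    """40 genomes, perfectly separating markers, no noise."""
    spec = SyntheticSpec(
        n_genomes_group_a=20,
        n_genomes_group_b=20,
        n_core=10,
        n_cloud=40,
        n_markers=5,
        p_marker_a=1.0,
        p_marker_b=0.0,
        flip_noise=0.0,
        seed=7,
    )
    return spec, generate_pangenome(spec)


@pytest.fixture
def tiny_labeled():
    """Hand-built 4x3 labeled matrix for contract tests."""
    matrix = pd.DataFrame(
        [[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 1]],
        index=["g1", "g2", "g3", "g4"],
        columns=["famA", "famB", "famC"],
    )
    labels = pd.Series(["x", "x", "y", "y"], index=matrix.index, name="group")
    return LabeledPangenome(matrix=matrix, labels=labels)


def shuffle_genomes(pangenome: LabeledPangenome, seed: int) -> LabeledPangenome:
    order = np.random.default_rng(seed).permutation(pangenome.genome_ids)
    return pangenome.subset_genomes(order)
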