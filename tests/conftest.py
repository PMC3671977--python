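import numpy as np
import pandas as pd
import pytest

from nscpipe.model import SpectralCountMatrix, StudyDesign


@pytest.fixture
def two_group_design():
    return StudyDesign.from_groups({"NN": 2, "NA": 2})


@pytest.fixture
def paper_design():
    from nscpipe.fixtures import paper_design

    return paper_design()


@pytest.fixture
def small_matrix(two_group_design):
    counts = pd.DataFrame(
        {"NN1": [3, 1], "NN2": [2, 2], "NA1": [0, 5], "NA2": [1, 3]},
        index=pd.Index(["A", "B"], name="accession"),
    )
    return SpectralCountMatrix(counts, two_group_design)


def random_design(rng: np.random.Generator, max_replicates: int = 6) -> StudyDesign:
    """Random 2-4 group design including the NN baseline, <= max replicates."""
    groups = ["NN"] + list(
        rng.choice(["NA", "ON", "OA"], size=rng.integers(1, 4), replace=False)
    )
    sizes = {}
    budget = max_replicates
    for i, g in enumerate(groups):
        remaining_groups = len(groups) - i - 1
        hi = budget - remaining_groups
        n = int(rng.integers(1, max(2, hi + 1)))
        sizes[g] = n
        budget -= n
    return StudyDesign.from_groups(sizes)


def random_matrix(
    rng: np.random.Generator,
    max_proteins: int = 8,
    max_replicates: int = 6,
    max_count: int = 20,
) -> SpectralCountMatrix:
    """Random small count matrix with zero-inflation; no all-zero replicate."""
    design = random_design(rng, max_replicates)
    n_prot = int(rng.integers(1, max_proteins + 1))
    reps = list(design.replicate_ids)
    while True:
        counts = rng.integers(0, max_count + 1, size=(n_prot, len(reps)))
        counts[rng.random(counts.shape) < 0.35] = 0
        if (counts.sum(axis=0) > 0).all():
            break
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"P{i}" for i in range(n_prot)], name="accession"),
        columns=reps,
    )
    return SpectralCountMatrix(df, design)
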