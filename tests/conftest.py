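import numpy as np
import pytest
from hypothesis import settings

from crossfeednet.classifiers import ClassifierSpec, cross_validate
from crossfeednet.folding import assemble_folds, cluster_pairs
from crossfeednet.metrics import panel_from_counts
from crossfeednet.synthetic import PRESETS, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small planted community: dataset, noisy records, truth, community."""
    return generate_dataset(PRESETS["tiny"])


@pytest.fixture(scope="session")
def tiny_dataset(tiny_bundle):
    return tiny_bundle[0]


@pytest.fixture(scope="session")
def paper_bundle():
    """Paper-scale planted community (P=3141, 260 organisms, 1326 pairs)."""
    return generate_dataset(PRESETS["paper_scale"])


@pytest.fixture(scope="session")
def paper_dataset(paper_bundle):
    return paper_bundle[0]


@pytest.fixture(scope="session")
def paper_knn_cv(paper_dataset):
    """KNN k=3 cross-validation on the paper-scale preset (pooled results)."""
    folds = assemble_folds(cluster_pairs(paper_dataset, 10, seed=7), paper_dataset, 4)
    predictions, counts = cross_validate(
        ClassifierSpec("knn", {"k": 3}), paper_dataset, folds
    )
    return predictions, counts, panel_from_counts(counts), folds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
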