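import numpy as np
import pandas as pd
import pytest

import aromascreen as a


@pytest.fixture(scope="session")
def compound_table():
    return a.load_compound_table(a.fixture_compound_path())


@pytest.fixture(scope="session")
def content_matrix():
    return a.load_content_matrix(a.fixture_content_path())


@pytest.fixture(scope="session")
def means(content_matrix):
    return a.cultivar_means(content_matrix)


@pytest.fixture(scope="session")
def oav(means, compound_table):
    return a.oav_matrix(means, compound_table)


@pytest.fixture(scope="session")
def flat_two_group_means(means):
    """Two pseudo-cultivars with identical base means (complete null)."""
    base = means.values["CV1"]
    absent = means.absent["CV1"]
    return a.CultivarMeans(
        values=pd.DataFrame({"A": base, "B": base}),
        absent=pd.DataFrame({"A": absent, "B": absent}),
    )


def two_cloud_data(rng, n_per=10, sep=50.0):
    """Two well-separated Gaussian point clouds plus true labels."""
    x0 = rng.normal(0.0, 1.0, size=(n_per, 3))
    x1 = rng.normal(sep, 1.0, size=(n_per, 3))
    return np.vstack([x0, x1]), np.r_[np.zeros(n_per, int), np.ones(n_per, int)]
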