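import numpy as np
import pandas as pd
import pytest

from morphodiverge.morphometrics import N_COORDS, N_LANDMARKS
from morphodiverge.synthetic import (
    SynthConfig,
    consensus_shape,
    gen_lines,
    gen_macro_shapes,
    gen_tree,
    structured_cov,
    table_from_shapes,
    tangent_basis,
)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Compact study design: quick to simulate, same structure as default."""
    return SynthConfig(seed=42, n_families=15, species_per_family=6,
                       n_lines=20, n_populations=4, inds_per_line=5)


@pytest.fixture(scope="session")
def small_phylogeny(small_config):
    phy = gen_tree(small_config)
    gen_macro_shapes(small_config, phy)
    return phy


@pytest.fixture(scope="session")
def line_configs(small_config):
    configs, effects = gen_lines(small_config)
    return configs, effects


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_psd(rng, p=N_COORDS, scale=1.0):
    """Random full-rank PSD matrix (independent of package code)."""
    A = rng.standard_normal((p, p + 5))
    return A @ A.T / (p + 5) * scale


def aligned_table(shapes, **meta):
    """Wrap shape vectors into an AlignedShapeTable with given metadata."""
    n = len(shapes)
    md = pd.DataFrame({k: (list(v) if not np.isscalar(v) else [v] * n)
                       for k, v in meta.items()})
    return table_from_shapes(np.asarray(shapes, float), md)
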