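import numpy as np
import pytest

import pollenkiller as pk

#: Seven-population ladder tree used throughout the introgression tests.
LADDER_TREE = (
    "(P1:1.0,(P2:0.8,(P3:0.6,(P4:0.45,(P5:0.3,(P6:0.15,P7:0.15):0.15)"
    ":0.15):0.15):0.2):0.2):0.0;"
)


@pytest.fixture(scope="session")
def ladder_tree():
    return pk.load_species_tree(LADDER_TREE)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Deterministic fixture set written by the synthetic-data module."""
    outdir = tmp_path_factory.mktemp("fixtures")
    pk.write_fixtures(outdir, seed=20240627, n_sites=120, n_null=50)
    return outdir


def invasion_theta0(f0: float) -> np.ndarray:
    return pk.genotype_frequencies_from_haplotype_homozygotes(
        {"Ab": f0, "aB": 1.0 - f0}
    )
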