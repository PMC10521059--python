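import warnings

import pytest

from amoebascan.synthetic_data import GeneratorParams, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One moderately sized synthetic bundle shared across test modules."""
    return generate_bundle(GeneratorParams(seed=101, n_scaffolds=30,
                                           n_genes=800))


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    """The shared bundle written to disk once."""
    d = tmp_path_factory.mktemp("bundle")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        default_bundle.write(d)
    return d
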