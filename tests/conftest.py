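import hypothesis
import pytest

import phosstoich as ps

hypothesis.settings.register_profile(
    "repro", derandomize=True, deadline=None, max_examples=100
)
hypothesis.settings.load_profile("repro")


@pytest.fixture(scope="session")
def builtin_pairs():
    pairs, flyability = ps.read_targets()
    return pairs, flyability


@pytest.fixture()
def noiseless_config():
    return ps.table2_like_config(noise_cv=0.0, n_replicates=3, seed=123)
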