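import pytest

from modmethyl import extract_all, write_store
from modmethyl.simulate import MethylProfile, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One default simulated dataset shared across the suite: 3v3 samples,
    one planted DMR window (mat 0.9 vs pat 0.3 on a 0.75 background)."""
    out = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(
        seed=1,
        profiles={
            "mat": MethylProfile(0.75, [(8000, 9500, 0.9)]),
            "pat": MethylProfile(0.75, [(8000, 9500, 0.3)]),
        },
    )
    res = simulate_dataset(cfg, out)
    return cfg, res


@pytest.fixture(scope="session")
def sim_store(sim_bundle, tmp_path_factory):
    _, res = sim_bundle
    path = tmp_path_factory.mktemp("store") / "methy.tsv.bgz"
    store = write_store(extract_all(res.bams), path)
    return store
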