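import pytest

from scsh import simulate as sim


@pytest.fixture(scope="session")
def bundle():
    """One shared synthetic corpus at default study conditions."""
    return sim.generate(sim.FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The shared corpus written to disk in every consumed dialect."""
    outdir = tmp_path_factory.mktemp("corpus")
    paths = sim.write_bundle(bundle, outdir)
    return paths
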