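import pytest

import beadmodes as bm

#: Canonical simulated-profile grid: beamline-like density over a
#: moderate-resolution q range (reciprocal Å).
QMAX = 0.25
NQ = 800


@pytest.fixture(scope="session")
def sphere30():
    """123-bead lattice sphere, R = 30 Å on a 10 Å grid."""
    return bm.make_shape(bm.ShapeSpec("sphere", {"radius": 30.0}, spacing=10.0))


@pytest.fixture(scope="session")
def rod():
    return bm.rod_fixture()


@pytest.fixture(scope="session")
def curved():
    return bm.curved_rod_fixture()


@pytest.fixture(scope="session")
def composite():
    return bm.rod_plus_lobe_fixture()


@pytest.fixture(scope="session")
def rod_results(rod):
    return bm.ElasticNetworkModel(rod).fit()


@pytest.fixture(scope="session")
def curved_results(curved):
    return bm.ElasticNetworkModel(curved).fit()


@pytest.fixture(scope="session")
def composite_results(composite):
    return bm.ElasticNetworkModel(composite).fit()


@pytest.fixture(scope="session")
def simulate():
    """Factory producing seeded noisy profiles on the canonical grid."""
    def _simulate(model, seed, noise=0.01, qmax=QMAX, nq=NQ):
        return bm.simulate_profile(model, qmax, nq, bm.NoiseSpec(noise, seed))
    return _simulate
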