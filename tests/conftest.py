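import pytest

from microgut import build_toy_models


@pytest.fixture(scope="session")
def toy_models():
    return build_toy_models(include_broken=True)


@pytest.fixture(scope="session")
def formulas(toy_models):
    out = {}
    for m in toy_models.values():
        out.update(m.formulas)
    return out


@pytest.fixture(scope="session")
def energies():
    from microgut.toys import GIBBS_ENERGIES
    return dict(GIBBS_ENERGIES)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from microgut.fixtures import generate
    return generate(seed=0, outdir=tmp_path_factory.mktemp("bundle"))
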