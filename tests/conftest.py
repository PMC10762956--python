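import pytest

import molprobe as mp


@pytest.fixture(scope="session")
def group_library():
    return mp.load_group_library()


@pytest.fixture(scope="session")
def fragment_library():
    return mp.load_fragment_library()


@pytest.fixture(scope="session")
def default_records():
    """300 molecules from the default generator conditions (all 11 cores,
    all 15 substituents, up to 3 substituents, 0.15 eV noise)."""
    config = mp.GeneratorConfig(n_molecules=300, seed=42)
    return mp.generate_dataset(config)


@pytest.fixture(scope="session")
def nitro_rule():
    """Noise-free rule in which the HOMO-like property depends only on the
    nitro count (-0.6 eV per nitro around a -5.5 eV intercept)."""
    return mp.PlantedRule(-5.5, {"nitro": -0.6}, 0.0)


#: Substituent pool for nitro-driven experiments: nitro listed twice to
#: raise its frequency, plus non-causal halogen and nitrile decorations.
NITRO_POOL = (
    mp.DEFAULT_SUBSTITUENTS["nitro"],
    mp.DEFAULT_SUBSTITUENTS["nitro"],
    "Cl",
    "F",
    "I",
    "C#N",
)


@pytest.fixture(scope="session")
def nitro_records(nitro_rule):
    """800 molecules whose property is a pure function of nitro count."""
    config = mp.GeneratorConfig(
        n_molecules=800, substituent_groups=NITRO_POOL, max_substituents=3, seed=11
    )
    return mp.generate_dataset(config, nitro_rule)


@pytest.fixture(scope="session")
def nitro_task(nitro_records):
    values = [r.properties["homo"] for r in nitro_records]
    return mp.compute_thresholds(values, 3, "homo")


class StubBackend:
    """Configurable test double satisfying the backend contract."""

    def __init__(self, mapping=None, default="0"):
        self.mapping = mapping or {}
        self.default = default
        self.metadata = {"name": "stub", "seed": 0, "hyperparameters": {}}

    def fit(self, pairs):
        return self

    def complete(self, prompt):
        return self.mapping.get(prompt, self.default)


@pytest.fixture
def stub_backend_factory():
    return StubBackend
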