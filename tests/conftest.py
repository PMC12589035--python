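import pytest
from hypothesis import settings

from icivig import scenarios, synthetic
from icivig.cases import DrugSynonyms, MeddraHierarchy

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hierarchy() -> MeddraHierarchy:
    return MeddraHierarchy.bundled()


@pytest.fixture(scope="session")
def synonyms() -> DrugSynonyms:
    return DrugSynonyms.bundled()


@pytest.fixture(scope="session")
def small_quarter(tmp_path_factory):
    """One generated quarter (8,000 cases, default contamination) plus
    its manifest and the case-level simulation truth."""
    out = tmp_path_factory.mktemp("quarter")
    config = scenarios.demo_config(n_cases=8000, seed=11)
    manifest = synthetic.generate_dataset(config, out)
    return {"dir": out, "manifest": manifest, "config": config,
            "sim": synthetic.simulate(config)}


def minimal_config(theta: float, n_cases: int, seed: int,
                   baseline: float = 0.01) -> synthetic.GeneratorConfig:
    """Two-drug, one-event population for replicated calibration studies."""
    return synthetic.GeneratorConfig(
        n_cases=n_cases,
        drug_catalog=(
            synthetic.DrugSpec("nivolumab", 0.3),
            synthetic.DrugSpec("aspirin", 0.7),
        ),
        event_catalog=(synthetic.EventSpec("Pneumonia", baseline, infection=True),),
        effect_matrix={("nivolumab", "Pneumonia"): theta} if theta != 1.0 else {},
        seed=seed,
    )
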