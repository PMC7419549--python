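import numpy as np
import pytest

from twindiag import Evidence, GeneratorConfig, generate_network, generate_vignette
from twindiag.fixtures import (
    confounded_network,
    single_link_network,
    symmetric_explainer_network,
)


@pytest.fixture
def single_link():
    return single_link_network()


@pytest.fixture
def symmetric_net():
    return symmetric_explainer_network()


@pytest.fixture
def confounder_net():
    return confounded_network("confounded")


def small_random_case(seed, max_layer=4, max_positive=3):
    """A random test-size network plus vignette evidence, or None when the
    draw lands outside the exhaustive-oracle contract (too many noise bits)."""
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(
        n_risk=int(rng.integers(1, max_layer + 1)),
        n_disease=int(rng.integers(2, max_layer + 1)),
        n_symptom=int(rng.integers(2, max_layer + 1)),
        risk_disease_density=0.5,
        disease_symptom_density=0.5,
        reveal_negative_symptom=0.3,
        seed=int(seed),
    )
    net = generate_network(cfg)
    vignette = generate_vignette(net, cfg, seed=0)
    ev = vignette.evidence
    pos = frozenset(sorted(ev.positive_symptoms)[:max_positive])
    return net, Evidence(ev.risk_evidence, pos, ev.negative_symptoms), vignette
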