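import pytest
from hypothesis import HealthCheck, settings

import graphpassage as gp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: Canonical seed for every stochastic test.
TEST_SEED = 0


@pytest.fixture(scope="session")
def star_clique_ensembles():
    """The four proposed-experiment arms, simulated once per session.

    Star with D=5 demes of size B=100, m_I=0.05, alpha=1/10 (m_O=0.5),
    st=0.01, started from one fully mutant deme (center, leaf, or
    uniformly chosen), plus the matched clique (m=0.11, same total
    inter-deme exchange); 10,000 replicates each.
    """
    star = gp.build_star(5, 0.05, 0.1, "receive_B")
    clique = gp.build_clique(5, 0.11)
    params = gp.PopulationParams(B=100, st=0.01)
    out = {}
    for name, g, placement in [
        ("center", star, "center"),
        ("leaf", star, "leaf"),
        ("any", star, "uniform"),
        ("clique", clique, "uniform"),
    ]:
        res = gp.run_ensemble(
            g, params, placement, 10_000, rng=TEST_SEED, record_fractions=False
        )
        out[name] = gp.summarize(res)
    return out
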