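import pytest

from hybridcrd import GameParams, HybridConfig, ModelSpec, PopulationParams

PAPER_DEFAULTS = dict(Z=100, mu=0.01, beta=2.0, b=1.0, c=0.1, N=6, M=3)


def build_spec(*, N=6, M=3, r=0.5, b=1.0, c=0.1, a=0, p=0.0, Z=100, mu=0.01, beta=2.0):
    return ModelSpec(
        game=GameParams(N=N, M=M, r=r, b=b, c=c),
        hybrid=HybridConfig(a=a, p=p),
        pop=PopulationParams(Z=Z, mu=mu, beta=beta),
    )


@pytest.fixture
def paper_spec():
    """Default scenario of the study: N=6, M=3, a=2 hybrid team, Z=100."""
    return build_spec(r=0.7, a=2, p=0.5)


@pytest.fixture
def toy_spec():
    """Small population where exhaustive enumeration is feasible."""
    return build_spec(Z=10, r=0.7, a=2, p=0.5)
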