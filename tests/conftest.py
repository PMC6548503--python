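import numpy as np
import pytest

from crossfeed import CommunityParams, MoserParams, StrainParams


@pytest.fixture
def symmetric_params() -> CommunityParams:
    """Fully symmetric, loss-free community: g_comm = sqrt(r^2/u^2) = r/u."""
    law = MoserParams(gmax=0.45, K=1e6, n=2.0)
    strain = StrainParams(r=2.0, u=10.0, d=0.0, c=0.0, birth_law=law)
    return CommunityParams(lh=strain, hl=strain)


@pytest.fixture
def generic_params() -> CommunityParams:
    """Asymmetric community with nonzero death and overproduction costs."""
    return CommunityParams(
        lh=StrainParams(r=0.4, u=2.0, d=0.01, c=0.02,
                        birth_law=MoserParams(0.50, 1e6, 2.0)),
        hl=StrainParams(r=1.0, u=5.0, d=0.015, c=0.01,
                        birth_law=MoserParams(0.50, 2e6, 1.0)),
    )


def random_community(rng: np.random.Generator) -> CommunityParams:
    """Random valid parameter set whose steady state is reachable (each
    strain's gmax exceeds the required steady-state birth rate)."""
    rh, rl = rng.uniform(0.2, 1.5, 2)
    ul, uh = rng.uniform(1.0, 8.0, 2)
    d_lh, c_lh, d_hl, c_hl = rng.uniform(0.0, 0.015, 4)
    g = -(d_hl + c_hl + d_lh + c_lh) / 2 + np.sqrt(
        rh * rl / (ul * uh) + (d_hl + c_hl - d_lh - c_lh) ** 2 / 4
    )
    margins = rng.uniform(0.1, 0.3, 2)
    return CommunityParams(
        lh=StrainParams(
            r=rh, u=ul, d=d_lh, c=c_lh,
            birth_law=MoserParams(g + d_lh + c_lh + margins[0],
                                  rng.uniform(1e5, 5e6), rng.uniform(1.0, 3.0)),
        ),
        hl=StrainParams(
            r=rl, u=uh, d=d_hl, c=c_hl,
            birth_law=MoserParams(g + d_hl + c_hl + margins[1],
                                  rng.uniform(1e5, 5e6), rng.uniform(1.0, 3.0)),
        ),
    )
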