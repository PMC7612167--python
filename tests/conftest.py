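import pytest

from scblock import BlockDesign, DesignContext

#: printed block-design realisations used across tests:
#: (r, N, B, theta_f, theta_e, p0, p1, ESS00, ESS01)
PUBLISHED_BLOCK_DESIGNS = [
    (5, 116, 1, 0.1348, 0.9831, 0.3, 0.5, 47.3, 47.2),
    (5, 112, 4, 0.3005, 0.9700, 0.3, 0.5, 49.2, 49.3),
    (6, 112, 1, 0.1072, 0.9740, 0.3, 0.5, 47.9, 45.4),
    (4, 80, 1, 0.0428, 0.9842, 0.3, 0.5, 57.3, 52.7),
    (4, 80, 4, 0.0609, 0.9752, 0.3, 0.5, 62.2, 57.1),
    (6, 198, 1, 0.1108, 0.9928, 0.7, 0.85, 61.1, 79.4),
    (4, 176, 4, 0.3391, 0.9965, 0.7, 0.85, 64.4, 87.7),
    (6, 184, 4, 0.2730, 0.9866, 0.7, 0.85, 66.4, 83.5),
    (5, 124, 1, 0.0064, 0.9960, 0.7, 0.85, 96.4, 95.9),
    (5, 128, 4, 0.1304, 0.9887, 0.7, 0.85, 80.1, 91.7),
]


def make_block_design(r, n_total, block, theta_f, theta_e, p0, p1,
                      alpha=0.15, beta=0.2) -> BlockDesign:
    return BlockDesign(
        r=r, n_total=n_total, block=block, theta_f=theta_f, theta_e=theta_e,
        context=DesignContext(p0=p0, p1=p1, alpha=alpha, beta=beta),
    )


@pytest.fixture
def ctx35() -> DesignContext:
    return DesignContext(p0=0.3, p1=0.5, alpha=0.15, beta=0.2)


@pytest.fixture
def tiny_design(ctx35) -> BlockDesign:
    """N=8, B=1: small enough for exhaustive path enumeration."""
    return BlockDesign(r=1, n_total=8, block=1, theta_f=0.0, theta_e=1.0,
                       context=ctx35)


@pytest.fixture
def tiny_sc_design(ctx35) -> BlockDesign:
    return BlockDesign(r=1, n_total=8, block=1, theta_f=0.3, theta_e=0.9,
                       context=ctx35)


@pytest.fixture
def table2_p0_optimal() -> BlockDesign:
    """Block-size-two p0-optimal realisation at (0.15, 0.20, 0.30, 0.50)."""
    return make_block_design(5, 116, 1, 0.1348, 0.9831, 0.3, 0.5)
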