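import numpy as np
import pytest

from btspcam import network, patterns, plasticity


@pytest.fixture(scope="session")
def small_scale():
    """A small but statistically meaningful network scale shared by tests."""
    return dict(m=800, n=1200, f_p=0.05, f_q=0.02, f_w=0.6)


@pytest.fixture(scope="session")
def learned_small(small_scale):
    """One learned network at the small scale with its full provenance."""
    p = small_scale
    M = 300
    ens = patterns.gen_random_patterns(M, p["m"], p["f_p"], seed=11)
    plats = plasticity.draw_plateaus(M, p["n"], p["f_q"], seed=12)
    mask = network.build_connectivity(p["m"], p["n"], p["f_w"], seed=13)
    res = plasticity.learn_sequence(ens, plats, mask, seed=14, v_th=8)
    return ens, plats, mask, res


def se_of_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(x.size))
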