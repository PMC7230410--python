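import numpy as np
import pytest

from glycofit.model import ModelParameters, evaluate


def random_params(rng, n, nu_range=(-1.5, 1.5)):
    """Random valid parameter draws spanning both damping regimes."""
    out = []
    for _ in range(n):
        alpha = float(np.exp(rng.uniform(np.log(0.005), np.log(0.3))))
        ratio = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
        out.append(
            ModelParameters(
                alpha=alpha,
                omega0_sq=ratio * alpha**2,
                g_stab=float(rng.uniform(4.0, 8.0)),
                mu=float(rng.uniform(4.0, 8.0)),
                nu=float(rng.uniform(*nu_range)),
            )
        )
    return out


def protocol_params(rng, n, nu_range=(0.2, 1.2)):
    """Draws representative of tolerance-test curves: the excursion both
    develops after the first sample and relaxes within the 240-min window,
    so all five parameters are identifiable from the protocol grid."""
    out = []
    while len(out) < n:
        alpha = float(np.exp(rng.uniform(np.log(0.02), np.log(0.12))))
        ratio = float(np.exp(rng.uniform(np.log(0.5), np.log(2.5))))
        w2 = ratio * alpha**2
        disc = alpha**2 - w2
        slow = -alpha + np.sqrt(disc) if disc > 0 else -alpha
        if abs(slow) * 240.0 < 4.0:  # not settled by window end
            continue
        p = ModelParameters(
            alpha=alpha,
            omega0_sq=w2,
            g_stab=float(rng.uniform(4.5, 7.0)),
            mu=float(rng.uniform(4.5, 7.0)),
            nu=float(rng.uniform(*nu_range)),
        )
        curve = np.asarray(evaluate(p, np.linspace(0.0, 240.0, 241)))
        if curve.min() < 1.5 or curve.max() > 30.0:  # unphysiologic excursion
            continue
        out.append(p)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
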