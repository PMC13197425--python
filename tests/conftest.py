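import numpy as np
import pytest

from tidechron import calcurve as cc
from tidechron import diet
from tidechron import synthetic as syn


@pytest.fixture(scope="session")
def shcal20() -> cc.CalibrationCurve:
    return cc.load_bundled_curve("shcal20")


@pytest.fixture(scope="session")
def marine20() -> cc.CalibrationCurve:
    return cc.load_bundled_curve("marine20")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def default_source_categories(rng: np.random.Generator, n: int = 12):
    """Raw source samples drawn from the default coastal configuration."""
    cfg = syn.DEFAULT_SOURCE_CONFIG
    cats = []
    for name in diet.SOURCE_ORDER:
        m13, m15, s13, s15 = cfg[name]
        cats.append(
            diet.SourceCategory(
                name,
                [
                    diet.IsotopeSample(
                        f"{name}_{i}",
                        rng.normal(m13, s13),
                        rng.normal(m15, s15),
                        cn_ratio=3.2,
                        pctC=40.0,
                        pctN=14.0,
                    )
                    for i in range(n)
                ],
            )
        )
    return cats


def consumers_from_truth(
    rng: np.random.Generator, p_true: np.ndarray, n: int
) -> list[diet.IsotopeSample]:
    """Consumers drawn from the process-error mixing likelihood."""
    cfg = syn.DEFAULT_SOURCE_CONFIG
    tef = diet.TrophicEnrichment()
    mu = np.array([[cfg[k][0], cfg[k][1]] for k in diet.SOURCE_ORDER])
    var = np.array([[cfg[k][2] ** 2, cfg[k][3] ** 2] for k in diet.SOURCE_ORDER])
    lam, tau2 = tef.mean_matrix(), tef.sd_matrix() ** 2
    mean = p_true @ (mu + lam)
    sd = np.sqrt((p_true**2) @ (var + tau2))
    return [
        diet.IsotopeSample(f"H{i}", *(rng.normal(mean, sd))) for i in range(n)
    ]
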