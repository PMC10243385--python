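import numpy as np
import pytest

import asmod


@pytest.fixture(scope="session")
def design24():
    return asmod.load_design24()


@pytest.fixture(scope="session")
def size_results(design24):
    """Saturated polymer-by-speed tensor submodel fitted to particle size."""
    model = asmod.NeurofuzzyModel.from_dataset(
        design24, "size_um", [(("plga_pct", "speed_rpm"), (3, 3))]
    )
    return model.fit()


@pytest.fixture(scope="session")
def dl_results(design24):
    """Bilinear drug-by-polymer submodel fitted to zero-filled drug loading."""
    model = asmod.NeurofuzzyModel.from_dataset(
        design24,
        "dl_pct",
        [(("drug_pct", "plga_pct"), (2, 2))],
        missing_policy="zero_fill",
    )
    return model.fit()


@pytest.fixture(scope="session")
def uniformity_results(design24):
    """Four-submodel additive fit of the size-distribution uniformity."""
    structure = [
        (("drug_pct", "speed_rpm"), (2, 3)),
        (("pva_pct",), (2,)),
        (("time_s", "ow_ratio"), (3, 2)),
        (("dilution_ratio",), (2,)),
    ]
    return asmod.NeurofuzzyModel.from_dataset(design24, "uniformity", structure).fit()


@pytest.fixture(scope="session")
def ee_results(design24):
    """Two-submodel additive fit of encapsulation efficiency (n=16)."""
    structure = [
        (("plga_pct", "ow_ratio"), (2, 3)),
        (("drug_pct", "time_s"), (2, 3)),
    ]
    return asmod.NeurofuzzyModel.from_dataset(design24, "ee_pct", structure).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
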