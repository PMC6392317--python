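import numpy as np
import pandas as pd
import pytest

import hmrisk as h


@pytest.fixture(scope="session")
def profile():
    return h.ExposureProfile()


@pytest.fixture(scope="session")
def reference():
    return h.builtin_reference()


@pytest.fixture(scope="session")
def fixture_bundle():
    return h.study_fixture()


@pytest.fixture
def small_panel():
    """3 brands × 3 metals + ethanol, no censoring."""
    brands = ["AAA", "BBB", "CCC"]
    levels = pd.DataFrame(
        {"As": [1.0, 2.0, 0.5], "Cu": [100.0, 5.0, 2.0],
         "Pb": [0.2, 0.1, 0.3], "ethanol": [40.0, 40.0, 20.0]},
        index=brands)
    cens = pd.DataFrame(False, index=brands, columns=levels.columns)
    mdl = pd.Series({"As": 0.1, "Cu": 0.05, "Pb": 0.05, "ethanol": np.nan})
    return h.ConcentrationPanel(levels=levels, censored=cens, mdl=mdl)


@pytest.fixture
def synthetic_panel():
    panel, truth = h.generate_panel(h.GeneratorConfig(seed=42))
    return panel, truth


def write_panel_file(tmp_path, text, name="panel.csv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p
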