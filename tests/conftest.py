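import numpy as np
import pandas as pd
import pytest

from monotrace import GeneratorConfig, make_geometry


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Scaled-down study conditions for fast end-to-end tests."""
    groups = ("PV", "SST", "VIP")
    return GeneratorConfig(
        n_animals_per_group={g: 2 for g in groups},
        starter_count_mean={g: 40.0 for g in groups},
        starter_count_sd={g: 5.0 for g in groups},
        inputs_per_starter={g: 6.0 for g in groups},
    )


@pytest.fixture(scope="session")
def default_geometry(small_config):
    return make_geometry(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_cell_table(x, depth=None, ap=None, animal_id="A", group="PV",
                    channel_class="input", layer="L4") -> pd.DataFrame:
    """Minimal cell table for statistics tests."""
    x = np.asarray(x, dtype=float)
    depth = np.zeros_like(x) if depth is None else np.asarray(depth, float)
    ap = np.zeros_like(x) if ap is None else np.asarray(ap, float)
    return pd.DataFrame({
        "animal_id": animal_id, "group": group,
        "slice_index": (ap // 50).astype(int),
        "x_um": x, "y_um": depth, "depth_um": depth, "ap_um": ap,
        "channel_class": channel_class, "layer": layer,
        "region": "A1", "hemisphere": "ipsi",
    })
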