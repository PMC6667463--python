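import numpy as np
import pandas as pd
import pytest

from mdmtv.qmaps_io import LabelVolume, QuantitativeMap
from mdmtv.relaxivity import BinningConfig
from mdmtv.synth import BrainSpec, RegionSpec, simulate_brain


def make_region_spec(name="reg", label=1, n_voxels=2000, noiseless=True, **kwargs):
    noise = {"R1": 0.0, "MTsat": 0.0} if noiseless else {"R1": 0.03, "MTsat": 0.08}
    defaults = dict(
        name=name,
        label=label,
        n_voxels=n_voxels,
        mtv_mean=0.22,
        mtv_sd=0.07,
        laws={"R1": (2.0, 0.5), "MTsat": (12.0, -0.1)},
        noise_sd=noise,
    )
    defaults.update(kwargs)
    return RegionSpec(**defaults)


@pytest.fixture
def noiseless_brain():
    """Two regions on exact lines with distinct planted slopes."""
    spec = BrainSpec(
        regions=(
            make_region_spec("alpha", 1, laws={"R1": (1.2, 0.4), "MTsat": (3.0, 0.0)}),
            make_region_spec("beta", 2, laws={"R1": (2.4, 0.2), "MTsat": (9.0, -0.3)}),
        )
    )
    return simulate_brain(spec, seed=7)


@pytest.fixture
def cube_labels():
    """A 5x5x5 solid-cube region inside a 9x9x9 volume."""
    labels = np.zeros((9, 9, 9), dtype=int)
    labels[2:7, 2:7, 2:7] = 1
    table = pd.DataFrame(
        [{"label": 1, "name": "cube", "hemisphere": "none", "tissue_class": "GM"}]
    )
    return LabelVolume(labels=labels, region_table=table)


@pytest.fixture
def default_binning():
    return BinningConfig()


def make_map(values, param="R1"):
    return QuantitativeMap(values=np.asarray(values, dtype=float), param=param)
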