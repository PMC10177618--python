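import numpy as np
import pytest

from psmflow import AxisFrame, CellRecord, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture
def frame():
    return AxisFrame.default()


def make_cell(
    cid=1,
    centroid=(0.0, 0.0, 0.0),
    axes=(10.0, 8.0, 5.0),
    direction=(1.0, 0.0, 0.0),
    region="PZ",
    origin="left_half",
    stage=22,
    filopodia=(),
    sox2=False,
    volume=None,
):
    axes = np.asarray(axes, dtype=float)
    if volume is None:
        volume = 4.0 / 3.0 * np.pi * axes.prod()
    return CellRecord(
        id=cid,
        centroid=np.asarray(centroid, dtype=float),
        axes_um=axes,
        direction=np.asarray(direction, dtype=float),
        volume_um3=float(volume),
        sox2=sox2,
        origin=origin,
        region=region,
        stage=stage,
        filopodia_um=list(filopodia),
    )


@pytest.fixture
def cell_factory():
    return make_cell
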