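import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from assemblink.io import read_ph_series_csv
from assemblink.svel import CellGeometry
from assemblink.synthgen import btp_buffer


@pytest.fixture(scope="session")
def buffer_btp():
    """Working buffer: 25 % glycerol, 50 mM NaCl, 25 degC, pH 8."""
    return btp_buffer()


@pytest.fixture(scope="session")
def table1_series():
    """The pH vs tetramerization-constant table at 50 mM NaCl."""
    from importlib import resources

    path = resources.files("assemblink") / "fixtures" / "paper" / "table1_50mM.csv"
    return read_ph_series_csv(str(path))


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced radial grid for fast velocity simulations in tests."""
    return CellGeometry(meniscus=6.14, bottom=7.2, rotor_speed=42000.0, n_radial=150)


@pytest.fixture(scope="session")
def scan_times():
    """15 scans over two hours."""
    return np.arange(1, 16) * 480.0
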