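import numpy as np
import pytest

from secmp import simulate as sim
from secmp.config import PeakWindowConfig, RunConfig
from secmp.uv_quant import DEFAULT_EXTINCTION, AcquisitionGeometry, ssdna_mass

MONOMER_WINDOW = (7.85, 9.35)
DRIFT_SLOPE = 0.05
GRID_START = 4.0


def drift_at(v: float) -> float:
    return DRIFT_SLOPE * (v - GRID_START)


def anchors_on_drift(window=MONOMER_WINDOW):
    lo, hi = window
    pair = ((lo, drift_at(lo)), (hi, drift_at(hi)))
    return {"a280": pair, "a260": pair}


@pytest.fixture
def geometry():
    return AcquisitionGeometry()


@pytest.fixture
def extinction():
    return DEFAULT_EXTINCTION


@pytest.fixture
def het_mix():
    """Default heterogeneous mix: 10% full, partials, aggregate, contaminants."""
    return sim.demo_mix_heterogeneous()


@pytest.fixture
def full_mix():
    """High-purity fully packaged preparation with typical impurities."""
    return sim.demo_mix_single_full()


@pytest.fixture
def het_run_config():
    """RunConfig matched to the default heterogeneous mix."""
    m_full = sim.EMPTY_CAPSID_KDA + ssdna_mass(4787) / 1000.0
    return RunConfig(
        peak_window=PeakWindowConfig(v_start_ml=MONOMER_WINDOW[0], v_end_ml=MONOMER_WINDOW[1]),
        baseline=anchors_on_drift(),
        mp={"full_mass_kda": m_full},
        genome={"n_nt": 4787},
    )


@pytest.fixture
def full_run_config():
    """RunConfig matched to the fully packaged demo mix (2763 nt genome)."""
    m_full = sim.EMPTY_CAPSID_KDA + ssdna_mass(2763) / 1000.0
    return RunConfig(
        peak_window=PeakWindowConfig(v_start_ml=MONOMER_WINDOW[0], v_end_ml=MONOMER_WINDOW[1]),
        baseline=anchors_on_drift(),
        mp={"full_mass_kda": m_full},
        genome={"n_nt": 2763},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230913)
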