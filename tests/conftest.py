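import dataclasses

import numpy as np
import pytest

import hypermet as hm


@pytest.fixture
def acq_8deg_1s():
    return hm.AcquisitionParams(flip_angle_deg=8.0, repetition_time_s=1.0, n_scans=120)


@pytest.fixture
def acq_15deg_1s():
    return hm.AcquisitionParams(flip_angle_deg=15.0, repetition_time_s=1.0, n_scans=120)


@pytest.fixture
def day7_series():
    """Noiseless day-7-like dynamic series with embedded truth."""
    sc = hm.get_preset("day7")
    return hm.generate_dynamic(dataclasses.replace(sc, noise_sd_frac=0.0))


@pytest.fixture
def expansion_panel():
    return hm.generate_expansion(hm.get_preset("expansion_default"))


def normalized_pair(series):
    """Scale a series so the substrate peak is 1 (common scale for both traces)."""
    peak = np.max(series.substrate_signal)
    return series.substrate_signal / peak, series.product_signal / peak
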