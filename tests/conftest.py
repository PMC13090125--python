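import numpy as np
import pytest

from dreams.nn.model import EncoderConfig, SpectrumTransformer
from dreams.spectrum import IonizationMode, Spectrum
from dreams.synthetic import SimConfig, generate_annotated_library, generate_run


def make_spectrum(mz, intensity, **kwargs):
    defaults = dict(
        precursor_mz=500.0,
        precursor_charge=1,
        retention_time=10.0,
        ms_level=2,
        ionization_mode=IonizationMode.POSITIVE,
    )
    defaults.update(kwargs)
    return Spectrum(mz=np.asarray(mz, float), intensity=np.asarray(intensity, float), **defaults)


@pytest.fixture(scope="session")
def tiny_cfg():
    return EncoderConfig(
        d=32,
        d_m=28,
        d_p=4,
        layers=2,
        heads=4,
        c=200,
        n_peaks=8,
        ffn_f_depth=2,
        ffn_f_hidden=32,
        m_min=0.05,
        m_max=100,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return SpectrumTransformer(tiny_cfg, seed=7)


@pytest.fixture(scope="session")
def synthetic_run():
    run, truth = generate_run(SimConfig(seed=11, n_scans=60))
    return run, truth


@pytest.fixture(scope="session")
def annotated_library():
    return generate_annotated_library(
        SimConfig(seed=13), n_molecules=16, spectra_per_molecule=2
    )
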