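import numpy as np
import pytest

import etdscore as e
from etdscore.spectra import remove_precursor_peaks


@pytest.fixture(scope="session")
def benchmark():
    """Seeded 130-pair synthetic ETD benchmark, preprocessed for training."""
    rng = np.random.default_rng(1)
    cfg = e.GeneratorConfig()
    spectra, pairs, truth = e.generate_benchmark(cfg, 130, rng)
    spectra = {k: remove_precursor_peaks(v) for k, v in spectra.items()}
    return cfg, spectra, pairs, truth


@pytest.fixture(scope="session")
def trained_model(benchmark):
    """ScoringModel + per-type report trained on the session benchmark."""
    _, spectra, pairs, _ = benchmark
    return e.train_scoring_model(pairs, spectra, seed=7)


def make_spectrum(mz, intensity, precursor_mz=600.0, charge=2, sid="s"):
    return e.Spectrum(
        id=sid,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        precursor_mz=precursor_mz,
        precursor_charge=charge,
    )


def random_flat_spectrum(rng, n_peaks):
    """Structureless random spectrum (uniform m/z, log-normal intensity)."""
    return make_spectrum(
        mz=np.sort(rng.uniform(100.0, 1500.0, size=n_peaks)),
        intensity=rng.lognormal(4.0, 1.0, size=n_peaks),
        precursor_mz=float(rng.uniform(400.0, 900.0)),
        charge=int(rng.integers(2, 4)),
    )
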