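import numpy as np
import pytest

from adductshift.pipeline import RunConfig, run_subject
from adductshift.registry import colon_panel
from adductshift.synthetic import build_layout, preset_config, simulate_dataset


@pytest.fixture(scope="session")
def panel():
    return colon_panel()


@pytest.fixture(scope="session")
def small_layout():
    return build_layout(32, 32, 2, seed=5)


@pytest.fixture(scope="session")
def noiseless_config():
    """Zero-noise stated world: emitted peaks equal ground truth exactly."""
    return preset_config(
        "healthy",
        seed=11,
        mz_jitter_sigma=0.0,
        intensity_cv=0.0,
        tic_cv=0.0,
        n_noise_peaks=0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(small_layout, noiseless_config):
    return simulate_dataset(small_layout, noiseless_config)


@pytest.fixture(scope="session")
def noiseless_table(noiseless_dataset, panel):
    """Deconvolved table of the zero-noise healthy dataset."""
    from adductshift.deconvolve import annotate, apportion_overlaps, estimate_class_ratios
    from adductshift.preprocess import align_to_axis, filter_dataset, normalize_dataset

    dataset, _ = noiseless_dataset
    dataset = normalize_dataset(dataset)
    aligned, axis = align_to_axis(dataset, 6.0)
    filtered = filter_dataset(aligned, 0.005)
    annot = annotate(filtered, axis, panel, 9.0)
    return apportion_overlaps(annot, estimate_class_ratios(annot))


@pytest.fixture(scope="session")
def small_run_config():
    """A reduced raster for tests that push subjects through the full pipeline."""
    return RunConfig(width=32, height=32, n_crypts=2)


@pytest.fixture(scope="session")
def healthy_subject(small_run_config):
    return run_subject("healthy", 101, small_run_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2021)
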