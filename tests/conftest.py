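import numpy as np
import pytest
from hypothesis import settings

from sersscreen import (
    MCRConfig,
    SpectralDataset,
    default_config,
    fit,
    generate_dataset,
    match_components,
    preprocess_dataset,
    reference_spectra,
    run_scenario,
    spiked_urine_design,
    water_dilution_design,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def water_ds():
    return generate_dataset(water_dilution_design(seed=1))


@pytest.fixture(scope="session")
def water_raw(water_ds):
    return SpectralDataset(
        water_ds.grid, np.maximum(water_ds.matrix, 0.0), water_ds.manifest.copy()
    )


@pytest.fixture(scope="session")
def water_signed(water_ds):
    return preprocess_dataset(water_ds, clip=False)


@pytest.fixture(scope="session")
def water_fit(water_raw):
    refs = reference_spectra(water_raw.grid, ["enrofloxacin"])
    cfg = MCRConfig(n_components=6, seed=1, smooth_background=1e6)
    result = fit(water_raw, refs=refs, config=cfg)
    assignment = match_components(result.S, refs)
    return result, assignment, refs


@pytest.fixture(scope="session")
def urine_ds():
    return generate_dataset(spiked_urine_design(seed=1))


@pytest.fixture(scope="session")
def urine_raw(urine_ds):
    return SpectralDataset(
        urine_ds.grid, np.maximum(urine_ds.matrix, 0.0), urine_ds.manifest.copy()
    )


@pytest.fixture(scope="session")
def urine_fit(urine_raw):
    refs = reference_spectra(urine_raw.grid, ["enrofloxacin"])
    cfg = MCRConfig(n_components=6, seed=1, smooth_background=1e5)
    result = fit(urine_raw, refs=refs, config=cfg)
    assignment = match_components(result.S, refs)
    return result, assignment, refs


@pytest.fixture(scope="session")
def invivo_reports():
    return run_scenario(default_config("in_vivo", seed=1))
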