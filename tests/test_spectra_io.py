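import numpy as np
import pandas as pd
import pytest

from sersscreen import (
    ConditionSpec,
    DatasetDesign,
    MatrixModel,
    SpectralDataset,
    Spectrum,
    SpectrumParseError,
    average_replicates,
    generate_dataset,
    read_dataset,
    read_spectrum,
    subtract_baseline,
)


def test_three_point_file(tmp_path):
    p = tmp_path / "s.csv"
    p.write_text("wavenumber_cm1,intensity\n400,1.0\n402,2.0\n404,1.0\n")
    s = read_spectrum(p)
    assert len(s) == 3
    np.testing.assert_array_equal(s.grid, [400, 402, 404])


def test_round_trip_identity(tmp_path):
    rng = np.random.default_rng(0)
    s = Spectrum(np.arange(400.0, 500.0, 2.0), rng.random(50))
    s.write(tmp_path / "s.csv")
    back = read_spectrum(tmp_path / "s.csv")
    np.testing.assert_allclose(back.intensities, s.intensities, atol=1e-9)
    np.testing.assert_allclose(back.grid, s.grid, atol=1e-9)


def test_manifest_round_trip_preserves_rows(tmp_path):
    """A written dataset manifest reads back with one row per spectrum,
    including a 250-spectrum pool."""
    conds = tuple(
        ConditionSpec(f"c{c:g}", "enrofloxacin", float(c), 50) for c in (10, 20, 50, 100, 10000)
    )
    design = DatasetDesign(conds, matrix=MatrixModel(noise_sigma=0.01), seed=0)
    ds = generate_dataset(design)
    man = ds.write(tmp_path)
    back = read_dataset(man)
    assert back.n_spectra == 250
    np.testing.assert_allclose(back.matrix, ds.matrix, atol=1e-9)


@pytest.mark.parametrize(
    "content",
    [
        "w,i\n400,1.0\n390,2.0\n",          # non-monotone grid
        "w,i\n400,1.0\n402,nan\n",          # NaN intensity
        "w,i\n400,1.0,9\n",                 # wrong column count
        "w,i\n400,abc\n",                   # non-numeric
    ],
)
def test_parse_errors_name_the_file(tmp_path, content):
    p = tmp_path / "bad.csv"
    p.write_text(content)
    with pytest.raises(SpectrumParseError, match="bad.csv"):
        read_spectrum(p)


def test_missing_manifest_is_parse_error(tmp_path):
    with pytest.raises(SpectrumParseError):
        read_dataset(tmp_path / "nope.csv")


def test_resample_identity_and_no_extrapolation():
    s = Spectrum(np.arange(400.0, 500.0, 2.0), np.arange(50.0))
    same = s.resample(s.grid)
    np.testing.assert_array_equal(same.intensities, s.intensities)
    with pytest.raises(ValueError):
        s.resample(np.arange(300.0, 500.0, 2.0))


def test_common_grid_drops_uncovered_channels(tmp_path):
    a = Spectrum(np.arange(400.0, 501.0, 2.0), np.ones(51), {"sample_id": "a"})
    b = Spectrum(np.arange(420.0, 481.0, 2.0), np.ones(31), {"sample_id": "b"})
    a.write(tmp_path / "a.csv")
    b.write(tmp_path / "b.csv")
    pd.DataFrame({"file": ["a.csv", "b.csv"]}).to_csv(tmp_path / "manifest.csv", index=False)
    ds = read_dataset(tmp_path / "manifest.csv")
    assert ds.grid[0] >= 420.0 and ds.grid[-1] <= 480.0


# ---------------------------------------------------------------------------
# Baseline subtraction
# ---------------------------------------------------------------------------

GRID = np.arange(400.0, 1800.0, 2.0)


def test_flat_spectrum_baseline_removed():
    s = Spectrum(GRID, np.full(GRID.size, 7.0))
    out = subtract_baseline(s)
    assert np.max(np.abs(out.intensities)) < 1e-6 * 7.0


def test_quadratic_background_mostly_removed():
    bg = 5.0 + 1e-5 * (GRID - 400.0) ** 2  # slowly varying, max ~25
    out = subtract_baseline(Spectrum(GRID, bg))
    assert np.max(np.abs(out.intensities)) < 0.02 * bg.max()


def test_peak_on_quadratic_background_recovered():
    """Known injected Lorentzian: recovered height within 5%."""
    peak = 10.0 / (1.0 + (2.0 * (GRID - 1000.0) / 12.0) ** 2)
    bg = 5.0 + 1e-5 * (GRID - 400.0) ** 2
    out = subtract_baseline(Spectrum(GRID, bg + peak))
    apex = np.argmin(np.abs(GRID - 1000.0))
    assert out.intensities[apex] == pytest.approx(10.0, rel=0.05)


def test_baseline_subtraction_idempotent():
    """Re-applying the baseline step changes the corrected spectrum by well
    under 1% of the spectrum's RMS: the smooth curve has already been
    removed, and only a sliver of peak area is shaved per pass."""
    rng = np.random.default_rng(3)
    peak = 5.0 / (1.0 + (2.0 * (GRID - 1200.0) / 12.0) ** 2)
    y = 2.0 + 0.002 * (GRID - 400.0) + peak + 0.002 * rng.standard_normal(GRID.size)
    once = subtract_baseline(Spectrum(GRID, y))
    twice = subtract_baseline(once)
    rms = lambda v: float(np.sqrt(np.mean(v**2)))
    assert rms(twice.intensities - once.intensities) < 0.01 * rms(y)


@pytest.mark.parametrize("kwargs", [{"lam": 0.0}, {"lam": -1.0}, {"p": 0.0}, {"p": 1.0}])
def test_baseline_parameter_validation(kwargs):
    s = Spectrum(GRID, np.ones(GRID.size))
    with pytest.raises(ValueError):
        subtract_baseline(s, **kwargs)


def test_baseline_needs_enough_channels():
    s = Spectrum(np.arange(5.0), np.ones(5))
    with pytest.raises(ValueError):
        subtract_baseline(s)


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------

def _toy_dataset():
    grid = np.arange(400.0, 420.0, 2.0)
    rows = np.array([[1.0] * 10, [3.0] * 10, [5.0] * 10])
    man = pd.DataFrame(
        {"condition": ["a", "a", "b"], "concentration_ppm": [1, 1, 2], "sample_id": list("xyz")}
    )
    return SpectralDataset(grid, rows, man)


def test_average_replicates_means_and_counts():
    avg = average_replicates(_toy_dataset(), by="condition")
    assert avg.n_spectra == 2
    np.testing.assert_allclose(avg.matrix[0], 2.0)  # (1+3)/2
    np.testing.assert_allclose(avg.matrix[1], 5.0)
    assert avg.manifest["n_averaged"].sum() == 3


def test_average_identical_rows_is_identity():
    ds = _toy_dataset()
    ds.matrix[1] = ds.matrix[0]
    avg = average_replicates(ds, by="condition")
    np.testing.assert_array_equal(avg.matrix[0], ds.matrix[0])


def test_average_missing_key_rejected():
    with pytest.raises(KeyError):
        average_replicates(_toy_dataset(), by="nope")
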