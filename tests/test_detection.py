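"""Peak calling, LOD rules, concentration trends, condition comparison and
MRL screening."""

import numpy as np
import pandas as pd
import pytest

from sersscreen import (
    ConditionSpec,
    DatasetDesign,
    MatrixModel,
    SpectralDataset,
    Spectrum,
    call_peaks,
    compare_conditions,
    concentration_trend,
    generate_dataset,
    identify,
    lod_mcr,
    lod_univariate,
    make_grid,
    preprocess_dataset,
    screen,
    simulate_spectrum,
)
from sersscreen.detection import NOT_REACHED, analyte_intensity
from sersscreen.mcr import ComponentAssignment, MCRConfig, MCRResult
from sersscreen.references import ENROFLOXACIN, NEOMYCIN
from sersscreen.simulate import WATER_MATRIX

GRID = make_grid()


def test_noiseless_enrofloxacin_both_id_peaks_found():
    s = simulate_spectrum(ENROFLOXACIN, 50.0, MatrixModel(), seed=0)
    calls = call_peaks(s, ENROFLOXACIN)
    assert {c.center_cm1 for c in calls} == {1390.0, 1624.0}
    assert all(c.found for c in calls)
    assert identify(s, ENROFLOXACIN)


def test_all_zero_spectrum_no_peaks():
    s = Spectrum(GRID, np.zeros(GRID.size))
    assert not any(c.found for c in call_peaks(s, ENROFLOXACIN))


def test_snr_estimate_unbiased_at_10_sigma():
    """Injected single peak of height 10*sigma: the MAD-based SNR averages
    within 20% of 10 over 100 noise draws."""
    sigma = 0.05
    peak = 10 * sigma / (1.0 + (2.0 * (GRID - 977.0) / 12.0) ** 2)
    snrs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        y = peak + sigma * rng.standard_normal(GRID.size)
        calls = call_peaks(Spectrum(GRID, y), NEOMYCIN)
        snrs.append(calls[0].snr)
    assert np.mean(snrs) == pytest.approx(10.0, rel=0.2)


def test_oversized_window_rejected():
    s = Spectrum(GRID, np.zeros(GRID.size))
    with pytest.raises(ValueError):
        call_peaks(s, ENROFLOXACIN, window_cm1=2000.0)


def _series(matrix, concs, reps, seed=0, analyte="enrofloxacin"):
    conds = [ConditionSpec("blank", analyte, 0.0, reps)]
    conds += [ConditionSpec(f"c{c:g}", analyte, float(c), reps) for c in concs]
    return generate_dataset(DatasetDesign(tuple(conds), matrix=matrix, seed=seed))


def test_lod_univariate_zero_noise_reaches_lowest_level():
    ds = _series(MatrixModel(noise_sigma=0.0, response_coeff=1.0), [0.01, 0.1, 1.0], reps=2)
    res = lod_univariate(ds, ENROFLOXACIN)
    assert res.lod_ppm == 0.01


def test_lod_univariate_blank_signal_not_reached():
    """Concentration labels present but no analyte signal in any spectrum."""
    ds = _series(MatrixModel(noise_sigma=0.05, response_coeff=1.0), [0.1, 1.0], reps=3)
    ds = SpectralDataset(ds.grid, np.zeros_like(ds.matrix), ds.manifest)
    noise = 0.05 * np.random.default_rng(0).standard_normal(ds.matrix.shape)
    ds = SpectralDataset(ds.grid, noise, ds.manifest)
    assert lod_univariate(ds, ENROFLOXACIN).lod_ppm == NOT_REACHED


def test_lod_univariate_requires_concentrations():
    ds = _series(MatrixModel(), [1.0], reps=1)
    man = ds.manifest.copy()
    man["concentration_ppm"] = 0.0
    with pytest.raises(ValueError):
        lod_univariate(SpectralDataset(ds.grid, ds.matrix, man), ENROFLOXACIN)


def test_lod_monotone_in_noise():
    """Raising noise_sigma never lowers the reported univariate LOD (shared
    seed across the noise grid)."""
    lods = []
    for sigma in (0.01, 0.05, 0.1, 0.3):
        m = MatrixModel(noise_sigma=sigma, response_coeff=1.0)
        ds = _series(m, [0.1, 0.5, 2.0, 10.0], reps=3, seed=11)
        res = lod_univariate(preprocess_dataset(ds, clip=False), ENROFLOXACIN)
        lods.append(np.inf if res.lod_ppm == NOT_REACHED else res.lod_ppm)
    assert all(b >= a for a, b in zip(lods, lods[1:]))


def test_lod_mcr_blanks_only_not_reached():
    conds = (ConditionSpec("blank", "enrofloxacin", 0.0, 8),)
    ds = generate_dataset(DatasetDesign(conds, matrix=WATER_MATRIX, seed=0))
    raw = SpectralDataset(ds.grid, np.maximum(ds.matrix, 0.0), ds.manifest)
    res, _, _ = lod_mcr(raw, ENROFLOXACIN, config=MCRConfig(n_components=3, seed=0))
    assert res.lod_ppm == NOT_REACHED


def test_lod_mcr_not_below_univariate_on_water(water_signed, water_raw, water_fit):
    """Pooling and unmixing can only help: the MCR LOD never exceeds the
    univariate LOD on the same dataset when both are reached."""
    uni = lod_univariate(water_signed, ENROFLOXACIN)
    result, assignment, refs = water_fit
    mcr_res, _, _ = lod_mcr(
        water_raw, ENROFLOXACIN,
        config=MCRConfig(6, seed=1, smooth_background=1e6), result=result,
    )
    assert uni.reached and mcr_res.reached
    assert mcr_res.lod_ppm <= uni.lod_ppm


# ---------------------------------------------------------------------------
# Trend / comparison / screening on synthetic contribution matrices
# ---------------------------------------------------------------------------

def _fake_fit(intensities, manifest):
    """Wrap a known per-sample intensity vector as a single-component fit."""
    C = np.asarray(intensities, float)[:, None]
    S = np.ones((1, 8))
    result = MCRResult(C=C, S=S, lof_percent=[1.0], n_iter=1, converged=True,
                       explained_variance=0.99)
    assignment = ComponentAssignment(
        assignments={"enrofloxacin": 0}, similarity={"enrofloxacin": 1.0},
        similarity_matrix=np.ones((1, 1)), analytes=("enrofloxacin",), threshold=0.7,
    )
    return result, assignment


def test_trend_spearman_on_urine_pool(urine_raw, urine_fit):
    result, assignment, _ = urine_fit
    trend = concentration_trend(result, assignment, urine_raw.manifest,
                                "enrofloxacin", data=urine_raw)
    assert trend["spearman_rho"] == pytest.approx(1.0)
    assert trend["levels_ppm"] == [10.0, 20.0, 50.0, 100.0, 10000.0]


def test_trend_shuffled_labels_uncorrelated(urine_raw, urine_fit):
    """Permuting the concentration labels destroys the per-sample rank
    correlation (mean |rho| over 100 shuffles well below the real trend)."""
    result, assignment, _ = urine_fit
    rng = np.random.default_rng(0)
    rhos = []
    for _ in range(100):
        man = urine_raw.manifest.assign(
            concentration_ppm=rng.permutation(urine_raw.manifest["concentration_ppm"].to_numpy())
        )
        t = concentration_trend(result, assignment, man, "enrofloxacin", data=urine_raw)
        rhos.append(abs(t["spearman_rho_samples"]))
    assert np.mean(rhos) < 0.3


def test_trend_handles_tied_concentrations():
    man = pd.DataFrame({
        "concentration_ppm": [1.0, 1.0, 2.0, 2.0, 5.0, 5.0],
        "condition": ["a"] * 6,
    })
    result, assignment = _fake_fit([1.0, 1.1, 2.0, 2.1, 5.0, 5.1], man)
    t = concentration_trend(result, assignment, man, "enrofloxacin")
    assert t["spearman_rho"] == pytest.approx(1.0)


def test_trend_requires_assignment(urine_raw, urine_fit):
    result, _, _ = urine_fit
    empty = ComponentAssignment({}, {"enrofloxacin": 0.1}, np.zeros((6, 1)),
                                ("enrofloxacin",), 0.7)
    with pytest.raises(ValueError):
        concentration_trend(result, empty, urine_raw.manifest, "enrofloxacin")


def test_compare_conditions_ordering(invivo_reports):
    comp = invivo_reports["comparison"]
    m = comp.condition_means
    assert m["day7"] > m["day1"] > m["control"]
    assert comp.ordering_ok
    assert comp.control_detected_fraction <= 0.1
    assert comp.condition_means["control"] < comp.detection_cut


def test_compare_identical_conditions_not_separable():
    rng = np.random.default_rng(1)
    vals = rng.normal(5.0, 0.5, size=30)
    man = pd.DataFrame({"condition": ["control"] * 10 + ["day1"] * 10 + ["day7"] * 10})
    result, assignment = _fake_fit(vals, man)
    comp = compare_conditions(result, assignment, man)
    assert not comp.separable
    assert not comp.ordering_ok


def test_compare_missing_condition_rejected():
    man = pd.DataFrame({"condition": ["control"] * 4 + ["day1"] * 4})
    result, assignment = _fake_fit(np.ones(8), man)
    with pytest.raises(ValueError, match="day7"):
        compare_conditions(result, assignment, man)


def test_screening_calls_on_urine_pool(urine_raw, urine_fit):
    """MRL 100 ppm: the 10-100 ppm spiked samples are detections below the
    guard cut, never positive; the 10,000 ppm samples are all positive."""
    result, assignment, _ = urine_fit
    report = screen(result, assignment, urine_raw.manifest,
                    analyte="enrofloxacin", mrl_ppm=100.0, data=urine_raw)
    s = report.samples
    low = s[s["concentration_ppm"].between(10, 100)]
    assert low["detected"].all()
    assert not (low["call"] == "positive").any()
    high = s[s["concentration_ppm"] == 10000.0]
    assert (high["call"] == "positive").all()
    controls = s[s["concentration_ppm"] == 0.0]
    assert (controls["call"] == "negative").all()


def test_screening_needs_calibration_levels():
    man = pd.DataFrame({
        "concentration_ppm": [0.0, 0.0, 200.0, 200.0],
        "condition": ["blank", "blank", "c200", "c200"],
        "sample_id": list("abcd"),
    })
    result, assignment = _fake_fit([0.0, 0.1, 5.0, 5.2], man)
    with pytest.raises(ValueError):
        screen(result, assignment, man, mrl_ppm=100.0)
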