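"""Seeded synthetic SERS datasets with the statistical structure the
screening analysis assumes.

Each simulated trace is

    I(w) = response_coeff * sensitivity * g(c) * R(w)          analyte signal
         + sum_j a_j F_j(w)                                    autofluorescence
         + matrix peaks + offset + slope * (w - w_min)         matrix/baseline
         + N(0, noise_sigma^2)  i.i.d. per channel             shot/read noise

where R is the max-normalized reference spectrum, g(c) = c / (1 + c/c_sat)
is linear in concentration below the substrate saturation c_sat and
Langmuir-saturating above it, and the fluorescence amplitudes a_j carry
per-sample log-normal jitter.  Three packaged matrix models define the study
conditions: clean water, spiked pig urine (strong broad autofluorescence and
a urea-region band near 1000 cm^-1), and in-vivo urine whose day-7 condition
carries a larger 1000 cm^-1 matrix band.

All randomness flows from a single integer design seed through
``numpy.random.SeedSequence``; a per-row child seed is recorded in the
manifest so any one spectrum can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .references import PeakSpec, ReferenceDefinition, REFERENCE_LIBRARY, build_reference_spectrum
from .spectra import Spectrum, SpectralDataset

DEFAULT_GRID = (400.0, 1800.0, 2.0)  # cm^-1: min, max, step — covers every bundled peak


def make_grid(spec: tuple[float, float, float] = DEFAULT_GRID) -> np.ndarray:
    lo, hi, step = spec
    if not (hi > lo and step > 0):
        raise ValueError("grid must be strictly increasing")
    return np.arange(lo, hi + 0.5 * step, step)


@dataclass(frozen=True)
class MatrixModel:
    """Everything in a measured spectrum that is not the analyte.

    fluorescence_components: broad bands (fwhm >= 200 cm^-1) whose
    rel_amplitude is the per-sample median; amplitudes are jittered
    log-normally with ``fluorescence_sigma_log``.  matrix_peaks are sharp
    non-analyte bands (urea region near 1000 cm^-1 in urine).  response_coeff
    is the substrate's SERS response in a.u. per ppm for a unit-sensitivity
    analyte; saturation_conc (ppm) is the Langmuir saturation scale
    (``None`` = strictly linear).
    """

    fluorescence_components: tuple[PeakSpec, ...] = ()
    matrix_peaks: tuple[PeakSpec, ...] = ()
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    noise_sigma: float = 0.0
    response_coeff: float = 1.0
    saturation_conc: float | None = None
    fluorescence_sigma_log: float = 0.3
    baseline_sigma_log: float = 0.0     # per-sample jitter of the offset
    matrix_peak_sigma_log: float = 0.0  # per-sample jitter of matrix bands

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.response_coeff <= 0:
            raise ValueError("response_coeff must be positive")
        for f in self.fluorescence_components:
            if f.fwhm < 200:
                raise ValueError("fluorescence components must be broad (fwhm >= 200 cm^-1)")
        if self.saturation_conc is not None and self.saturation_conc <= 0:
            raise ValueError("saturation_conc must be positive or None")

    def response(self, conc: float) -> float:
        """Langmuir-saturating concentration response g(c) (linear at low c)."""
        if self.saturation_conc is None:
            return conc
        return conc / (1.0 + conc / self.saturation_conc)

    def scaled_matrix_peaks(self, factor: float) -> "MatrixModel":
        peaks = tuple(replace(p, rel_amplitude=p.rel_amplitude * factor) for p in self.matrix_peaks)
        return replace(self, matrix_peaks=peaks)


# ---------------------------------------------------------------------------
# Packaged study conditions.  Amplitude/noise constants are the frozen
# calibration of the synthetic platform (docs/methods.md): water noise 0.05
# a.u. with unit enrofloxacin response puts the per-spectrum SNR threshold
# crossing between 0.1 and 0.5 ppm; urine fluorescence is strong enough that
# single-spectrum identification fails below the 10,000 ppm level while
# unmixing still recovers 10 ppm.
# ---------------------------------------------------------------------------

WATER_MATRIX = MatrixModel(
    fluorescence_components=(
        PeakSpec(900, fwhm=400, rel_amplitude=0.4),
        PeakSpec(1150, fwhm=500, rel_amplitude=0.5),
        PeakSpec(1450, fwhm=350, rel_amplitude=0.3),
    ),
    baseline_offset=0.5,
    baseline_slope=5e-4,
    noise_sigma=0.05,
    response_coeff=1.0,
    saturation_conc=2000.0,
    fluorescence_sigma_log=0.3,
    baseline_sigma_log=0.3,
)

URINE_MATRIX = MatrixModel(
    fluorescence_components=(
        PeakSpec(900, fwhm=500, rel_amplitude=120.0),
        PeakSpec(1200, fwhm=600, rel_amplitude=200.0),
        PeakSpec(1550, fwhm=450, rel_amplitude=100.0),
    ),
    matrix_peaks=(PeakSpec(1000, fwhm=16, rel_amplitude=3.0),),
    baseline_offset=5.0,
    baseline_slope=2e-3,
    noise_sigma=0.15,
    response_coeff=0.12,
    saturation_conc=2000.0,
    fluorescence_sigma_log=0.25,
    baseline_sigma_log=0.3,
)

# Standard stock solutions are measured as droplets on the same substrate,
# so they share the scenario's matrix model.
STANDARD_CONC_PPM = 1000.0

DAY7_MATRIX_PEAK_SCALE = 2.0  # stronger urea-region band in day-7 urine
DAY7_CONC_FACTOR = 3.0        # consecutive dosing: higher effective level on day 7
DAY1_CONC_PPM = 30.0

WATER_DILUTION_PPM = (0.01, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
SPIKED_URINE_PPM = (10.0, 20.0, 50.0, 100.0, 10000.0)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: label, analyte, true concentration, replicate count.

    ``matrix`` optionally overrides the design-level matrix model (used for
    the day-7 urea band in the in-vivo design).
    """

    label: str
    analyte: str
    concentration_ppm: float
    n_replicates: int
    matrix: MatrixModel | None = None

    def __post_init__(self) -> None:
        if self.concentration_ppm < 0:
            raise ValueError(f"{self.label}: concentration must be >= 0")
        if self.n_replicates < 1:
            raise ValueError(f"{self.label}: n_replicates must be >= 1")


@dataclass(frozen=True)
class DatasetDesign:
    """A full synthetic acquisition: conditions, grid, matrix model, master seed."""

    conditions: tuple[ConditionSpec, ...]
    matrix: MatrixModel
    grid: tuple[float, float, float] = DEFAULT_GRID
    seed: int = 0

    @property
    def n_rows(self) -> int:
        return sum(c.n_replicates for c in self.conditions)


def simulate_spectrum(
    ref: ReferenceDefinition,
    conc: float,
    matrix: MatrixModel,
    seed: int,
    grid: np.ndarray | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """One synthetic SERS trace; identical seed => bit-identical spectrum."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if grid is None:
        grid = make_grid()
    rng = np.random.default_rng(seed)
    y = np.zeros_like(grid, dtype=float)
    # analyte signal
    signal = matrix.response_coeff * ref.sensitivity * matrix.response(conc)
    if signal > 0:
        y += signal * build_reference_spectrum(ref, grid)
    # autofluorescence with per-sample log-normal amplitude jitter
    for f in matrix.fluorescence_components:
        jitter = float(np.exp(matrix.fluorescence_sigma_log * rng.standard_normal()))
        y += jitter * f.profile(grid)
    for p in matrix.matrix_peaks:
        jitter = float(np.exp(matrix.matrix_peak_sigma_log * rng.standard_normal()))
        y += jitter * p.profile(grid)
    # offset amplitude jitters per sample; the slope term is a fixed
    # instrument/substrate property shared by all spectra of a scenario
    off_j = float(np.exp(matrix.baseline_sigma_log * rng.standard_normal()))
    y += off_j * matrix.baseline_offset + matrix.baseline_slope * (grid - grid[0])
    if matrix.noise_sigma > 0:
        y += matrix.noise_sigma * rng.standard_normal(grid.size)
    return Spectrum(grid, y, dict(meta or {}))


def generate_dataset(design: DatasetDesign) -> SpectralDataset:
    """One spectrum per (condition, replicate); manifest carries per-row seeds."""
    grid = make_grid(design.grid)
    for cond in design.conditions:
        if cond.analyte not in REFERENCE_LIBRARY:
            raise ValueError(f"unknown analyte {cond.analyte!r}")
    child_seeds = np.random.SeedSequence(design.seed).generate_state(design.n_rows)
    rows = []
    metas = []
    i = 0
    for cond in design.conditions:
        ref = REFERENCE_LIBRARY[cond.analyte]
        matrix = cond.matrix if cond.matrix is not None else design.matrix
        for rep in range(cond.n_replicates):
            seed = int(child_seeds[i])
            s = simulate_spectrum(ref, cond.concentration_ppm, matrix, seed=seed, grid=grid)
            rows.append(s.intensities)
            metas.append(
                {
                    "sample_id": f"{cond.label}_r{rep:02d}",
                    "analyte": cond.analyte,
                    "concentration_ppm": cond.concentration_ppm,
                    "condition": cond.label,
                    "replicate": rep,
                    "seed": seed,
                }
            )
            i += 1
    return SpectralDataset(grid, np.vstack(rows), pd.DataFrame(metas))


# ---------------------------------------------------------------------------
# Scenario designs
# ---------------------------------------------------------------------------

def water_dilution_design(
    analyte: str = "enrofloxacin",
    seed: int = 1,
    n_replicates: int = 5,
    n_blanks: int = 6,
    n_standards: int = 3,
    concentrations: tuple[float, ...] = WATER_DILUTION_PPM,
) -> DatasetDesign:
    """Aqueous dilution series: blanks, ten concentration levels, aqueous standards.

    Defaults give 6 + 10*5 + 3 = 59 spectra for the enrofloxacin run.
    """
    conds = [ConditionSpec("blank", analyte, 0.0, n_blanks)]
    conds += [ConditionSpec(f"c{c:g}", analyte, c, n_replicates) for c in concentrations]
    if n_standards:
        conds.append(ConditionSpec("standard", analyte, STANDARD_CONC_PPM, n_standards))
    return DatasetDesign(tuple(conds), matrix=WATER_MATRIX, seed=seed)


def spiked_urine_design(
    seed: int = 1,
    n_replicates: int = 50,
    n_controls: int = 10,
    concentrations: tuple[float, ...] = SPIKED_URINE_PPM,
) -> DatasetDesign:
    """Control urine spiked with enrofloxacin at five levels, 50 replicates
    each (250 spiked spectra), plus unspiked control urine for the
    detection null."""
    conds = [ConditionSpec("control", "enrofloxacin", 0.0, n_controls)]
    conds += [ConditionSpec(f"c{c:g}", "enrofloxacin", c, n_replicates) for c in concentrations]
    return DatasetDesign(tuple(conds), matrix=URINE_MATRIX, seed=seed)


def in_vivo_design(
    seed: int = 1,
    n_control: int = 13,
    n_day1: int = 20,
    n_day7: int = 20,
    day1_conc: float = DAY1_CONC_PPM,
    day7_factor: float = DAY7_CONC_FACTOR,
) -> DatasetDesign:
    """Control / day-1 / day-7 urine after repeated dosing (53 spectra by default).

    Day 7 carries a higher effective enrofloxacin level (default 3x day 1)
    and a doubled urea-region matrix band.
    """
    base = replace(URINE_MATRIX, matrix_peak_sigma_log=0.2)  # urea varies pig to pig
    day7_matrix = base.scaled_matrix_peaks(DAY7_MATRIX_PEAK_SCALE)
    conds = (
        ConditionSpec("control", "enrofloxacin", 0.0, n_control),
        ConditionSpec("day1", "enrofloxacin", day1_conc, n_day1),
        ConditionSpec("day7", "enrofloxacin", day1_conc * day7_factor, n_day7, matrix=day7_matrix),
    )
    return DatasetDesign(conds, matrix=base, seed=seed)


SCENARIOS = {
    "water_dilution": water_dilution_design,
    "spiked_urine": spiked_urine_design,
    "in_vivo": in_vivo_design,
}
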