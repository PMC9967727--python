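"""Reference peak tables for the three veterinary antibiotics and synthetic
reference spectra built from them.

The bundled library encodes the characteristic SERS bands of enrofloxacin,
oxytetracycline and neomycin measured on silver-nanorod substrates:

* enrofloxacin — 752, 803, 835, 1252, 1390, 1552, 1624 cm^-1; the 1390 and
  1624 cm^-1 bands (symmetric O-C-O stretch, C=O stretch) are the
  identification peaks.  1387 cm^-1 is recorded as an alias of 1390.
* oxytetracycline — 803, 835, 1170, 1254, 1315, 1620 cm^-1; identified by
  1315 and 1620 cm^-1 (aromatic ring modes).
* neomycin — a single dominant band at 977 cm^-1 (CH2 rock / C-C stretch).

The 803/835 cm^-1 bands are shared between enrofloxacin and oxytetracycline
and are therefore given low relative amplitude and never used for
identification.  ``sensitivity`` is the analyte's relative SERS response
(a.u. per ppm, multiplying the matrix model's response coefficient); the
three defaults are calibrated constants of the synthetic study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class PeakSpec:
    """One Raman band: center (cm^-1), full width at half maximum (cm^-1),
    relative amplitude (dimensionless, >= 0), line shape."""

    center: float
    fwhm: float = 12.0
    rel_amplitude: float = 1.0
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"peak at {self.center} cm^-1: fwhm must be positive")
        if not np.isfinite(self.rel_amplitude) or self.rel_amplitude < 0:
            raise ValueError(f"peak at {self.center} cm^-1: rel_amplitude must be finite and >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-height line profile evaluated on ``grid``, scaled by rel_amplitude."""
        x = np.asarray(grid, dtype=float) - self.center
        if self.shape == "lorentzian":
            prof = 1.0 / (1.0 + (2.0 * x / self.fwhm) ** 2)
        else:
            prof = np.exp(-4.0 * np.log(2.0) * (x / self.fwhm) ** 2)
        return self.rel_amplitude * prof


@dataclass(frozen=True)
class ReferenceDefinition:
    """Per-analyte peak table plus the subset of peaks required for a presence call."""

    analyte: str
    peaks: tuple[PeakSpec, ...]
    identification_peaks: tuple[float, ...]
    peak_aliases: dict = field(default_factory=dict)  # alternative printed positions, e.g. 1387 -> 1390
    sensitivity: float = 1.0  # relative SERS response, a.u. per ppm multiplier

    def __post_init__(self) -> None:
        centers = {p.center for p in self.peaks}
        if not self.identification_peaks:
            raise ValueError(f"{self.analyte}: at least one identification peak required")
        missing = [c for c in self.identification_peaks if c not in centers]
        if missing:
            raise ValueError(f"{self.analyte}: identification peaks {missing} not in peak list")
        if self.sensitivity <= 0:
            raise ValueError(f"{self.analyte}: sensitivity must be positive")

    def with_sensitivity(self, sensitivity: float) -> "ReferenceDefinition":
        return replace(self, sensitivity=sensitivity)


def build_reference_spectrum(ref: ReferenceDefinition, grid: np.ndarray) -> np.ndarray:
    """Noiseless sum of the analyte's line profiles on ``grid``, max-normalized to 1.

    An empty peak list yields the all-zero spectrum.  A peak center outside
    the grid range is rejected, naming the analyte and peak.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    for p in ref.peaks:
        if not (grid[0] <= p.center <= grid[-1]):
            raise ValueError(
                f"{ref.analyte}: peak at {p.center} cm^-1 outside grid range "
                f"[{grid[0]}, {grid[-1]}]"
            )
        y += p.profile(grid)
    m = y.max()
    if m > 0:
        y = y / m
    return y


def _peaks(centers_amps, fwhm=12.0):
    return tuple(PeakSpec(c, fwhm=fwhm, rel_amplitude=a) for c, a in centers_amps)


# Identification peaks carry amplitude 1.0, other listed bands 0.5 and the
# shared 803/835 cm^-1 bands 0.3; Lorentzian, fwhm 12 cm^-1 (typical
# solid-state Raman linewidth).  Sensitivities are frozen calibration
# constants of the synthetic study conditions (see docs/methods.md).
ENROFLOXACIN = ReferenceDefinition(
    analyte="enrofloxacin",
    peaks=_peaks([(752, 0.5), (803, 0.3), (835, 0.3), (1252, 0.5), (1390, 1.0), (1552, 0.5), (1624, 1.0)]),
    identification_peaks=(1390.0, 1624.0),
    peak_aliases={1387.0: 1390.0},
    sensitivity=1.0,
)

OXYTETRACYCLINE = ReferenceDefinition(
    analyte="oxytetracycline",
    peaks=_peaks([(803, 0.3), (835, 0.3), (1170, 0.5), (1254, 0.5), (1315, 1.0), (1620, 1.0)]),
    identification_peaks=(1315.0, 1620.0),
    sensitivity=0.13,
)

NEOMYCIN = ReferenceDefinition(
    analyte="neomycin",
    peaks=_peaks([(977, 1.0)]),
    identification_peaks=(977.0,),
    sensitivity=0.0025,
)

REFERENCE_LIBRARY: dict[str, ReferenceDefinition] = {
    r.analyte: r for r in (ENROFLOXACIN, OXYTETRACYCLINE, NEOMYCIN)
}


def reference_library() -> dict[str, ReferenceDefinition]:
    """The bundled analyte definitions, keyed by analyte name."""
    return dict(REFERENCE_LIBRARY)


def reference_spectra(grid: np.ndarray, analytes=None) -> dict[str, np.ndarray]:
    """Baseline-free, max-normalized reference spectra on ``grid`` for matching."""
    lib = REFERENCE_LIBRARY if analytes is None else {a: REFERENCE_LIBRARY[a] for a in analytes}
    return {name: build_reference_spectrum(ref, grid) for name, ref in lib.items()}
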