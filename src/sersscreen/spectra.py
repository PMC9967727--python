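"""Raman spectrum containers, plain-text I/O and preprocessing.

A :class:`Spectrum` is one trace on a strictly increasing wavenumber grid
(cm^-1) with intensities in arbitrary units, plus sample metadata.  A
:class:`SpectralDataset` row-stacks spectra that share a common grid into the
matrix D that downstream unmixing factorizes, with a pandas manifest carrying
per-row metadata.

On-disk formats are deliberately plain: one two-column CSV per spectrum
(wavenumber, intensity; single header line) and a manifest CSV with columns
``file, sample_id, analyte, concentration_ppm, condition, replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

MANIFEST_COLUMNS = ["file", "sample_id", "analyte", "concentration_ppm", "condition", "replicate"]


class SpectrumParseError(ValueError):
    """Raised when a spectrum or manifest file fails validation; names the file (and line where known)."""


@dataclass
class Spectrum:
    """One Raman trace: wavenumber grid (cm^-1), intensities (a.u.), metadata."""

    grid: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.grid.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("grid and intensities must be 1-D")
        if self.grid.shape != self.intensities.shape:
            raise ValueError(
                f"grid length {self.grid.size} != intensities length {self.intensities.size}"
            )
        if not np.all(np.isfinite(self.grid)) or not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite values in spectrum")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def __len__(self) -> int:
        return self.grid.size

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid``.

        Resampling onto the spectrum's own grid is the identity.  Target
        channels outside the measured range are rejected rather than
        extrapolated; callers should clip the target grid to the overlap.
        """
        grid = np.asarray(grid, dtype=float)
        if grid.size == self.grid.size and np.array_equal(grid, self.grid):
            return Spectrum(self.grid.copy(), self.intensities.copy(), dict(self.meta))
        if grid[0] < self.grid[0] - 1e-9 or grid[-1] > self.grid[-1] + 1e-9:
            raise ValueError(
                f"target grid [{grid[0]}, {grid[-1]}] extends beyond measured range "
                f"[{self.grid[0]}, {self.grid[-1]}]; out-of-range channels are not extrapolated"
            )
        y = np.interp(grid, self.grid, self.intensities)
        return Spectrum(grid, y, dict(self.meta))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("wavenumber_cm1,intensity\n")
            for w, i in zip(self.grid, self.intensities):
                fh.write(f"{w:.6g},{i:.10g}\n")


def read_spectrum(path: str | Path, meta: dict | None = None) -> Spectrum:
    """Read a two-column CSV (wavenumber, intensity) with one header line."""
    path = Path(path)
    if not path.exists():
        raise SpectrumParseError(f"{path}: no such file")
    grid: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and any(c.isalpha() for c in line.split(",")[0]):
                continue  # header
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                w, i = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            if not (np.isfinite(w) and np.isfinite(i)):
                raise SpectrumParseError(f"{path}:{lineno}: non-finite value")
            grid.append(w)
            intens.append(i)
    if not grid:
        raise SpectrumParseError(f"{path}: empty spectrum")
    g = np.array(grid)
    if g.size > 1 and not np.all(np.diff(g) > 0):
        raise SpectrumParseError(f"{path}: wavenumber grid not strictly increasing")
    return Spectrum(g, np.array(intens), dict(meta or {}))


@dataclass
class SpectralDataset:
    """Row-stacked spectra on one shared grid (the data matrix D) plus a manifest."""

    grid: np.ndarray
    matrix: np.ndarray  # n_spectra x n_channels
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] < 1:
            raise ValueError("dataset needs at least one spectrum")
        if self.matrix.shape[1] != self.grid.size:
            raise ValueError("matrix column count does not match grid length")
        if len(self.manifest) != self.matrix.shape[0]:
            raise ValueError("manifest row count does not match matrix")
        self.manifest = self.manifest.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    def spectra(self) -> Iterator[Spectrum]:
        for i in range(self.n_spectra):
            yield Spectrum(self.grid, self.matrix[i], self.manifest.iloc[i].to_dict())

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[i], self.manifest.iloc[i].to_dict())

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum], grid: np.ndarray | None = None) -> "SpectralDataset":
        """Stack spectra, interpolating each onto the shared grid (default: first spectrum's)."""
        spectra = list(spectra)
        if not spectra:
            raise ValueError("no spectra given")
        if grid is None:
            grid = spectra[0].grid
        rows = [s.resample(grid).intensities for s in spectra]
        manifest = pd.DataFrame([s.meta for s in spectra])
        for col in MANIFEST_COLUMNS[1:]:
            if col not in manifest.columns:
                manifest[col] = np.nan
        return cls(np.asarray(grid, float), np.vstack(rows), manifest)

    def subset(self, mask) -> "SpectralDataset":
        mask = np.asarray(mask)
        return SpectralDataset(self.grid, self.matrix[mask], self.manifest.loc[mask].reset_index(drop=True))

    def write(self, out_dir: str | Path, prefix: str = "spectrum") -> Path:
        """Write per-spectrum CSVs plus ``manifest.csv``; returns the manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i in range(self.n_spectra):
            fname = f"{prefix}_{i:04d}.csv"
            self.spectrum(i).write(out_dir / fname)
            meta = self.manifest.iloc[i].to_dict()
            meta["file"] = fname
            rows.append(meta)
        man = pd.DataFrame(rows)
        cols = [c for c in MANIFEST_COLUMNS if c in man.columns]
        cols += [c for c in man.columns if c not in cols]
        man = man[cols]
        man_path = out_dir / "manifest.csv"
        man.to_csv(man_path, index=False)
        return man_path


def read_dataset(manifest_path: str | Path, grid: np.ndarray | None = None) -> SpectralDataset:
    """Read a manifest CSV and the spectra it names; align all rows onto one grid.

    The common grid defaults to the first spectrum's grid clipped to the
    wavenumber range covered by every file (out-of-range channels are
    dropped, never extrapolated).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise SpectrumParseError(f"{manifest_path}: no such file")
    try:
        man = pd.read_csv(manifest_path)
    except Exception as exc:  # malformed CSV
        raise SpectrumParseError(f"{manifest_path}: cannot parse manifest ({exc})") from exc
    if "file" not in man.columns:
        raise SpectrumParseError(f"{manifest_path}: manifest lacks required 'file' column")
    base = manifest_path.parent
    spectra = []
    for _, row in man.iterrows():
        meta = row.to_dict()
        s = read_spectrum(base / str(row["file"]), meta=meta)
        spectra.append(s)
    if grid is None:
        lo = max(s.grid[0] for s in spectra)
        hi = min(s.grid[-1] for s in spectra)
        g0 = spectra[0].grid
        grid = g0[(g0 >= lo - 1e-9) & (g0 <= hi + 1e-9)]
        if grid.size == 0:
            raise SpectrumParseError(f"{manifest_path}: spectra share no overlapping wavenumber range")
    return SpectralDataset.from_spectra(spectra, grid=grid)


def asls_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01, n_iter: int = 10) -> np.ndarray:
    """Asymmetric least-squares baseline (Eilers & Boelens).

    Minimizes  sum_i w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2  with
    asymmetric weights w_i = p for y_i > z_i, (1 - p) otherwise, so the
    smooth curve z hugs the lower envelope — appropriate for broad
    fluorescence under sharp Raman bands.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    DtD = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        W = sp.diags(w)
        z = spsolve((W + DtD).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def whittaker_smooth(y: np.ndarray, lam: float) -> np.ndarray:
    """Whittaker smoother: minimizes ||y - z||^2 + lam * ||Delta^2 z||^2."""
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return spsolve((sp.eye(n) + lam * (D.T @ D)).tocsc(), y)


def subtract_baseline(s: Spectrum, lam: float = 1e5, p: float = 0.01, clip: bool = False) -> Spectrum:
    """Return ``s`` minus an asymmetric least-squares baseline.

    ``clip=True`` additionally clips negative residuals at zero (used before
    non-negative factorization; peak calling keeps the signed residual so the
    MAD noise estimate stays meaningful).
    """
    if len(s) < 10:
        raise ValueError("baseline subtraction needs at least 10 channels")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not (0.0 < p < 1.0):
        raise ValueError("asymmetry p must lie in (0, 1)")
    z = asls_baseline(s.intensities, lam=lam, p=p)
    out = s.intensities - z
    if clip:
        out = np.maximum(out, 0.0)
    return Spectrum(s.grid.copy(), out, dict(s.meta))


def preprocess_dataset(ds: SpectralDataset, lam: float = 1e5, p: float = 0.01, clip: bool = False) -> SpectralDataset:
    """Baseline-subtract every row of a dataset (optionally clipping at zero)."""
    rows = np.empty_like(ds.matrix)
    for i in range(ds.n_spectra):
        z = asls_baseline(ds.matrix[i], lam=lam, p=p)
        rows[i] = ds.matrix[i] - z
    if clip:
        np.maximum(rows, 0.0, out=rows)
    return SpectralDataset(ds.grid.copy(), rows, ds.manifest.copy())


def despike(s: Spectrum, kernel: int = 5) -> Spectrum:
    """Optional cosmic-ray removal by median filtering (off by default in the pipeline)."""
    from scipy.signal import medfilt

    return Spectrum(s.grid.copy(), medfilt(s.intensities, kernel_size=kernel), dict(s.meta))


def average_replicates(ds: SpectralDataset, by: str = "condition") -> SpectralDataset:
    """One mean spectrum per group of ``by``; manifest records the group size."""
    if by not in ds.manifest.columns:
        raise KeyError(f"grouping key {by!r} not in manifest")
    rows = []
    metas = []
    for key, idx in ds.manifest.groupby(by, sort=False, dropna=False).groups.items():
        sel = ds.manifest.index.get_indexer(idx)
        rows.append(ds.matrix[sel].mean(axis=0))
        meta = ds.manifest.iloc[sel[0]].to_dict()
        meta[by] = key
        meta["n_averaged"] = len(sel)
        metas.append(meta)
    return SpectralDataset(ds.grid.copy(), np.vstack(rows), pd.DataFrame(metas))
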