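"""Reading, writing, resampling and normalizing FTIR spectra.

All downstream stages (classifier, attribution, fingerprint analysis)
operate on absorbance spectra sampled on one canonical, uniform,
endpoint-inclusive wavenumber grid of 3106 points spanning 650-3775 cm^-1.
This module owns the :class:`WavenumberGrid` / :class:`Spectrum` containers
and the plumbing that moves arbitrary two-column spectral files onto that
grid: CSV and single-block JCAMP-DX input, linear resampling with constant
extrapolation, and per-spectrum min-max normalization to [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "CANONICAL_GRID",
    "DegenerateSpectrumError",
    "SpectrumParseError",
    "Spectrum",
    "WavenumberGrid",
    "normalize_spectrum",
    "read_spectrum",
    "resample_to_grid",
    "write_spectrum",
]


class SpectrumParseError(ValueError):
    """A spectral file could not be parsed; the message names the offending line."""


class DegenerateSpectrumError(ValueError):
    """Raised for inputs that carry no spectral information (constant, <2 points)."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber grid, inclusive of both endpoints.

    Parameters
    ----------
    start, stop : float
        First and last wavenumber in cm^-1 (``start < stop``).
    n_points : int
        Number of grid points (>= 2); spacing is ``(stop - start) / (n_points - 1)``.
    """

    start: float
    stop: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start {self.start} must be < stop {self.stop}")
        if self.n_points < 2:
            raise ValueError("a grid needs at least 2 points")

    @property
    def spacing(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)

    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


#: The grid every classifier consumes: 3106 points over 650-3775 cm^-1
#: (spacing 3125/3105 ~ 1.0064 cm^-1).
CANONICAL_GRID = WavenumberGrid(start=650.0, stop=3775.0, n_points=3106)


@dataclass
class Spectrum:
    """An absorbance spectrum on some wavenumber grid.

    ``grid`` may be a :class:`WavenumberGrid` (uniform) or, for raw file
    input, an explicit ascending wavenumber array stored in ``wavenumbers``.
    """

    absorbance: np.ndarray
    grid: WavenumberGrid | None = None
    wavenumbers_: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers_ is not None:
            self.wavenumbers_ = np.asarray(self.wavenumbers_, dtype=float)
            if self.wavenumbers_.shape != self.absorbance.shape:
                raise ValueError("wavenumber and absorbance lengths differ")
        if self.grid is not None and self.absorbance.size != self.grid.n_points:
            raise ValueError(
                f"absorbance length {self.absorbance.size} != grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    def wavenumbers(self) -> np.ndarray:
        if self.grid is not None:
            return self.grid.wavenumbers()
        assert self.wavenumbers_ is not None
        return self.wavenumbers_

    @property
    def n_points(self) -> int:
        return self.absorbance.size


def _parse_two_column_text(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\s;]+", line)
        parts = [p for p in parts if p]
        if len(parts) < 2:
            raise SpectrumParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise SpectrumParseError(f"{path}:{lineno}: non-numeric data {line!r}") from None
        xs.append(x)
        ys.append(y)
    return np.asarray(xs), np.asarray(ys)


def _dedupe_sort(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort ascending in wavenumber; average duplicate wavenumbers."""
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inverse = np.unique(x, return_inverse=True)
    if ux.size == x.size:
        return x, y
    sums = np.zeros(ux.size)
    counts = np.zeros(ux.size)
    np.add.at(sums, inverse, y)
    np.add.at(counts, inverse, 1.0)
    return ux, sums / counts


def _parse_jcamp(lines: list[str], path: str) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Parse a single-block JCAMP-DX file: ##XYDATA=(X++(Y..Y)) or ##XYPOINTS."""
    meta: dict[str, Any] = {}
    header: dict[str, str] = {}
    i = 0
    mode = None
    data_start = 0
    for i, raw in enumerate(lines):
        line = raw.strip()
        m = re.match(r"##\$?([^=]+)=\s*(.*)", line)
        if not m:
            continue
        key = m.group(1).strip().upper().replace(" ", "")
        val = m.group(2).strip()
        header[key] = val
        if key == "XYDATA":
            mode, data_start = "xydata", i + 1
            break
        if key == "XYPOINTS":
            mode, data_start = "xypoints", i + 1
            break
    if mode is None:
        raise SpectrumParseError(f"{path}: no ##XYDATA or ##XYPOINTS block found")

    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(lines[data_start:], start=data_start + 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            break
        tokens = re.split(r"[,\s;]+", line.replace("+", " "))
        tokens = [t for t in tokens if t]
        try:
            vals = [float(t) for t in tokens]
        except ValueError:
            raise SpectrumParseError(f"{path}:{lineno}: non-numeric JCAMP data {line!r}") from None
        if mode == "xydata":
            if len(vals) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: XYDATA line with no Y values")
            x0, yvals = vals[0], vals[1:]
            # consecutive Y values advance X by one DELTAX step
            if "DELTAX" in header:
                dx = float(header["DELTAX"])
            else:
                first = float(header.get("FIRSTX", 0.0))
                last = float(header.get("LASTX", 0.0))
                npts = int(float(header.get("NPOINTS", len(yvals))))
                dx = (last - first) / max(npts - 1, 1)
            for k, yv in enumerate(yvals):
                # line-start abscissa is in file units (scaled by XFACTOR);
                # FIRSTX/LASTX/DELTAX are in physical units already
                xs.append(x0 * xfac + k * dx)
                ys.append(yv * yfac)
        else:  # xypoints: free-form (x, y) pairs
            if len(vals) % 2 != 0:
                raise SpectrumParseError(f"{path}:{lineno}: odd token count in XYPOINTS")
            for k in range(0, len(vals), 2):
                xs.append(vals[k] * xfac)
                ys.append(vals[k + 1] * yfac)

    meta["jcamp_title"] = header.get("TITLE", "")
    yunits = header.get("YUNITS", "").upper()
    x = np.asarray(xs)
    y = np.asarray(ys)
    if "TRANSMITTANCE" in yunits:
        # convert to absorbance; transmittance clipped away from 0 to keep it finite
        y = -np.log10(np.clip(y, 1e-6, 1.0))
        meta["converted_from"] = "transmittance"
    return x, y, meta


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a raw spectrum from a CSV or JCAMP-DX file.

    The result keeps the file's native sampling, sorted by ascending
    wavenumber with duplicate wavenumbers averaged. ``format`` defaults to
    ``"jcamp"`` for ``.jdx``/``.dx`` extensions and ``"csv"`` otherwise.
    """
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "csv"
    lines = path.read_text().splitlines()
    meta: dict[str, Any] = {"source": str(path)}
    if format == "jcamp":
        x, y, jmeta = _parse_jcamp(lines, str(path))
        meta.update(jmeta)
    elif format == "csv":
        x, y = _parse_two_column_text(lines, str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    if x.size < 2:
        raise DegenerateSpectrumError(f"{path}: fewer than 2 data points")
    x, y = _dedupe_sort(x, y)
    if x.size < 2:
        raise DegenerateSpectrumError(f"{path}: fewer than 2 distinct wavenumbers")
    return Spectrum(absorbance=y, wavenumbers_=x, meta=meta)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV (wavenumber, absorbance)."""
    path = Path(path)
    x = s.wavenumbers()
    with path.open("w") as fh:
        fh.write("wavenumber_cm-1,absorbance\n")
        for xi, yi in zip(x, s.absorbance):
            fh.write(f"{float(xi)!r},{float(yi)!r}\n")


def resample_to_grid(s: Spectrum, grid: WavenumberGrid = CANONICAL_GRID) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Grid points outside the native wavenumber range take the nearest
    endpoint value (constant extrapolation), which is also what
    ``np.interp`` does.
    """
    x = s.wavenumbers()
    if x.size < 2:
        raise DegenerateSpectrumError("resampling needs at least 2 points")
    y = np.interp(grid.wavenumbers(), x, s.absorbance)
    return Spectrum(absorbance=y, grid=grid, meta=dict(s.meta))


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Min-max scale the absorbance to [0, 1].

    Records the original min/max in ``meta`` so the scaling is invertible.
    A constant spectrum carries no shape information and raises
    :class:`DegenerateSpectrumError` rather than silently producing zeros.
    """
    lo = float(np.min(s.absorbance))
    hi = float(np.max(s.absorbance))
    if hi - lo <= 0.0:
        raise DegenerateSpectrumError("constant spectrum cannot be min-max normalized")
    y = (s.absorbance - lo) / (hi - lo)
    meta = dict(s.meta)
    meta.setdefault("normalization", {"min": lo, "max": hi})
    return Spectrum(absorbance=y, grid=s.grid, wavenumbers_=s.wavenumbers_, meta=meta)
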