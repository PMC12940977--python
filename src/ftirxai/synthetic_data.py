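"""Synthetic FTIR spectra with planted characteristic absorption bands.

Real FTIR functional-group datasets (NIST WebBook scale) are not
redistributable, so the pipeline is validated on synthetic spectra that
reproduce the statistical structure the analysis relies on: a molecule is a
set of functional groups, each group plants absorption bands inside its
literature characteristic wavenumber range(s), and the rendered spectrum
adds confounder bands, a smooth baseline and noise before per-spectrum
min-max normalization. Classes are balanced per target group, mirroring the
balanced 100-spectrum evaluation sets used for the S+/S- statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .spectra_io import CANONICAL_GRID, Spectrum, WavenumberGrid, normalize_spectrum

__all__ = [
    "DEFAULT_LIBRARY",
    "Band",
    "GroupBandLibrary",
    "SimulationConfig",
    "VirtualMolecule",
    "generate_dataset",
    "render_spectrum",
    "sample_molecule",
]


@dataclass(frozen=True)
class GroupBandLibrary:
    """Characteristic wavenumber intervals per functional group.

    Intervals are literature assignment ranges in cm^-1, all inside the
    canonical 650-3775 cm^-1 span.
    """

    entries: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for name, intervals in self.entries.items():
            if not intervals:
                raise ValueError(f"group {name!r} has no intervals")
            for lo, hi in intervals:
                if not (650.0 <= lo < hi <= 3775.0):
                    raise ValueError(f"group {name!r}: bad interval [{lo}, {hi}]")

    def __contains__(self, group: str) -> bool:
        return group in self.entries

    def __getitem__(self, group: str) -> list[tuple[float, float]]:
        return self.entries[group]

    def groups(self) -> list[str]:
        return sorted(self.entries)


#: Literature characteristic ranges for fourteen common functional groups.
DEFAULT_LIBRARY = GroupBandLibrary(
    entries={
        "alcohols": [(1000.0, 1300.0), (3200.0, 3650.0)],
        "aldehydes": [(1680.0, 1715.0), (2720.0, 2740.0), (2700.0, 2900.0)],
        "alkane": [(1340.0, 1395.0), (1430.0, 1480.0), (2850.0, 2990.0)],
        "alkene": [(685.0, 995.0), (1600.0, 1680.0), (3000.0, 3100.0)],
        "alkyne": [(2100.0, 2250.0), (3200.0, 3310.0)],
        "amides": [(1630.0, 1700.0), (3150.0, 3500.0)],
        "amines": [(3250.0, 3550.0)],
        "aromatics": [(680.0, 900.0), (1440.0, 1620.0), (3000.0, 3100.0)],
        "carboxylic acids": [(1000.0, 1300.0), (1680.0, 1725.0), (3200.0, 3500.0)],
        "esters": [(1000.0, 1300.0), (1715.0, 1730.0), (1735.0, 1765.0)],
        "ketones": [(1650.0, 1700.0), (1705.0, 1750.0)],
        "nitriles": [(2200.0, 2280.0)],
        "nitro": [(1300.0, 1390.0), (1490.0, 1570.0)],
        "phenols": [(3200.0, 3700.0)],
    }
)

#: Characteristic intervals wider than this are broad X-H stretch envelopes;
#: bands planted there get doubled widths.
_BROAD_INTERVAL_CM = 200.0


@dataclass(frozen=True)
class Band:
    center: float  # cm^-1
    width: float  # cm^-1 (Gaussian sigma / Lorentzian half-width)
    amplitude: float
    shape: Literal["gaussian", "lorentzian"] = "gaussian"


@dataclass
class VirtualMolecule:
    """A molecule reduced to its functional groups and absorption bands."""

    groups: set[str]
    bands: list[Band]
    labels: dict[str, int]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic binary-classification task.

    Defaults follow the evaluation design the analysis assumes: balanced
    classes (``positive_fraction=0.5``), 2-6 confounder bands so total
    intensity alone cannot separate the classes, Gaussian bands of width
    8-40 cm^-1, a smooth low-order polynomial baseline and mild i.i.d.
    noise.
    """

    seed: int = 0
    n_spectra: int = 100
    target_group: str = "nitriles"
    positive_fraction: float = 0.5
    confounder_bands: tuple[int, int] = (2, 6)
    other_group_prob: float = 0.15
    amplitude_range: tuple[float, float] = (0.3, 1.0)
    width_range: tuple[float, float] = (8.0, 40.0)
    baseline_amplitude: float = 0.15
    noise_sd: float = 0.01
    lorentzian_prob: float = 0.25
    hard_negatives: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lo, hi in (self.confounder_bands, self.amplitude_range, self.width_range):
            if hi < lo:
                raise ValueError("empty range in config")


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _in_any(x: float, intervals: Iterable[tuple[float, float]]) -> bool:
    return any(lo <= x <= hi for lo, hi in intervals)


def _too_close(band: Band, intervals: Iterable[tuple[float, float]]) -> bool:
    """True if the band leaks non-negligible tail energy into any interval.

    Negative molecules must keep the target ranges clean; the exclusion
    margin scales with band width and is wider for Lorentzians, whose
    tails decay only quadratically (4 sigma for Gaussians, 8 half-widths
    for Lorentzians).
    """
    margin = (4.0 if band.shape == "gaussian" else 8.0) * band.width
    return any(lo - margin <= band.center <= hi + margin for lo, hi in intervals)


def _draw_band(
    rng: np.random.Generator,
    interval: tuple[float, float],
    config: SimulationConfig,
) -> Band:
    lo, hi = interval
    center = rng.uniform(lo, hi)
    width = rng.uniform(*config.width_range)
    if hi - lo > _BROAD_INTERVAL_CM:
        width *= 2.0
    amplitude = rng.uniform(*config.amplitude_range)
    shape = "lorentzian" if rng.random() < config.lorentzian_prob else "gaussian"
    return Band(center=center, width=width, amplitude=amplitude, shape=shape)


def sample_molecule(
    library: GroupBandLibrary,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> VirtualMolecule:
    """Draw one virtual molecule for the task defined by ``config``.

    A positive draw (probability ``positive_fraction``) contains the target
    group, with one band planted in each of the group's characteristic
    intervals. Both classes may carry other library groups and 2-6
    confounder bands; for negative molecules no band — from other groups or
    confounders — may fall inside any target interval, so the target ranges
    are informative by construction. With ``hard_negatives`` confounders
    may instead sit just outside the target intervals (within 60 cm^-1).
    """
    if config.target_group not in library:
        raise KeyError(f"target group {config.target_group!r} not in library")
    target_intervals = library[config.target_group]
    positive = bool(rng.random() < config.positive_fraction)

    groups: set[str] = set()
    bands: list[Band] = []
    if positive:
        groups.add(config.target_group)
        for interval in target_intervals:
            bands.append(_draw_band(rng, interval, config))

    for other in library.groups():
        if other == config.target_group:
            continue
        if rng.random() >= config.other_group_prob:
            continue
        intervals = library[other]
        if not positive and any(
            _intervals_overlap(iv, tv) for iv in intervals for tv in target_intervals
        ):
            continue  # would force a band into a target range of a negative molecule
        groups.add(other)
        for interval in intervals:
            for _ in range(20):
                band = _draw_band(rng, interval, config)
                if positive or not _too_close(band, target_intervals):
                    bands.append(band)
                    break

    n_conf = int(rng.integers(config.confounder_bands[0], config.confounder_bands[1] + 1))
    span = (CANONICAL_GRID.start, CANONICAL_GRID.stop)
    for _ in range(n_conf):
        for _ in range(200):
            center = rng.uniform(*span)
            width = rng.uniform(*config.width_range)
            amplitude = rng.uniform(*config.amplitude_range)
            shape = "lorentzian" if rng.random() < config.lorentzian_prob else "gaussian"
            if not positive and config.hard_negatives:
                # pull the confounder toward (but not into) a target interval
                lo, hi = target_intervals[int(rng.integers(len(target_intervals)))]
                side = -1.0 if rng.random() < 0.5 else 1.0
                center = (lo if side < 0 else hi) + side * rng.uniform(5.0, 60.0)
                center = float(np.clip(center, *span))
                if _in_any(center, target_intervals):
                    continue
            band = Band(center, width, amplitude, shape)
            if positive or config.hard_negatives or not _too_close(band, target_intervals):
                bands.append(band)
                break

    labels = {g: 1 if g in groups else 0 for g in library.groups()}
    labels[config.target_group] = int(positive)
    return VirtualMolecule(groups=groups, bands=bands, labels=labels)


def band_profile(band: Band, x: np.ndarray) -> np.ndarray:
    """Evaluate one absorption band on wavenumbers ``x``."""
    if band.shape == "gaussian":
        return band.amplitude * np.exp(-((x - band.center) ** 2) / (2.0 * band.width**2))
    return band.amplitude * band.width**2 / ((x - band.center) ** 2 + band.width**2)


def render_spectrum(
    molecule: VirtualMolecule,
    grid: WavenumberGrid,
    baseline_amplitude: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> Spectrum:
    """Render a molecule to a normalized absorbance spectrum.

    absorbance = sum of band profiles + smooth quadratic baseline
    + i.i.d. Gaussian noise, then min-max normalized to [0, 1].
    """
    x = grid.wavenumbers()
    y = np.zeros_like(x)
    for band in molecule.bands:
        y += band_profile(band, x)
    # smooth baseline: random quadratic over the span, scaled to baseline_amplitude
    u = (x - x[0]) / (x[-1] - x[0])
    coeffs = rng.uniform(-1.0, 1.0, size=3)
    baseline = coeffs[0] + coeffs[1] * u + coeffs[2] * u**2
    if baseline_amplitude > 0:
        ptp = np.ptp(baseline)
        if ptp > 0:
            baseline = baseline / ptp * baseline_amplitude
        y = y + (baseline - baseline.min())
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    s = Spectrum(absorbance=y, grid=grid, meta={"labels": dict(molecule.labels),
                                                "groups": sorted(molecule.groups)})
    return normalize_spectrum(s)


def generate_dataset(
    library: GroupBandLibrary = DEFAULT_LIBRARY,
    config: SimulationConfig = SimulationConfig(),
    grid: WavenumberGrid = CANONICAL_GRID,
) -> list[tuple[Spectrum, int]]:
    """Generate ``config.n_spectra`` labeled spectra for the target group.

    The positive count is exactly ``round(n_spectra * positive_fraction)``;
    class assignment order is shuffled deterministically by the config seed,
    and one shared RNG stream makes the whole dataset reproducible.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_spectra
    n_pos = int(round(n * config.positive_fraction))
    flags = np.zeros(n, dtype=bool)
    flags[:n_pos] = True
    rng.shuffle(flags)
    out: list[tuple[Spectrum, int]] = []
    for i, want_positive in enumerate(flags):
        # force the class by rejection so counts are exact while all band
        # draws still come from the single shared stream
        for _ in range(10_000):
            mol = sample_molecule(library, config, rng)
            if (config.target_group in mol.groups) == want_positive:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to draw requested class")
        spec = render_spectrum(mol, grid, config.baseline_amplitude, config.noise_sd, rng)
        spec.meta["index"] = i
        spec.meta["label"] = int(want_positive)
        out.append((spec, int(want_positive)))
    return out
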