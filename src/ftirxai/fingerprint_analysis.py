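"""Aggregation of attributions into range sums, S+/S-, FA/FB/FC profiles,
fingerprint regions, and per-spectrum explanation artifacts.

Per-spectrum attributions are summarized two ways. Range sums add the
signed attribution values over the grid points inside a group's literature
characteristic interval(s); averaging those sums over the positive
(``S+``) and negative (``S-``) halves of a balanced test set gives the
per-group statistics. Pointwise, the positive-subset mean ``FA`` and the
sign-flipped negative-subset mean ``FB`` are combined into ``FC = FA + FB``,
whose large values mark the wavenumber regions the classifier actually
relies on; thresholding FC extracts those *fingerprint regions* as
intervals.

Interval membership is half-open, ``lo <= x < hi``, so adjacent literature
ranges never double-count a grid point; an interval reaching the end of the
grid also includes the final grid point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .expected_gradients import AttributionVector
from .spectra_io import CANONICAL_GRID, Spectrum, WavenumberGrid

__all__ = [
    "AggregateProfile",
    "FingerprintRegion",
    "GroupStatistics",
    "RangeSum",
    "aggregate_profiles",
    "error_report",
    "extract_fingerprint_regions",
    "group_statistics",
    "jaccard",
    "render_explanation",
    "sum_in_ranges",
]


@dataclass
class RangeSum:
    spectrum_id: str
    ranges: list[tuple[float, float]]
    value: float


@dataclass
class GroupStatistics:
    """Averaged characteristic-range attribution sums for one group.

    ``S_plus`` averages over spectra whose molecules contain the group,
    ``S_minus`` over those that do not.
    """

    group: str
    S_plus: float
    S_minus: float
    n_positive: int
    n_negative: int


@dataclass
class AggregateProfile:
    """Pointwise FA/FB/FC profiles with per-point standard deviations.

    FA is the mean attribution over the positive subset; FB the *negated*
    mean over the negative subset, so informative absence also shows as a
    positive peak; FC = FA + FB exactly. Standard deviations are computed
    per point within each subset (FB's on the sign-flipped values).
    """

    wavenumbers: np.ndarray
    FA: np.ndarray
    FB: np.ndarray
    FC: np.ndarray
    sd_FA: np.ndarray
    sd_FB: np.ndarray
    sd_FC: np.ndarray
    n_A: int
    n_B: int


@dataclass
class FingerprintRegion:
    intervals: list[tuple[float, float]]
    scores: list[float]


def _range_mask(
    x: np.ndarray, ranges: Sequence[tuple[float, float]], grid_stop: float
) -> np.ndarray:
    mask = np.zeros(x.size, dtype=bool)
    for lo, hi in ranges:
        if lo < x[0] - 1e-9 or hi > grid_stop + 1e-9:
            raise ValueError(f"range [{lo}, {hi}] outside grid span [{x[0]}, {grid_stop}]")
        m = (x >= lo) & (x < hi)
        if hi >= grid_stop:  # interval reaching the grid end keeps the last point
            m |= x == x[-1]
        mask |= m
    return mask


def sum_in_ranges(
    a: AttributionVector,
    ranges: Sequence[tuple[float, float]],
    grid: WavenumberGrid = CANONICAL_GRID,
) -> RangeSum:
    """Sum attribution values over grid points inside any of ``ranges``.

    Overlapping ranges count each grid point once.
    """
    x = grid.wavenumbers()
    if a.values.size != x.size:
        raise ValueError("attribution length does not match grid")
    mask = _range_mask(x, ranges, grid.stop)
    return RangeSum(
        spectrum_id=a.spectrum_id,
        ranges=[tuple(r) for r in ranges],
        value=float(a.values[mask].sum()),
    )


def group_statistics(
    attributions: Sequence[AttributionVector],
    labels: Sequence[int],
    ranges: Sequence[tuple[float, float]],
    group: str = "",
    grid: WavenumberGrid = CANONICAL_GRID,
) -> GroupStatistics:
    """S+ / S- over a labeled attribution set for one group's ranges."""
    if len(attributions) != len(labels):
        raise ValueError("attributions and labels must be aligned")
    sums = np.array([sum_in_ranges(a, ranges, grid).value for a in attributions])
    lab = np.asarray(labels, dtype=int)
    if not np.any(lab == 1):
        raise ValueError("no positive spectra: cannot compute S+")
    if not np.any(lab == 0):
        raise ValueError("no negative spectra: cannot compute S-")
    return GroupStatistics(
        group=group,
        S_plus=float(sums[lab == 1].mean()),
        S_minus=float(sums[lab == 0].mean()),
        n_positive=int((lab == 1).sum()),
        n_negative=int((lab == 0).sum()),
    )


def aggregate_profiles(
    attributions: Sequence[AttributionVector],
    labels: Sequence[int],
    grid: WavenumberGrid = CANONICAL_GRID,
) -> AggregateProfile:
    """Pointwise FA (positive mean), FB (negated negative mean), FC = FA + FB."""
    lab = np.asarray(labels, dtype=int)
    if len(attributions) != lab.size:
        raise ValueError("attributions and labels must be aligned")
    if not np.any(lab == 1):
        raise ValueError("no positive spectra: FA undefined")
    if not np.any(lab == 0):
        raise ValueError("no negative spectra: FB undefined")
    V = np.stack([a.values for a in attributions])
    A = V[lab == 1]
    B = -V[lab == 0]  # sign flip: informative absence becomes positive
    FA = A.mean(axis=0)
    FB = B.mean(axis=0)
    ddofA = 1 if A.shape[0] > 1 else 0
    ddofB = 1 if B.shape[0] > 1 else 0
    sd_FA = A.std(axis=0, ddof=ddofA)
    sd_FB = B.std(axis=0, ddof=ddofB)
    return AggregateProfile(
        wavenumbers=grid.wavenumbers(),
        FA=FA,
        FB=FB,
        FC=FA + FB,
        sd_FA=sd_FA,
        sd_FB=sd_FB,
        sd_FC=np.sqrt(sd_FA**2 + sd_FB**2),
        n_A=int(A.shape[0]),
        n_B=int(B.shape[0]),
    )


def extract_fingerprint_regions(
    profile: AggregateProfile,
    threshold_fraction: float = 0.25,
    min_width: float = 15.0,
    window: tuple[float, float] | None = None,
) -> FingerprintRegion:
    """Intervals where FC stays above a fraction of its maximum.

    Maximal runs of grid points with ``FC >= threshold_fraction * max(FC)``
    are merged when separated by gaps narrower than ``min_width`` cm^-1 and
    discarded when themselves narrower than ``min_width``. ``window``
    optionally restricts the analysis (and the maximum) to a wavenumber
    sub-range. Each interval's score is its mean FC. If FC has no positive
    values the result is empty.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    x = profile.wavenumbers
    fc = profile.FC
    sel = np.ones(x.size, dtype=bool)
    if window is not None:
        sel = (x >= window[0]) & (x <= window[1])
    fmax = fc[sel].max() if np.any(sel) else 0.0
    if fmax <= 0.0:
        import warnings

        warnings.warn("FC has no positive values; no fingerprint regions", stacklevel=2)
        return FingerprintRegion(intervals=[], scores=[])
    above = sel & (fc >= threshold_fraction * fmax)
    # maximal runs of True
    runs: list[tuple[int, int]] = []
    i = 0
    n = x.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by gaps narrower than min_width
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and x[run[0]] - x[merged[-1][1]] < min_width:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    intervals: list[tuple[float, float]] = []
    scores: list[float] = []
    for i0, i1 in merged:
        if x[i1] - x[i0] < min_width:
            continue
        intervals.append((float(x[i0]), float(x[i1])))
        scores.append(float(fc[i0:i1 + 1].mean()))
    return FingerprintRegion(intervals=intervals, scores=scores)


def jaccard(a: tuple[float, float], b: Sequence[tuple[float, float]]) -> float:
    """Jaccard overlap |a ∩ B| / |a ∪ B| between one interval and a set."""
    lo, hi = a
    inter = sum(max(0.0, min(hi, h) - max(lo, l)) for l, h in b)
    blen = sum(h - l for l, h in b)
    union = (hi - lo) + blen - inter
    return inter / union if union > 0 else 0.0


def _diverging_colors(values: np.ndarray) -> tuple[np.ndarray, float]:
    vmax = float(np.max(np.abs(values)))
    return values, (vmax if vmax > 0 else 1.0)


def render_explanation(
    s: Spectrum,
    a: AttributionVector,
    out_path: str | Path,
) -> Path:
    """Plot the spectrum colored by attribution and write a sidecar table.

    Colors follow a symmetric diverging map centered at zero: red for
    positive attribution, blue for negative, gray near zero, with limits
    at +/- max|a|. The sidecar CSV (same stem, ``.csv``) holds columns
    wavenumber, absorbance, shap_value and round-trips the attribution
    exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if s.n_points != a.values.size:
        raise ValueError("spectrum and attribution lengths differ")
    out_path = Path(out_path)
    x = s.wavenumbers()
    vals, vmax = _diverging_colors(a.values)
    cmap = LinearSegmentedColormap.from_list(
        "shap_bgr", [(0.0, 0.2, 0.9), (0.6, 0.6, 0.6), (0.9, 0.1, 0.1)]
    )
    fig, ax = plt.subplots(figsize=(9, 3.2))
    sc = ax.scatter(x, s.absorbance, c=vals, cmap=cmap, vmin=-vmax, vmax=vmax, s=4)
    ax.plot(x, s.absorbance, color="0.85", lw=0.5, zorder=0)
    ax.set_xlabel("wavenumber [cm$^{-1}$]")
    ax.set_ylabel("normalized absorbance")
    if a.target_group:
        ax.set_title(f"attributions for {a.target_group!r} classifier")
    fig.colorbar(sc, ax=ax, label="SHAP value")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    sidecar = out_path.with_suffix(".csv")
    with sidecar.open("w") as fh:
        fh.write("wavenumber_cm-1,absorbance,shap_value\n")
        for xi, yi, vi in zip(x, s.absorbance, a.values):
            fh.write(f"{float(xi)!r},{float(yi)!r},{float(vi)!r}\n")
    return out_path


def _sign_runs(values: np.ndarray, x: np.ndarray, sign: int) -> list[dict]:
    """Maximal runs of strictly positive (sign=+1) / negative (-1) values."""
    want = values > 0 if sign > 0 else values < 0
    runs: list[dict] = []
    i, n = 0, values.size
    while i < n:
        if want[i]:
            j = i
            while j + 1 < n and want[j + 1]:
                j += 1
            seg = values[i:j + 1]
            runs.append(
                {
                    "lo": float(x[i]),
                    "hi": float(x[j]),
                    "mean_attribution": float(seg.mean()),
                    "sum_attribution": float(seg.sum()),
                }
            )
            i = j + 1
        else:
            i += 1
    return runs


def error_report(
    model,
    s: Spectrum,
    a: AttributionVector,
    true_label: int,
    target_ranges: Sequence[tuple[float, float]] = (),
    top_k: int = 3,
    grid: WavenumberGrid = CANONICAL_GRID,
) -> dict:
    """Structured per-spectrum explanation, most useful on misclassifications.

    Contains the decision, probability and true label; the top-k disjoint
    positive- and negative-attribution intervals (maximal constant-sign
    runs ranked by |mean attribution|); and the characteristic-range sum,
    reported regardless of the decision's correctness.
    """
    from .cnn_kan_model import predict

    prob, decision = predict(model, s)
    x = grid.wavenumbers()
    pos = sorted(_sign_runs(a.values, x, +1), key=lambda r: -abs(r["mean_attribution"]))
    neg = sorted(_sign_runs(a.values, x, -1), key=lambda r: -abs(r["mean_attribution"]))
    if decision == true_label:
        verdict = "correct"
    elif decision == 1:
        verdict = "false positive"
    else:
        verdict = "false negative"
    report = {
        "spectrum_id": a.spectrum_id or str(s.meta.get("index", "")),
        "target_group": a.target_group,
        "probability": prob,
        "decision": decision,
        "true_label": int(true_label),
        "verdict": verdict,
        "top_positive_intervals": pos[:top_k],
        "top_negative_intervals": neg[:top_k],
    }
    if target_ranges:
        report["characteristic_range_sum"] = sum_in_ranges(a, target_ranges, grid).value
        report["characteristic_ranges"] = [list(r) for r in target_ranges]
    return report


def write_profile_csv(profile: AggregateProfile, path: str | Path) -> None:
    """Columns: wavenumber, FA, FB, FC, sd_FA, sd_FB, sd_FC."""
    import pandas as pd

    pd.DataFrame(
        {
            "wavenumber_cm-1": profile.wavenumbers,
            "FA": profile.FA,
            "FB": profile.FB,
            "FC": profile.FC,
            "sd_FA": profile.sd_FA,
            "sd_FB": profile.sd_FB,
            "sd_FC": profile.sd_FC,
        }
    ).to_csv(path, index=False)
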