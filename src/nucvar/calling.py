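"""Nucleosome calling from smoothed tiling signal.

The caller resamples irregular probe signal onto a uniform grid,
smooths it with a Savitzky-Golay filter, and reads nucleosome geometry
off the derivatives: zeros of the first derivative mark nucleosome
centers, zeros of the second derivative mark the borders of nucleosomal
peaks. Each candidate peak is then least-squares fitted to a parabola
— the simplest analytical peak shape — whose vertex supplies the
refined center and height; the peak width is the distance between the
two second-derivative borders. Calls from the variant and bulk-histone
channels are merged into one list of positioned nucleosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .io import ProbeTrack


@dataclass
class CallerParams:
    """Tunables of the peak caller.

    grid_step
        Resampling step in bp (default 10).
    sg_window, sg_order
        Savitzky-Golay window (grid points, odd) and polynomial order;
        defaults 15 points x 10 bp ~ one nucleosome footprint, order 3.
    min_height
        Minimum peak prominence above the chromosome-wide median of the
        smoothed signal. ``None`` (default) means 0.5x the robust SD
        (1.4826 x MAD) of the smoothed signal, floored at 3x the SD of
        Savitzky-Golay-filtered noise (probe noise estimated from first
        differences of the raw signal). The floor is what rejects pure
        noise bumps on channels that are mostly baseline, where the
        signal MAD itself collapses to the noise level.
    min_width, max_width
        Accepted fitted-width range in bp.
    merge_distance
        Centers from different channels closer than this are one
        nucleosome (default 74 bp, half a footprint).
    """

    grid_step: int = 10
    sg_window: int = 15
    sg_order: int = 3
    min_height: float | None = None
    min_width: float = 80.0
    max_width: float = 300.0
    merge_distance: float = 74.0

    def __post_init__(self) -> None:
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if not self.min_width < self.max_width:
            raise ValueError("min_width must be below max_width")


@dataclass
class NucleosomeCall:
    """A positioned nucleosome."""

    chromosome: str
    center: float  # parabola vertex, bp
    width: float  # distance between the two support borders, bp
    height: float  # vertex signal value
    support: tuple[float, float]  # [left border, right border], bp
    channel: str  # 'variant', 'histone' or 'both'

    def __post_init__(self) -> None:
        if not self.support[0] <= self.center <= self.support[1]:
            raise ValueError("support must contain the center")
        if not self.width > 0 or not np.isfinite(self.height):
            raise ValueError("invalid call geometry")


def resample_to_grid(track: ProbeTrack, grid_step: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of probe signal onto a regular grid.

    The grid starts at the first probe and never extrapolates beyond
    the last one. Returns (grid positions, values).
    """
    if len(track) < 2:
        raise ValueError("need at least 2 probes to resample")
    grid = np.arange(track.positions[0], track.positions[-1] + 1, grid_step)
    values = np.interp(grid, track.positions, track.values)
    return grid.astype(float), values


def smooth_and_differentiate(signal: np.ndarray, sg_window: int, sg_order: int,
                             grid_step: float = 1.0
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothing plus first and second derivatives per bp.

    The filter fits a local polynomial by least squares, which preserves
    peak areas, extremum positions and widths; derivatives come from the
    same local fits, scaled to per-bp units via ``grid_step``.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < sg_window:
        raise ValueError("signal shorter than the smoothing window")
    smoothed = savgol_filter(signal, sg_window, sg_order, deriv=0)
    d1 = savgol_filter(signal, sg_window, sg_order, deriv=1, delta=grid_step)
    d2 = savgol_filter(signal, sg_window, sg_order, deriv=2, delta=grid_step)
    return smoothed, d1, d2


def _zero_crossings_down(d: np.ndarray) -> list[tuple[int, float]]:
    """Indices and interpolated sub-grid offsets where d crosses + -> -.

    A run of exact zeros flanked by + on the left and - on the right is
    a plateau; its midpoint is the crossing.
    """
    out = []
    sign = np.sign(d)
    nz = np.flatnonzero(sign != 0)
    if len(nz) < 2:
        return out
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] > 0 and sign[b] < 0:
            if b == a + 1:
                frac = d[a] / (d[a] - d[b])
                out.append((a, float(frac)))
            else:  # plateau of exact zeros in (a, b)
                mid = (a + 1 + b - 1) / 2.0
                out.append((int(np.floor(mid)), float(mid - np.floor(mid))))
    return out


def _zero_crossings_any(d: np.ndarray) -> np.ndarray:
    """Fractional grid indices of all sign changes of d."""
    sign = np.sign(d)
    nz = np.flatnonzero(sign != 0)
    pts = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] != sign[b]:
            if b == a + 1:
                pts.append(a + d[a] / (d[a] - d[b]))
            else:
                pts.append((a + b) / 2.0)
    return np.asarray(pts)


def detect_peaks(grid: np.ndarray, smoothed: np.ndarray, d1: np.ndarray,
                 d2: np.ndarray) -> list[dict]:
    """Candidate peaks: d1 +->- crossings, supported by flanking d2 zeros.

    Returns dicts with keys center (bp), support (bp pair) and the
    integer grid slice covering the support. Candidates lacking a d2
    border on either side are discarded as edge artifacts.
    """
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    borders = _zero_crossings_any(d2)
    candidates = []
    for idx, frac in _zero_crossings_down(d1):
        center_gi = idx + frac
        left = borders[borders < center_gi]
        right = borders[borders > center_gi]
        if len(left) == 0 or len(right) == 0:
            continue
        li, ri = left[-1], right[0]
        i0 = int(np.floor(li))
        i1 = int(np.ceil(ri)) + 1
        candidates.append({
            "center": grid[0] + center_gi * step,
            "support": (grid[0] + li * step, grid[0] + ri * step),
            "slice": (i0, i1),
        })
    return candidates


def fit_parabola(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares fit of y = a*(x - c)^2 + h; returns (c, h, a, rms).

    Non-concave fits (a >= 0) signal a rejected candidate and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("parabola fit needs at least 3 points")
    xm = x.mean()  # center for conditioning
    X = np.column_stack([(x - xm) ** 2, x - xm, np.ones_like(x)])
    (a, b, c0), *_ = np.linalg.lstsq(X, y, rcond=None)
    if a >= 0:
        raise ValueError("non-concave parabola fit")
    vertex = xm - b / (2 * a)
    height = c0 - b * b / (4 * a)
    resid = y - (a * (x - vertex) ** 2 + height)
    return float(vertex), float(height), float(a), float(np.sqrt(np.mean(resid ** 2)))


def _filtered_noise_sd(signal: np.ndarray, params: CallerParams) -> float:
    """SD of SG-filtered probe noise.

    Probe noise SD is estimated robustly from first differences of the
    raw grid signal (slow signal components contribute little there);
    the smoothing attenuates its variance by the sum of squared filter
    coefficients.
    """
    from scipy.signal import savgol_coeffs

    diffs = np.diff(signal)
    probe_sd = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2)
    gain = float(np.sum(savgol_coeffs(params.sg_window, params.sg_order) ** 2))
    return probe_sd * np.sqrt(gain)


def call_nucleosomes(track: ProbeTrack, params: CallerParams | None = None,
                     channel: str = "histone") -> list[NucleosomeCall]:
    """Full per-chromosome caller: resample, smooth, detect, fit, filter."""
    params = params or CallerParams()
    grid, signal = resample_to_grid(track, params.grid_step)
    smoothed, d1, d2 = smooth_and_differentiate(
        signal, params.sg_window, params.sg_order, grid_step=params.grid_step)

    baseline = float(np.median(smoothed))
    if params.min_height is None:
        mad = float(np.median(np.abs(smoothed - baseline)))
        min_height = max(0.5 * 1.4826 * mad,
                         3.0 * _filtered_noise_sd(signal, params))
    else:
        min_height = params.min_height

    calls = []
    for cand in detect_peaks(grid, smoothed, d1, d2):
        i0, i1 = cand["slice"]
        try:
            vertex, height, _a, _rms = fit_parabola(grid[i0:i1], smoothed[i0:i1])
        except ValueError:
            continue
        left, right = cand["support"]
        if not left <= vertex <= right:
            vertex = cand["center"]  # fit drifted outside support; keep d1 zero
            height = float(np.interp(vertex, grid, smoothed))
        width = right - left
        if height - baseline < min_height:
            continue
        if not params.min_width <= width <= params.max_width:
            continue
        calls.append(NucleosomeCall(
            chromosome=track.chromosome, center=vertex, width=width,
            height=height, support=(left, right), channel=channel))
    calls.sort(key=lambda c: c.center)
    return calls


def merge_calls(calls_variant: list[NucleosomeCall],
                calls_histone: list[NucleosomeCall],
                merge_distance: float = 74.0) -> list[NucleosomeCall]:
    """Union of the two channel lists with cross-channel deduplication.

    Each variant-channel call whose nearest histone-channel center lies
    within ``merge_distance`` is merged into that histone call (histone
    geometry kept, provenance recorded as 'both'); ties go to the
    leftmost histone call. Remaining variant calls pass through.
    """
    if not calls_histone:
        return sorted(calls_variant, key=lambda c: c.center)
    h_centers = np.array([c.center for c in calls_histone])
    absorbed = [False] * len(calls_histone)
    out_variant = []
    for vc in calls_variant:
        j = int(np.searchsorted(h_centers, vc.center))
        best, bestd = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(h_centers):
                d = abs(h_centers[k] - vc.center)
                if d < bestd - 1e-12:  # strict: ties keep the leftmost
                    best, bestd = k, d
        if best is not None and bestd <= merge_distance:
            absorbed[best] = True
        else:
            out_variant.append(vc)
    merged = [replace(c, channel="both") if absorbed[i] else c
              for i, c in enumerate(calls_histone)]
    merged.extend(out_variant)
    merged.sort(key=lambda c: c.center)
    return merged
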