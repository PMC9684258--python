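"""Global field power and GFP-peak map extraction.

GFP at a time instant is the population standard deviation (divisor ``N``)
of the potentials across all electrodes -- a reference-free measure of
field strength. Moments of maximal GFP are moments of highest topographic
stability, so the scalp maps at GFP peaks are the observations fed to
microstate clustering and backfitting.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording


@dataclass
class GFPSeries:
    """Per-sample GFP values (microvolts) with their sampling rate."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")


@dataclass
class PeakMaps:
    """Scalp maps extracted at GFP peaks: ``maps`` is peaks x channels."""

    indices: np.ndarray
    maps: np.ndarray = field(repr=False)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.maps = np.asarray(self.maps, dtype=float)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.maps.shape[0] != self.indices.size:
            raise ValueError("one map per peak index required")

    @property
    def n_peaks(self) -> int:
        return self.indices.size


def global_field_power(rec: EEGRecording) -> GFPSeries:
    """GFP of an average-referenced recording.

    Computed as the per-sample SD across channels with divisor ``N``.
    Average-referencing first makes the result invariant to any common
    offset added before re-referencing.
    """
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(data**2, axis=0))
    return GFPSeries(values=values, fs=rec.fs)


def _strict_local_maxima(v: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau peak is its first sample.

    Endpoints are never peaks. Implemented by compressing runs of equal
    values, finding interior maxima of the compressed series, and mapping
    back to the first sample of each run.
    """
    n = v.size
    if n < 3:
        return np.empty(0, dtype=int)
    keep = np.empty(n, dtype=bool)
    keep[0] = True
    np.not_equal(v[1:], v[:-1], out=keep[1:])
    cv = v[keep]
    ci = np.flatnonzero(keep)
    if cv.size < 3:
        return np.empty(0, dtype=int)
    interior = np.flatnonzero((cv[1:-1] > cv[:-2]) & (cv[1:-1] > cv[2:])) + 1
    return ci[interior]


def _thin_peaks(idx: np.ndarray, heights: np.ndarray, min_sep: int) -> np.ndarray:
    """Greedy thinning: accept peaks tallest-first, reject any within min_sep."""
    if min_sep <= 1 or idx.size <= 1:
        return idx
    # tallest first; earlier index wins ties (stable sort on -height)
    order = np.argsort(-heights, kind="stable")
    accepted: list[int] = []  # kept sorted by position
    for j in order:
        pos = int(idx[j])
        i = bisect.bisect_left(accepted, pos)
        if i > 0 and pos - accepted[i - 1] < min_sep:
            continue
        if i < len(accepted) and accepted[i] - pos < min_sep:
            continue
        accepted.insert(i, pos)
    return np.asarray(accepted, dtype=int)


def find_gfp_peaks(
    gfp: GFPSeries,
    min_separation_ms: float = 10.0,
    smoothing_ms: float = 0.0,
) -> np.ndarray:
    """Find GFP peak sample indices.

    Peaks are strict local maxima of the (optionally moving-average
    smoothed) GFP series, thinned so surviving peaks are at least
    ``min_separation_ms`` apart, keeping the larger of two close peaks.
    Series endpoints are never peaks. The defaults (10 ms separation, no
    smoothing) are package conventions.
    """
    v = gfp.values
    if v.size < 3:
        return np.empty(0, dtype=int)
    if smoothing_ms > 0:
        w = max(1, int(round(smoothing_ms * gfp.fs / 1000.0)))
        if w > 1:
            kernel = np.ones(w) / w
            v = np.convolve(v, kernel, mode="same")
    peaks = _strict_local_maxima(v)
    min_sep = int(round(min_separation_ms * gfp.fs / 1000.0))
    return _thin_peaks(peaks, v[peaks], min_sep)


def extract_peak_maps(rec: EEGRecording, peaks: np.ndarray, source_id: str | None = None) -> PeakMaps:
    """Copy the average-referenced scalp maps at the given peak instants."""
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size and (peaks.min() < 0 or peaks.max() >= rec.n_samples):
        raise IndexError(
            f"peak index out of range [0, {rec.n_samples}): "
            f"{peaks[(peaks < 0) | (peaks >= rec.n_samples)][:5]}"
        )
    maps = rec.data[:, peaks].T.copy()
    if maps.size:
        maps -= maps.mean(axis=1, keepdims=True)
    return PeakMaps(indices=peaks, maps=maps,
                    source_id=source_id if source_id is not None else rec.subject_id)
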