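"""Backfitting of global templates and microstate metric extraction.

Backfitting reduces a recording to a sequence of microstates: at every
GFP peak the winning template is the one with the highest absolute
spatial correlation to the instantaneous map (winner-take-all), and each
sample between peaks inherits the label of its nearest peak (interval
boundaries at the midpoints between consecutive peaks, edges extended to
the recording bounds). Consecutive same-label intervals merge into
*segments*, from which four metrics are computed per template:

* mean duration (ms) -- average segment length;
* occurrence (Hz) -- segments per analyzed second;
* coverage (%) -- share of analyzed time;
* directional predominance (percentage points) -- for an ordered template
  pair (X, Y), ``100 * (P(X->Y) - P(Y->X))`` with row-normalized
  transition probabilities over consecutive distinct segments; positive
  means net flow from X to Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .clustering import TemplateSet
from .io import EEGRecording


@dataclass
class Segment:
    label: str
    start: float  # sample units (fractional boundaries from the midpoint rule)
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class MicrostateSequence:
    """Winner-take-all labels at GFP peaks plus derived segments."""

    peak_indices: np.ndarray
    peak_labels: tuple[str, ...]
    peak_abscorr: np.ndarray
    segments: list[Segment]
    labels: tuple[str, ...]          # template label vocabulary
    fs: float
    n_samples: int
    ties: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def analyzed_seconds(self) -> float:
        return self.n_samples / self.fs

    def segment_labels(self) -> list[str]:
        return [s.label for s in self.segments]


def backfit(
    rec: EEGRecording,
    global_templates: TemplateSet,
    peaks: np.ndarray,
    tie_tol: float = 1e-12,
) -> MicrostateSequence:
    """Assign each GFP peak (and its surrounding interval) to a template.

    Raises
    ------
    ValueError
        If the montages differ or no peaks are supplied.
    """
    if global_templates.montage.names != rec.montage.names:
        raise ValueError("recording montage does not match template montage")
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("backfitting needs at least one GFP peak")
    maps = rec.data[:, peaks].T
    maps = maps - maps.mean(axis=1, keepdims=True)
    t = global_templates.templates
    tc = t - t.mean(axis=1, keepdims=True)
    tn = tc / np.linalg.norm(tc, axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    corr = np.abs((maps / norms) @ tn.T)           # peaks x k
    winners = np.argmax(corr, axis=1)               # ties -> lower index
    best = corr[np.arange(len(peaks)), winners]
    sorted_corr = np.sort(corr, axis=1)
    ties = np.flatnonzero(
        (corr.shape[1] > 1)
        & (sorted_corr[:, -1] - sorted_corr[:, -2] <= tie_tol)
    )
    peak_labels = tuple(global_templates.labels[w] for w in winners)

    # midpoint rule: interval j spans [(p_{j-1}+p_j)/2, (p_j+p_{j+1})/2)
    bounds = np.empty(peaks.size + 1)
    bounds[0] = 0.0
    bounds[-1] = rec.n_samples
    bounds[1:-1] = (peaks[:-1] + peaks[1:]) / 2.0
    segments: list[Segment] = []
    for lab, b0, b1 in zip(peak_labels, bounds[:-1], bounds[1:]):
        if segments and segments[-1].label == lab:
            segments[-1].end = b1
        else:
            segments.append(Segment(label=lab, start=float(b0), end=float(b1)))
    return MicrostateSequence(
        peak_indices=peaks,
        peak_labels=peak_labels,
        peak_abscorr=best,
        segments=segments,
        labels=global_templates.labels,
        fs=rec.fs,
        n_samples=rec.n_samples,
        ties=ties,
    )


def compute_metrics(seq: MicrostateSequence) -> pd.DataFrame:
    """Per-template mean duration (ms), occurrence (Hz) and coverage (%).

    Templates with no segments get NaN duration, occurrence 0, coverage 0.
    """
    if not seq.segments:
        raise ValueError("sequence has no segments")
    seconds = seq.analyzed_seconds
    total = float(sum(s.length for s in seq.segments))
    rows = []
    for lab in seq.labels:
        lengths = np.array([s.length for s in seq.segments if s.label == lab])
        if lengths.size:
            duration_ms = float(lengths.mean() / seq.fs * 1000.0)
            occurrence = lengths.size / seconds
            coverage = 100.0 * float(lengths.sum()) / total
        else:
            duration_ms, occurrence, coverage = float("nan"), 0.0, 0.0
        rows.append({
            "template": lab,
            "duration_ms": duration_ms,
            "occurrence_hz": occurrence,
            "coverage_pct": coverage,
        })
    return pd.DataFrame(rows)


def transition_stats(
    seq: MicrostateSequence,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-order transition probabilities and directional predominance.

    Transitions are counted between consecutive distinct segments and
    row-normalized (no self-transitions by construction). Directional
    predominance for the ordered pair (X, Y) is
    ``dp = 100 * (P(X->Y) - P(Y->X))`` in percentage points; rows with no
    outgoing transitions leave P -- and any dp involving them -- as NaN.

    Returns ``(transition_probabilities, dp_table)`` where the dp table
    has one row per unordered template pair {X, Y} listed as X->Y with
    X < Y alphabetically.
    """
    if len(seq.segments) < 2:
        raise ValueError("transition statistics need at least 2 segments")
    labels = seq.labels
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k))
    seg_labels = seq.segment_labels()
    for a, b in zip(seg_labels[:-1], seg_labels[1:]):
        counts[index[a], index[b]] += 1
    out = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / out[:, None]
    probs[out == 0] = np.nan
    prob_df = pd.DataFrame(probs, index=list(labels), columns=list(labels))

    rows = []
    for x, y in combinations(labels, 2):
        p_xy = probs[index[x], index[y]]
        p_yx = probs[index[y], index[x]]
        dp = 100.0 * (p_xy - p_yx)
        rows.append({"pair": f"{x}->{y}", "p_xy": p_xy, "p_yx": p_yx,
                     "dp_pct": dp})
    return prob_df, pd.DataFrame(rows)


def metrics_table(
    sequences: dict[tuple[str, str, str], MicrostateSequence],
) -> pd.DataFrame:
    """Tidy per-subject metric table from backfitted sequences.

    ``sequences`` maps ``(subject, condition, side)`` to a sequence. The
    result has columns subject, condition, side, target (template or
    ordered pair), metric, value -- the layout the group statistics
    consume.
    """
    records = []
    for (subject, condition, side), seq in sequences.items():
        met = compute_metrics(seq)
        for _, row in met.iterrows():
            for metric in ("duration_ms", "occurrence_hz", "coverage_pct"):
                records.append({
                    "subject": subject, "condition": condition, "side": side,
                    "target": row["template"], "metric": metric,
                    "value": row[metric],
                })
        _, dp = transition_stats(seq)
        for _, row in dp.iterrows():
            records.append({
                "subject": subject, "condition": condition, "side": side,
                "target": row["pair"], "metric": "dp_pct",
                "value": row["dp_pct"],
            })
    return pd.DataFrame(records)
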