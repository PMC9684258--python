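"""Synthetic resting-state EEG with planted microstate structure.

The generator emulates the statistical skeleton that microstate analysis
assumes: at any moment the scalp field is one of ``k`` fixed unit-GFP
topographies, up to an arbitrary sign and additive spatial noise, and the
active topography switches on a 40-100 ms time scale following a
first-order chain with no self-transitions.

Concretely, a recording is built as a semi-Markov chain of *runs*:

* run labels follow a user-supplied row-stochastic transition matrix with
  zero diagonal;
* run lengths are geometric (memoryless) with a per-template mean in
  milliseconds; a fixed-length option exists for hand-checkable fixtures;
* each run carries a random sign (+1/-1 with probability 1/2), mimicking
  the polarity irrelevance of real microstates;
* within a run the field amplitude follows a rectified 10 Hz sinusoid
  anchored at the run start (peak amplitude 10 uV), the alpha-dominant
  eyes-closed regime, so every run opens on a well-defined GFP peak;
* spatially white Gaussian noise, scaled relative to the unit template
  norm and modulated by the same amplitude envelope, is added before
  average-referencing.

Every simulation returns the :class:`GroundTruth` (per-sample labels, true
templates, realized durations / occurrences / coverages / transition
counts) so each downstream stage has a recovery test against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording
from .maps import canonical_templates, polarity_corr, unit_gfp
from .montage import Montage, standard_1020_19

#: Peak amplitude of the rectified-alpha envelope, microvolts.
AMPLITUDE_UV = 10.0
#: Frequency of the rectified amplitude modulation, Hz (peaks every 50 ms).
MODULATION_HZ = 10.0


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    ``mean_duration_ms`` may be a scalar or a per-template sequence; the
    default 70 ms sits mid-range of the 40-100 ms band typical of resting
    microstates. ``transition`` defaults to uniform off-diagonal (no
    directional asymmetry). ``noise_sigma`` is the spatial noise SD
    relative to the unit-GFP template norm; 0.3 is the package's standard
    test condition.
    """

    montage: Montage = field(default_factory=standard_1020_19)
    fs: float = 256.0
    duration: float = 600.0
    k_true: int = 4
    templates: np.ndarray | None = None
    mean_duration_ms: float | np.ndarray = 70.0
    transition: np.ndarray | None = None
    noise_sigma: float = 0.3
    duration_model: str = "geometric"  # or "fixed"
    seed: int = 0

    def resolved_transition(self) -> np.ndarray:
        k = self.k_true
        if self.transition is None:
            if k < 2:
                raise ValueError("k_true must be >= 2")
            t = np.full((k, k), 1.0 / (k - 1))
            np.fill_diagonal(t, 0.0)
            return t
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (k, k):
            raise ValueError(f"transition must be {k}x{k}")
        if np.any(np.abs(np.diag(t)) > 0):
            raise ValueError("transition diagonal must be zero (no self-transitions)")
        if np.any(t < 0):
            raise ValueError("transition probabilities must be non-negative")
        rows = t.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        return t

    def resolved_durations(self) -> np.ndarray:
        d = np.broadcast_to(np.asarray(self.mean_duration_ms, dtype=float),
                            (self.k_true,)).copy()
        if np.any(d <= 0):
            raise ValueError("mean_duration_ms must be positive")
        return d


@dataclass
class GroundTruth:
    """Planted truth of a simulation, for recovery tests."""

    labels: np.ndarray               # per-sample template index
    templates: np.ndarray            # k x channels, unit GFP
    run_starts: np.ndarray           # sample index of each run start
    run_labels: np.ndarray
    run_signs: np.ndarray
    fs: float

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    def run_lengths_ms(self) -> np.ndarray:
        bounds = np.append(self.run_starts, self.n_samples)
        return np.diff(bounds) / self.fs * 1000.0

    def mean_duration_ms(self) -> np.ndarray:
        """Realized mean run length per template, ms (NaN if absent)."""
        lengths = self.run_lengths_ms()
        out = np.full(self.k, np.nan)
        for j in range(self.k):
            sel = self.run_labels == j
            if sel.any():
                out[j] = lengths[sel].mean()
        return out

    def occurrence_hz(self) -> np.ndarray:
        seconds = self.n_samples / self.fs
        return np.bincount(self.run_labels, minlength=self.k) / seconds

    def coverage(self) -> np.ndarray:
        """Fraction of samples per template; sums to 1."""
        return np.bincount(self.labels, minlength=self.k) / self.n_samples

    def transition_counts(self) -> np.ndarray:
        counts = np.zeros((self.k, self.k))
        np.add.at(counts, (self.run_labels[:-1], self.run_labels[1:]), 1)
        return counts


def make_dipolar_templates(montage: Montage, k: int, seed: int = 0) -> np.ndarray:
    """Generate ``k`` well-separated unit-GFP average-referenced maps.

    The first four are the canonical A-D shapes (two diagonal gradients,
    one anterior-posterior gradient, one fronto-central pattern); extra
    templates are seeded random smooth fields accepted only if their
    absolute spatial correlation with every previous template stays
    below 0.8.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 12:
        raise ValueError("k must be <= 12")
    base = canonical_templates(montage)
    templates = [base[i] for i in range(min(k, 4))]
    if k > 4:
        rng = np.random.default_rng(seed)
        x, y = montage.positions.T
        basis = np.stack([x, y, x * y, x**2 - y**2, x**2 + y**2,
                          x * (x**2 + y**2), y * (x**2 + y**2)])
        attempts = 0
        while len(templates) < k:
            attempts += 1
            if attempts > 2000:
                raise ValueError(
                    f"cannot place {k} templates with pairwise |corr| < 0.8 "
                    f"on this montage"
                )
            cand = unit_gfp(rng.standard_normal(basis.shape[0]) @ basis)
            if all(polarity_corr(cand, t)[1] < 0.8 for t in templates):
                templates.append(cand)
    return np.stack(templates)


def simulate(config: SimulationConfig) -> tuple[EEGRecording, GroundTruth]:
    """Generate one synthetic recording plus its ground truth.

    Deterministic given an identical config and seed.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_true
    trans = config.resolved_transition()
    if np.any(trans.sum(axis=1) == 0):
        raise ValueError("transition matrix has an absorbing state")
    mean_samples = config.resolved_durations() * config.fs / 1000.0
    if np.any(mean_samples < 1.0):
        raise ValueError("mean_duration_ms below one sample at this rate")
    n = int(round(config.duration * config.fs))
    if n < 1:
        raise ValueError("duration too short")

    if config.templates is not None:
        templates = np.asarray(config.templates, dtype=float)
        if templates.shape != (k, config.montage.n_channels):
            raise ValueError("templates must be k_true x n_channels")
        templates = np.stack([unit_gfp(t) for t in templates])
    else:
        templates = make_dipolar_templates(config.montage, k, seed=config.seed)

    cum = np.cumsum(trans, axis=1)

    run_labels: list[int] = []
    run_lengths: list[int] = []
    state = int(rng.integers(k))
    total = 0
    while total < n:
        run_labels.append(state)
        if config.duration_model == "geometric":
            length = int(rng.geometric(1.0 / mean_samples[state]))
        elif config.duration_model == "fixed":
            length = max(1, int(round(mean_samples[state])))
        else:
            raise ValueError(f"unknown duration_model {config.duration_model!r}")
        run_lengths.append(length)
        total += length
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
    run_lengths[-1] -= total - n  # truncate final run at recording end
    run_labels_arr = np.asarray(run_labels, dtype=int)
    run_lengths_arr = np.asarray(run_lengths, dtype=int)
    run_starts = np.concatenate([[0], np.cumsum(run_lengths_arr)[:-1]])
    run_signs = rng.choice([-1.0, 1.0], size=run_labels_arr.size)

    labels = np.repeat(run_labels_arr, run_lengths_arr)
    signs = np.repeat(run_signs, run_lengths_arr)
    # time since run start, per sample
    t_idx = np.arange(n, dtype=float)
    t_run = (t_idx - np.repeat(run_starts, run_lengths_arr)) / config.fs
    amplitude = AMPLITUDE_UV * np.abs(np.cos(2.0 * np.pi * MODULATION_HZ * t_run))

    n_ch = config.montage.n_channels
    data = templates[labels].T * (signs * amplitude)  # channels x samples
    if config.noise_sigma > 0:
        noise = rng.standard_normal((n_ch, n)) * (config.noise_sigma * amplitude)
        data = data + noise
    data = data - data.mean(axis=0, keepdims=True)

    rec = EEGRecording(data=data, fs=config.fs, montage=config.montage)
    truth = GroundTruth(
        labels=labels,
        templates=templates,
        run_starts=run_starts,
        run_labels=run_labels_arr,
        run_signs=run_signs,
        fs=config.fs,
    )
    return rec, truth
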