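"""Scalp-map primitives: average reference, GFP, spatial correlation.

A *map* is a 1-D vector of potentials, one entry per electrode of a fixed
montage. All microstate mathematics in this package reduces to three map
operations defined here:

* average reference -- subtract the instantaneous mean across electrodes,
  making the field reference-free;
* GFP of a map -- the population (divisor ``N``) standard deviation of the
  potentials across electrodes;
* spatial correlation -- Pearson correlation across electrodes, whose
  absolute value is the polarity-invariant similarity used everywhere
  microstate polarity is irrelevant.

With average-referenced maps these definitions make the identity
``GD^2 = 2 (1 - r)`` between global dissimilarity and spatial correlation
exact, which the comparison module relies on.
"""

from __future__ import annotations

import numpy as np

from .montage import Montage


def average_reference_map(u: np.ndarray) -> np.ndarray:
    """Return ``u`` minus its mean across electrodes."""
    u = np.asarray(u, dtype=float)
    return u - u.mean(axis=-1, keepdims=True)


def gfp_of_map(u: np.ndarray) -> float:
    """Global field power of a single map: population SD across electrodes."""
    u = np.asarray(u, dtype=float)
    return float(np.std(u))


def unit_gfp(u: np.ndarray) -> np.ndarray:
    """Average-reference a map and rescale it to GFP 1.

    Raises
    ------
    ValueError
        If the map has zero GFP (flat field).
    """
    u = average_reference_map(u)
    g = gfp_of_map(u)
    if g == 0.0:
        raise ValueError("map has zero GFP; cannot normalize")
    return u / g


def polarity_corr(u: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Spatial (Pearson) correlation between two maps.

    Returns ``(r, abs(r))``: the signed correlation and its absolute value.
    The absolute value is the similarity used wherever microstate polarity
    is irrelevant (clustering, backfitting).

    Raises
    ------
    ValueError
        If the maps differ in length or either has zero GFP.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"map shapes differ: {u.shape} vs {v.shape}")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-GFP map has no defined spatial correlation")
    r = float(uc @ vc / (nu * nv))
    r = min(1.0, max(-1.0, r))
    return r, abs(r)


def canonical_templates(montage: Montage) -> np.ndarray:
    """The four canonical microstate reference topographies A-D.

    Built analytically from electrode positions, matching the shapes
    reported across the resting-state literature:

    * **A** -- left-posterior to right-anterior diagonal gradient,
    * **B** -- right-posterior to left-anterior diagonal gradient,
    * **C** -- anterior-posterior gradient,
    * **D** -- fronto-central maximum against the periphery.

    Returns a ``(4, n_channels)`` array of average-referenced unit-GFP maps.
    """
    x = montage.positions[:, 0]
    y = montage.positions[:, 1]
    r2 = x**2 + y**2
    raw = np.stack([
        (x + y) / np.sqrt(2.0),   # A
        (-x + y) / np.sqrt(2.0),  # B
        y,                        # C
        1.0 - 2.0 * r2,           # D
    ])
    return np.stack([unit_gfp(m) for m in raw])
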