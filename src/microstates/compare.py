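"""Global map dissimilarity and permutation TANOVA.

Global dissimilarity (GD) between two scalp maps u and v is

    GD = sqrt( (1/N) * sum_i ( u_i/GFP_u - v_i/GFP_v )^2 ),

the root-mean-square difference of the GFP-normalized fields. For
average-referenced maps it obeys the identity ``GD^2 = 2 (1 - r)`` with r
the spatial correlation, so GD ranges over [0, 2] with the extremes at
r = +1 and r = -1.

The topographic analysis of variance (TANOVA) tests whether two paired
groups of maps (e.g. per-subject templates from a pre- and a
post-treatment condition) differ in topography: the observed statistic is
the GD between the two condition mean maps, and the null distribution is
built by randomly swapping condition labels within subject pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import average_reference_map, gfp_of_map, unit_gfp


def global_dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """GD between two maps (average-referenced internally).

    Raises
    ------
    ValueError
        On shape mismatch or a zero-GFP map.
    """
    u = average_reference_map(u)
    v = average_reference_map(v)
    if u.shape != v.shape:
        raise ValueError(f"map shapes differ: {u.shape} vs {v.shape}")
    gu = gfp_of_map(u)
    gv = gfp_of_map(v)
    if gu == 0.0 or gv == 0.0:
        raise ValueError("zero-GFP map has no defined dissimilarity")
    d = u / gu - v / gv
    return float(np.sqrt(np.mean(d**2)))


@dataclass
class TanovaResult:
    """Per-template and global permutation TANOVA outcome."""

    labels: tuple[str, ...]
    observed_gd: dict[str, float]
    p_values: dict[str, float]
    global_observed: float
    global_p: float
    n_perm: int


def _sign_align(maps: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Flip each row's sign to correlate positively with ``ref``."""
    signs = np.sign(maps @ ref)
    signs[signs == 0] = 1.0
    return maps * signs[:, None]


def _mean_map_gd(u_maps: np.ndarray, v_maps: np.ndarray) -> float:
    mu = unit_gfp(u_maps.mean(axis=0))
    mv = unit_gfp(v_maps.mean(axis=0))
    return global_dissimilarity(mu, mv)


def tanova(
    group_u: np.ndarray,
    group_v: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    labels: tuple[str, ...] | None = None,
) -> TanovaResult:
    """Paired permutation TANOVA between two groups of subject maps.

    Parameters
    ----------
    group_u, group_v
        Either ``(n_subjects, n_channels)`` arrays (a single template) or
        ``(n_subjects, n_templates, n_channels)`` arrays; subject i of one
        group is paired with subject i of the other.
    n_perm
        Number of sign-swap permutations (>= 99).
    labels
        Template labels; defaults to A, B, C, ...

    Notes
    -----
    Because microstate maps carry an arbitrary sign, every map is first
    sign-aligned to the first group's grand-mean map of its template. The
    per-template statistic is the GD between the two condition mean maps
    (each mean average-referenced and renormalized); the global statistic
    is the mean GD across templates under the same permutations. p-values
    use the add-one estimator ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    u = np.asarray(group_u, dtype=float)
    v = np.asarray(group_v, dtype=float)
    if u.ndim == 2:
        u = u[:, None, :]
        v = v[:, None, :]
    if u.shape != v.shape:
        raise ValueError(
            f"groups must be paired with equal shapes, got {u.shape} vs {v.shape}"
        )
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n_subj, n_tpl, _ = u.shape
    if labels is None:
        labels = tuple(chr(ord("A") + t) for t in range(n_tpl))

    # polarity alignment per template, against the first group's mean field
    u_al = np.empty_like(u)
    v_al = np.empty_like(v)
    for t in range(n_tpl):
        ref = _sign_align(u[:, t, :], u[0, t, :]).mean(axis=0)
        u_al[:, t, :] = _sign_align(u[:, t, :], ref)
        v_al[:, t, :] = _sign_align(v[:, t, :], ref)

    observed = np.array([_mean_map_gd(u_al[:, t, :], v_al[:, t, :])
                         for t in range(n_tpl)])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_tpl)
    exceed_global = 0
    obs_global = observed.mean()
    for _ in range(n_perm):
        swap = rng.random(n_subj) < 0.5
        pu = np.where(swap[:, None, None], v_al, u_al)
        pv = np.where(swap[:, None, None], u_al, v_al)
        stat = np.array([_mean_map_gd(pu[:, t, :], pv[:, t, :])
                         for t in range(n_tpl)])
        exceed += stat >= observed
        if stat.mean() >= obs_global:
            exceed_global += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return TanovaResult(
        labels=labels,
        observed_gd={lab: float(o) for lab, o in zip(labels, observed)},
        p_values={lab: float(x) for lab, x in zip(labels, p)},
        global_observed=float(obs_global),
        global_p=(1.0 + exceed_global) / (1.0 + n_perm),
        n_perm=n_perm,
    )
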