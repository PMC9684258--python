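"""Polarity-invariant template clustering and cluster-number selection.

Microstate templates are extracted from GFP-peak maps with the *modified
k-means* of topographic segmentation: a map belongs to the template with
the highest **absolute** spatial correlation (polarity is irrelevant), and
each template is re-estimated as the first principal direction of its
assigned maps -- the sign-indeterminate analogue of a centroid mean.

Goodness of fit is the explained variance

    EV = 100 * sum_i (GFP_i * |corr_i|)^2 / sum_i GFP_i^2,

the fraction of GFP-weighted map variance captured by the winning
templates, and the complementary within-cluster dispersion

    W(k) = sum_i (1 - corr_i^2) * GFP_i^2,

an orientation-invariant residual that is non-increasing in ``k``. The
number of templates is selected with the Krzanowski-Lai criterion on the
W(k) curve; the second KL maximum convention of the source literature is
implemented as documented in :func:`krzanowski_lai`.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .gfp import PeakMaps
from .maps import canonical_templates, polarity_corr  # noqa: F401  (re-export)
from .montage import Montage


@dataclass
class TemplateSet:
    """A set of unit-GFP average-referenced template maps with labels."""

    templates: np.ndarray = field(repr=False)  # k x channels
    labels: tuple[str, ...]
    montage: Montage
    provenance: str = "individual"

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2:
            raise ValueError("templates must be a k x channels matrix")
        if self.templates.shape[1] != self.montage.n_channels:
            raise ValueError("template width must match montage size")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.templates.shape[0]:
            raise ValueError("one label per template required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("template labels must be unique")

    @property
    def k(self) -> int:
        return self.templates.shape[0]

    def __getitem__(self, label: str) -> np.ndarray:
        return self.templates[self.labels.index(label)]


@dataclass
class ClusterResult:
    """Outcome of one clustering run at a fixed ``k``."""

    template_set: TemplateSet
    assignment: np.ndarray
    dispersion: float            # W(k)
    explained_variance: float    # percent
    converged: bool
    n_iter: int


@dataclass
class ClusterQuality:
    """Per-k quality curves and the KL-selected cluster number."""

    ks: tuple[int, ...]
    dispersion: dict[int, float]
    explained_variance: dict[int, float]
    kl: dict[int, float]
    chosen_k: int
    kl_fallback: bool


def _default_labels(k: int) -> tuple[str, ...]:
    return tuple(string.ascii_uppercase[:k])


def _as_map_matrix(maps: PeakMaps | np.ndarray) -> np.ndarray:
    v = maps.maps if isinstance(maps, PeakMaps) else np.asarray(maps, dtype=float)
    v = v - v.mean(axis=1, keepdims=True)
    return v


def _principal_direction(m: np.ndarray) -> np.ndarray:
    """First principal direction (unit norm) of a maps x channels block."""
    cross = m.T @ m
    vals, vecs = np.linalg.eigh(cross)
    return vecs[:, -1]


def cluster_maps(
    maps: PeakMaps | np.ndarray,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    montage: Montage | None = None,
) -> ClusterResult:
    """Modified (polarity-invariant) k-means over GFP-peak maps.

    Assignment maximizes ``|corr|`` to the current templates (ties go to
    the lower template index); each template update is the first principal
    direction of its assigned maps, renormalized to unit GFP. The best of
    ``n_restarts`` seeded restarts by explained variance is returned.

    Parameters
    ----------
    maps
        ``PeakMaps`` or a plain peaks x channels matrix (average-referenced
        on entry).
    montage
        Required if ``maps`` is a bare matrix.
    """
    v = _as_map_matrix(maps)
    n, n_ch = v.shape
    if montage is None:
        if not isinstance(maps, PeakMaps):
            raise ValueError("montage required when maps is a bare matrix")
        raise ValueError("montage must be supplied to build the TemplateSet")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")

    norms2 = np.einsum("ij,ij->i", v, v)
    total = norms2.sum()
    if total == 0:
        raise ValueError("all maps have zero GFP")
    nonzero = np.flatnonzero(norms2 > 0)
    if nonzero.size < k:
        raise ValueError("fewer nonzero-GFP maps than clusters")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, bool, int] | None = None

    for restart in range(max(1, n_restarts)):
        if restart % 2 == 0:
            init = rng.choice(nonzero, size=k, replace=False)
            centroids = v[init] / np.linalg.norm(v[init], axis=1, keepdims=True)
        else:
            # random-direction inits widen the search beyond map-pair seeds,
            # which matters for small map counts
            g = rng.standard_normal((k, n_ch))
            g -= g.mean(axis=1, keepdims=True)
            centroids = g / np.linalg.norm(g, axis=1, keepdims=True)
        ev_old = None
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            proj = v @ centroids.T                      # n x k signed projections
            assign = np.argmax(np.abs(proj), axis=1)    # ties -> lower index
            fit = proj[np.arange(n), assign] ** 2
            # re-seed empty clusters with the worst-fit map
            for j in range(k):
                if not np.any(assign == j):
                    worst = int(np.argmin(fit))
                    assign[worst] = j
                    fit[worst] = 0.0
            for j in range(k):
                centroids[j] = _principal_direction(v[assign == j])
            proj = v @ centroids.T
            assign = np.argmax(np.abs(proj), axis=1)
            ev = float(np.sum(proj[np.arange(n), assign] ** 2) / total)
            if ev_old is not None and abs(ev - ev_old) <= tol * max(abs(ev_old), 1e-12):
                converged = True
                break
            ev_old = ev
        if best is None or ev > best[0]:
            best = (ev, centroids.copy(), assign.copy(), converged, it)

    ev, centroids, assign, converged, n_iter = best
    # unit GFP: SD across channels = 1 <=> Euclidean norm = sqrt(n_ch)
    templates = centroids * np.sqrt(n_ch)
    dispersion = float((total - ev * total) / n_ch)  # sum (1 - corr^2) GFP^2
    tset = TemplateSet(
        templates=templates,
        labels=_default_labels(k),
        montage=montage,
        provenance="individual",
    )
    return ClusterResult(
        template_set=tset,
        assignment=assign,
        dispersion=dispersion,
        explained_variance=100.0 * ev,
        converged=converged,
        n_iter=n_iter,
    )


def dispersion_curve(
    maps: PeakMaps | np.ndarray,
    k_range: range | tuple[int, ...] = range(1, 13),
    montage: Montage | None = None,
    **kwargs,
) -> tuple[dict[int, float], dict[int, float], dict[int, ClusterResult]]:
    """Cluster at every ``k`` in the range; return W(k), EV(k), and results."""
    disp: dict[int, float] = {}
    ev: dict[int, float] = {}
    results: dict[int, ClusterResult] = {}
    for k in k_range:
        res = cluster_maps(maps, k, montage=montage, **kwargs)
        disp[k] = res.dispersion
        ev[k] = res.explained_variance
        results[k] = res
    return disp, ev, results


def krzanowski_lai(
    dispersion: dict[int, float], n_features: int
) -> tuple[dict[int, float], int, bool]:
    """Krzanowski-Lai cluster-number criterion on a W(k) curve.

    With ``p = n_features`` (the electrode count),

        DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k)
        KL(k)   = |DIFF(k)| / |DIFF(k+1)|

    so KL is defined for the interior of the supplied contiguous k range.

    The selected k implements the *second KL maximum* convention of the
    microstate literature: the trivial maximum at the boundary of the
    evaluable range (where the initial steep drop of W makes KL large by
    construction) is discarded, and the chosen k is the position of the
    largest **interior local maximum** of the KL curve -- i.e. the largest
    maximum after the trivial first one. If the curve has no interior
    local maximum (e.g. near-geometric W, where KL is flat) the global KL
    maximum is used as a flagged fallback.

    A numerical guard excludes spurious candidates: because KL(k) is a
    ratio of successive penalized-dispersion drops, a drop near zero in
    the denominator inflates KL at a k that is no elbow at all. An elbow
    candidate must therefore have a genuinely positive drop,
    ``DIFF(k) > 0`` and ``|DIFF(k)|`` at least 1% of the curve's largest
    drop; candidates failing the guard are never selected.

    Returns ``(kl_values, chosen_k, used_fallback)``.

    Raises
    ------
    ValueError
        If fewer than 4 contiguous k values are supplied.
    """
    ks = sorted(dispersion)
    if len(ks) < 4:
        raise ValueError("KL criterion needs W(k) for at least 4 k values")
    if any(b - a != 1 for a, b in zip(ks[:-1], ks[1:])):
        raise ValueError("k range must be contiguous")
    w = np.array([dispersion[k] for k in ks], dtype=float)
    karr = np.array(ks, dtype=float)
    penalized = karr ** (2.0 / n_features) * w
    diff = penalized[:-1] - penalized[1:]          # DIFF(k) for k = ks[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(diff[:-1]) / np.abs(diff[1:])
    ratio = np.where(np.isfinite(ratio), ratio, np.inf)
    kl_ks = ks[1:-1]
    kl = dict(zip(kl_ks, (float(x) for x in ratio)))

    # elbow guard: DIFF(k) must be a real drop, not denominator noise
    diff_floor = 0.01 * np.max(np.abs(diff))
    valid = diff[:-1] > max(diff_floor, 0.0)

    # interior local maxima: strictly above both neighbouring KL values
    interior = [
        (ratio[i], kl_ks[i])
        for i in range(1, len(kl_ks) - 1)
        if valid[i] and ratio[i] > ratio[i - 1] and ratio[i] > ratio[i + 1]
    ]
    if interior:
        chosen = max(interior)[1]
        return kl, chosen, False
    candidates = np.flatnonzero(valid)
    if candidates.size:
        chosen = kl_ks[int(candidates[np.argmax(ratio[candidates])])]
    else:
        chosen = kl_ks[int(np.argmax(ratio))]
    return kl, chosen, True


def select_k(
    maps: PeakMaps | np.ndarray,
    k_range: range | tuple[int, ...] = range(1, 13),
    montage: Montage | None = None,
    **kwargs,
) -> ClusterQuality:
    """Run the full W(k) / KL model-selection sweep."""
    disp, ev, _ = dispersion_curve(maps, k_range, montage=montage, **kwargs)
    n_features = montage.n_channels
    kl, chosen, fallback = krzanowski_lai(disp, n_features)
    return ClusterQuality(
        ks=tuple(sorted(disp)),
        dispersion=disp,
        explained_variance=ev,
        kl=kl,
        chosen_k=chosen,
        kl_fallback=fallback,
    )


def meta_cluster(
    individual_sets: list[TemplateSet],
    k: int,
    provenance: str = "global",
    **kwargs,
) -> TemplateSet:
    """Second-level clustering: pool individual template sets into globals.

    All sets must share a montage and have exactly ``k`` templates; the
    pooled unit-GFP maps are re-clustered with the same polarity-invariant
    algorithm.
    """
    if not individual_sets:
        raise ValueError("no template sets supplied")
    montage = individual_sets[0].montage
    for s in individual_sets:
        if s.montage.names != montage.names:
            raise ValueError("all template sets must share a montage")
        if s.k != k:
            raise ValueError(
                f"mixed template counts: expected k={k}, got {s.k}"
            )
    pooled = np.vstack([s.templates for s in individual_sets])
    res = cluster_maps(pooled, k, montage=montage, **kwargs)
    tset = res.template_set
    tset.provenance = provenance
    return tset


def canonical_label(tset: TemplateSet) -> TemplateSet:
    """Relabel templates by greedy matching to the canonical A-D shapes.

    The highest ``|corr|`` pair is matched first, one-to-one; templates
    beyond the four canonical shapes are labeled E, F, ... in their
    residual order. The returned set is reordered alphabetically and each
    template's sign is flipped to correlate positively with its canon.
    """
    refs = canonical_templates(tset.montage)
    k = tset.k
    score = np.zeros((k, refs.shape[0]))
    signs = np.ones((k, refs.shape[0]))
    for i in range(k):
        for j in range(refs.shape[0]):
            r, a = polarity_corr(tset.templates[i], refs[j])
            score[i, j] = a
            signs[i, j] = 1.0 if r >= 0 else -1.0
    labels = [None] * k
    flip = np.ones(k)
    work = score.copy()
    for _ in range(min(k, refs.shape[0])):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        labels[i] = string.ascii_uppercase[j]
        flip[i] = signs[i, j]
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    next_letter = refs.shape[0]
    for i in range(k):
        if labels[i] is None:
            labels[i] = string.ascii_uppercase[next_letter]
            next_letter += 1
    order = np.argsort(labels)
    return TemplateSet(
        templates=(tset.templates * flip[:, None])[order],
        labels=tuple(np.asarray(labels)[order]),
        montage=tset.montage,
        provenance=tset.provenance,
    )
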