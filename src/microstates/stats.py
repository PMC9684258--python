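"""Aligned rank transform (ART) factorial statistics and plumbing tests.

The ART makes factorial ANOVA applicable to non-normal repeated-measures
metrics: for each effect of interest the data are *aligned* (the
estimated contributions of every other effect are stripped, keeping the
residual plus the target effect's own marginal estimate), converted to
midranks, and submitted to an ordinary factorial ANOVA; only the target
effect's row of that ANOVA is interpreted. Estimates come from cell and
marginal means (the original alignment scheme), and the linear model is
the full factorial of the design's factors with a single residual error
stratum, so for a design with N observations and a p-parameter full
factorial the denominator df is N - p.

Contrast testing follows the ART-C recipe: data are re-aligned and
re-ranked for the combined cell factor spanned by the contrast family,
each contrast is a pooled-variance t-test between cells on those ranks,
and the family is Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ARTDesign:
    """A factorial design on a tidy table.

    ``factors`` maps a column name to its ordered levels; all listed
    factors enter the linear model as a full factorial. ``response`` is
    the measured column and ``subject`` identifies the repeated-measures
    unit (used only for completeness checks).
    """

    response: str
    factors: dict[str, tuple] = field(default_factory=dict)
    subject: str = "subject"

    def effect_names(self) -> list[tuple[str, ...]]:
        names = list(self.factors)
        effects: list[tuple[str, ...]] = []
        for r in range(1, len(names) + 1):
            effects.extend(combinations(names, r))
        return effects


def _check_design(df: pd.DataFrame, design: ARTDesign) -> None:
    for f, levels in design.factors.items():
        if f not in df.columns:
            raise ValueError(f"factor column {f!r} missing from data")
        extra = set(df[f].unique()) - set(levels)
        if extra:
            raise ValueError(f"factor {f!r} has unlisted levels {sorted(map(str, extra))}")
    if design.response not in df.columns:
        raise ValueError(f"response column {design.response!r} missing")
    if df[design.response].isna().any():
        raise ValueError("response contains missing values")
    counts = df.groupby([*design.factors], observed=True).size()
    full = np.prod([len(v) for v in design.factors.values()])
    if len(counts) != full:
        have = set(counts.index if counts.index.nlevels > 1
                   else ((i,) for i in counts.index))
        missing = [c for c in _all_cells(design) if c not in have]
        raise ValueError(f"design has empty cells: {missing[:10]}")


def _all_cells(design: ARTDesign):
    from itertools import product
    return list(product(*design.factors.values()))


def _marginal_means(df: pd.DataFrame, response: str,
                    factors: tuple[str, ...]) -> pd.Series | float:
    if not factors:
        return float(df[response].mean())
    return df.groupby(list(factors), observed=True)[response].mean()


def _effect_estimate(df: pd.DataFrame, response: str,
                     effect: tuple[str, ...]) -> np.ndarray:
    """Moebius (inclusion-exclusion) estimate of one effect per observation."""
    est = np.zeros(len(df))
    m = len(effect)
    for r in range(m + 1):
        for sub in combinations(effect, r):
            sign = (-1) ** (m - r)
            means = _marginal_means(df, response, sub)
            if not sub:
                est += sign * means
            else:
                key = df[list(sub)].apply(tuple, axis=1) if len(sub) > 1 else df[sub[0]]
                mapped = key.map(means if len(sub) > 1 else means.to_dict())
                est += sign * mapped.to_numpy(dtype=float)
    return est


def art_align_and_rank(
    df: pd.DataFrame, design: ARTDesign, effect: tuple[str, ...] | str
) -> np.ndarray:
    """Aligned midranks of the response for one target effect.

    The aligned response is the within-cell residual plus the target
    effect's own marginal estimate; every other effect's estimate is
    thereby subtracted. By construction the aligned values of any
    non-target effect sum to zero within each of its levels.
    """
    if isinstance(effect, str):
        effect = (effect,)
    unknown = [f for f in effect if f not in design.factors]
    if unknown:
        raise ValueError(f"effect references unknown factor(s) {unknown}")
    _check_design(df, design)
    y = df[design.response].to_numpy(dtype=float)
    cell_means = _marginal_means(df, design.response, tuple(design.factors))
    key = df[list(design.factors)].apply(tuple, axis=1)
    fitted = key.map(cell_means).to_numpy(dtype=float) if len(design.factors) > 1 \
        else df[list(design.factors)[0]].map(cell_means.to_dict()).to_numpy(dtype=float)
    residual = y - fitted
    aligned = residual + _effect_estimate(df, design.response, effect)
    return sps.rankdata(aligned)


def _sum_coded(values: pd.Series, levels: tuple) -> np.ndarray:
    """Sum-to-zero coding: L-1 columns, last level coded -1."""
    n = len(values)
    cols = np.zeros((n, len(levels) - 1))
    arr = values.to_numpy()
    for j, lev in enumerate(levels[:-1]):
        cols[arr == lev, j] = 1.0
    cols[arr == levels[-1], :] = -1.0
    return cols


def _design_matrices(
    df: pd.DataFrame, design: ARTDesign
) -> tuple[np.ndarray, dict[tuple[str, ...], slice]]:
    """Full-factorial sum-coded design matrix and per-effect column slices."""
    blocks = [np.ones((len(df), 1))]
    slices: dict[tuple[str, ...], slice] = {}
    start = 1
    main = {f: _sum_coded(df[f], tuple(levels))
            for f, levels in design.factors.items()}
    for effect in design.effect_names():
        cols = main[effect[0]]
        for f in effect[1:]:
            # interaction columns: all pairwise products
            a, b = cols, main[f]
            cols = np.einsum("ni,nj->nij", a, b).reshape(len(df), -1)
        blocks.append(cols)
        slices[effect] = slice(start, start + cols.shape[1])
        start += cols.shape[1]
    return np.hstack(blocks), slices


def _f_test(x_full: np.ndarray, y: np.ndarray, drop: slice) -> tuple[float, int, int, float]:
    keep = np.ones(x_full.shape[1], dtype=bool)
    keep[drop] = False
    x_red = x_full[:, keep]
    rss_full = _rss(x_full, y)
    rss_red = _rss(x_red, y)
    df1 = int(drop.stop - drop.start)
    df2 = int(len(y) - np.linalg.matrix_rank(x_full))
    if df2 <= 0:
        raise ValueError("singular design: no residual degrees of freedom")
    num = max(rss_red - rss_full, 0.0) / df1
    den = rss_full / df2
    if den == 0.0:
        f = np.inf if num > 0 else 0.0
    else:
        f = num / den
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), df1, df2, p


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


@dataclass
class ARTResult:
    """Per-effect aligned-rank F tests."""

    table: pd.DataFrame  # columns: effect, F, df1, df2, p
    design: ARTDesign

    def effect(self, *factors: str) -> pd.Series:
        name = " x ".join(factors)
        sel = self.table[self.table["effect"] == name]
        if sel.empty:
            raise KeyError(f"no effect {name!r} in result")
        return sel.iloc[0]


def art_anova(
    df: pd.DataFrame,
    design: ARTDesign,
    effects: list[tuple[str, ...]] | None = None,
) -> ARTResult:
    """Factorial ART ANOVA: one aligned-rank F test per effect.

    Each effect is aligned and ranked separately, then tested in the full
    factorial linear model on those ranks with a single residual error
    term (denominator df = N - p for a p-parameter full factorial).
    """
    _check_design(df, design)
    if effects is None:
        effects = design.effect_names()
    x_full, slices = _design_matrices(df, design)
    rows = []
    for effect in effects:
        effect = tuple(effect) if not isinstance(effect, str) else (effect,)
        ranks = art_align_and_rank(df, design, effect)
        f, df1, df2, p = _f_test(x_full, ranks, slices[effect])
        rows.append({"effect": " x ".join(effect), "F": f,
                     "df1": df1, "df2": df2, "p": p})
    return ARTResult(table=pd.DataFrame(rows), design=design)


@dataclass
class Contrast:
    """A two-cell contrast on the combined levels of one or more factors."""

    cell_a: tuple
    cell_b: tuple


def art_c_contrasts(
    df: pd.DataFrame,
    design: ARTDesign,
    effect: tuple[str, ...],
    contrasts: list[Contrast],
) -> pd.DataFrame:
    """ART-C multifactor contrasts with Bonferroni family correction.

    Data are aligned and ranked for the *combined* effect spanned by the
    contrast factors; each contrast is a pooled-variance t-test between
    its two cells, with the error variance pooled across all combined
    cells (df = N - number of cells). Adjusted p is ``min(1, m * p)``
    over the family of ``m`` contrasts.
    """
    effect = tuple(effect)
    unknown = [f for f in effect if f not in design.factors]
    if unknown:
        raise ValueError(f"contrast references unknown factor(s) {unknown}")
    _check_design(df, design)
    # ART-C alignment: the contrast factors are fused into one combined
    # cell factor, and the data are aligned for that single effect
    # (residual + combined-cell mean - grand mean), then midranked.
    y = df[design.response].to_numpy(dtype=float)
    all_cells = _marginal_means(df, design.response, tuple(design.factors))
    if len(design.factors) > 1:
        full_key = df[list(design.factors)].apply(tuple, axis=1)
        fitted = full_key.map(all_cells).to_numpy(dtype=float)
    else:
        only = list(design.factors)[0]
        fitted = df[only].map(all_cells.to_dict()).to_numpy(dtype=float)
    combined = _marginal_means(df, design.response, effect)
    key = df[list(effect)].apply(tuple, axis=1) if len(effect) > 1 \
        else df[effect[0]].map(lambda v: (v,))
    combo_key = key if len(effect) > 1 else df[list(effect)].apply(tuple, axis=1)
    cell_est = combo_key.map(combined if len(effect) > 1
                             else {(k,): v for k, v in combined.items()})
    aligned = (y - fitted) + cell_est.to_numpy(dtype=float) - y.mean()
    ranks = sps.rankdata(aligned)
    groups = {cell: ranks[(key == cell).to_numpy()] for cell in key.unique()}
    n_total = len(df)
    n_cells = len(groups)
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    dfe = n_total - n_cells
    mse = sse / dfe
    m = len(contrasts)
    rows = []
    for c in contrasts:
        for cell in (c.cell_a, c.cell_b):
            if cell not in groups:
                raise ValueError(f"contrast references absent cell {cell!r}")
        ga, gb = groups[c.cell_a], groups[c.cell_b]
        se = np.sqrt(mse * (1.0 / len(ga) + 1.0 / len(gb)))
        t = (ga.mean() - gb.mean()) / se
        p_raw = 2.0 * float(sps.t.sf(abs(t), dfe))
        rows.append({
            "cell_a": c.cell_a, "cell_b": c.cell_b, "t": float(t),
            "df": dfe, "p_raw": p_raw, "p_adj": min(1.0, m * p_raw),
        })
    return pd.DataFrame(rows)


def chi_square_table(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns ``(chi2, df, p)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), int(dof), float(p)
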