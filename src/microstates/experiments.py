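"""Self-validation experiments on synthetic ground truth.

Each function runs one closed-loop experiment -- generate data with
planted structure (or load the packaged cohort table), run the package's
own analysis path, and measure how well the planted quantities are
recovered. They are used by the test suite and by ``scripts/acceptance.py``
and are deliberately written against the public API only.

Problem sizes are the package's standard validation conditions: 10-minute
recordings at 256 Hz with 19 channels, spatial noise 0.3 relative to the
unit template norm, 27-subject statistical designs matching the clinical
study layout the package targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .backfit import backfit, compute_metrics, transition_stats
from .clustering import TemplateSet, cluster_maps, dispersion_curve, krzanowski_lai
from .cohort import load_cohort, summarize_cohort
from .compare import global_dissimilarity
from .gfp import extract_peak_maps, find_gfp_peaks, global_field_power
from .maps import polarity_corr, unit_gfp
from .montage import standard_1020_19
from .simulate import SimulationConfig, simulate
from .stats import ARTDesign, Contrast, art_anova, art_c_contrasts

TEMPLATES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# cohort descriptives
# ---------------------------------------------------------------------------

def cohort_summary_experiment() -> dict:
    """Descriptive statistics of the packaged 27-patient cohort table."""
    cohort = load_cohort()
    summary = summarize_cohort(cohort)
    return {
        "n_patients": summary["n"],
        "mean_lev_dose_mg": summary["lev_dose_mg"]["mean"],
        "sd_lev_dose_mg": summary["lev_dose_mg"]["sd"],
        "mean_age_years": summary["age"]["mean"],
        "sd_age_years": summary["age"]["sd"],
        "pct_seizure_free": summary["outcome"]["SF"]["pct"],
        "pct_nsf_gt50": summary["outcome"]["NSF>50"]["pct"],
        "pct_nsf_lt50": summary["outcome"]["NSF<50"]["pct"],
        "pct_structural_aetiology": summary["structural_aetiology"]["pct"],
        "pct_adverse_events": summary["adverse_events"]["pct"],
        "n_females": summary["sex"]["F"]["count"],
    }


# ---------------------------------------------------------------------------
# global dissimilarity identities
# ---------------------------------------------------------------------------

def gd_identity_experiment(n_pairs: int = 1000, seed: int = 0) -> dict:
    """Check GD(u,u)=0, GD(u,-u)=2 and GD = sqrt(2(1-r)) on random maps."""
    rng = np.random.default_rng(seed)
    montage = standard_1020_19()
    n_ch = montage.n_channels
    max_identity_err = 0.0
    self_err = 0.0
    flip_err = 0.0
    for _ in range(n_pairs):
        u = unit_gfp(rng.standard_normal(n_ch)) * rng.uniform(0.5, 20.0)
        v = unit_gfp(rng.standard_normal(n_ch)) * rng.uniform(0.5, 20.0)
        gd = global_dissimilarity(u, v)
        r, _ = polarity_corr(u, v)
        max_identity_err = max(max_identity_err, abs(gd - np.sqrt(2.0 * (1.0 - r))))
        self_err = max(self_err, abs(global_dissimilarity(u, u)))
        flip_err = max(flip_err, abs(global_dissimilarity(u, -u) - 2.0))
    return {
        "n_pairs": n_pairs,
        "max_identity_error": max_identity_err,
        "max_self_gd": self_err,
        "max_antipodal_gd_error": flip_err,
    }


# ---------------------------------------------------------------------------
# template recovery and KL model selection
# ---------------------------------------------------------------------------

def _matched_min_corr(recovered: np.ndarray, truth: np.ndarray) -> float:
    """Min |corr| under the optimal one-to-one template matching."""
    k = truth.shape[0]
    score = np.zeros((recovered.shape[0], k))
    for i in range(recovered.shape[0]):
        for j in range(k):
            score[i, j] = polarity_corr(recovered[i], truth[j])[1]
    rows, cols = linear_sum_assignment(-score)
    return float(score[rows, cols].min())


def template_recovery_experiment(
    n_runs: int = 20,
    seed: int = 0,
    duration: float = 600.0,
    noise_sigma: float = 0.3,
    n_restarts: int = 10,
    k_max: int = 12,
) -> dict:
    """Recover planted templates and the template count across seeded runs.

    For each run a 10-minute 4-template recording is simulated, peak maps
    are clustered over k = 1..k_max, the KL criterion picks k, and the
    k=4 solution is matched one-to-one against the planted templates.
    """
    montage = standard_1020_19()
    min_corrs = []
    chosen_ks = []
    for r in range(n_runs):
        cfg = SimulationConfig(
            duration=duration, noise_sigma=noise_sigma, seed=seed + r
        )
        rec, gt = simulate(cfg)
        gfp = global_field_power(rec)
        peaks = find_gfp_peaks(gfp)
        pmaps = extract_peak_maps(rec, peaks)
        disp, _, results = dispersion_curve(
            pmaps, range(1, k_max + 1), montage=montage,
            n_restarts=n_restarts, seed=seed + r,
        )
        _, chosen, _ = krzanowski_lai(disp, montage.n_channels)
        chosen_ks.append(chosen)
        min_corrs.append(
            _matched_min_corr(results[4].template_set.templates, gt.templates)
        )
    chosen_ks = np.asarray(chosen_ks)
    return {
        "n_runs": n_runs,
        "min_matched_abs_corr": float(np.min(min_corrs)),
        "kl_correct_rate": float(np.mean(chosen_ks == 4)),
        "chosen_k_values": chosen_ks.tolist(),
    }


# ---------------------------------------------------------------------------
# metric recovery through backfitting
# ---------------------------------------------------------------------------

#: Planted per-template mean durations spanning the 40-100 ms band.
PLANTED_DURATIONS_MS = np.array([40.0, 60.0, 80.0, 100.0])

#: Planted transition matrix with P(A->C) - P(C->A) = 0.3.
PLANTED_TRANSITION = np.array([
    [0.00, 0.25, 0.50, 0.25],
    [0.30, 0.00, 0.30, 0.40],
    [0.20, 0.40, 0.00, 0.40],
    [0.34, 0.33, 0.33, 0.00],
])
PLANTED_DP_AC = 100.0 * (PLANTED_TRANSITION[0, 2] - PLANTED_TRANSITION[2, 0])


def metric_recovery_experiment(
    seed: int = 0,
    duration: float = 600.0,
    noise_sigma: float = 0.3,
    n_recordings: int = 3,
) -> dict:
    """Recover planted durations and transition asymmetry via backfitting.

    Simulates ``n_recordings`` 10-minute recordings with per-template mean
    durations spanning 40-100 ms and an A->C transition asymmetry of 30
    percentage points, backfits the *true* templates (isolating the
    backfitting/metric path from clustering error), and reports the
    recovered metrics averaged over recordings. Peak thinning is disabled
    here: resolving segments near the 40 ms end requires the detector's
    full temporal resolution.
    """
    montage = standard_1020_19()
    durations = np.zeros((n_recordings, 4))
    dp_ac = np.zeros(n_recordings)
    for r in range(n_recordings):
        cfg = SimulationConfig(
            duration=duration,
            noise_sigma=noise_sigma,
            mean_duration_ms=PLANTED_DURATIONS_MS,
            transition=PLANTED_TRANSITION,
            seed=seed + r,
        )
        rec, gt = simulate(cfg)
        tset = TemplateSet(templates=gt.templates, labels=TEMPLATES,
                           montage=montage, provenance="global")
        gfp = global_field_power(rec)
        peaks = find_gfp_peaks(gfp, min_separation_ms=0.0)
        seq = backfit(rec, tset, peaks)
        met = compute_metrics(seq)
        durations[r] = met["duration_ms"].to_numpy()
        _, dp = transition_stats(seq)
        dp_ac[r] = dp.loc[dp["pair"] == "A->C", "dp_pct"].iloc[0]
    mean_dur = durations.mean(axis=0)
    return {
        "n_recordings": n_recordings,
        "planted_durations_ms": PLANTED_DURATIONS_MS.tolist(),
        "recovered_durations_ms": mean_dur.tolist(),
        "max_duration_error_ms": float(np.max(np.abs(mean_dur - PLANTED_DURATIONS_MS))),
        "planted_dp_ac": PLANTED_DP_AC,
        "recovered_dp_ac": float(dp_ac.mean()),
        "dp_error_points": float(abs(dp_ac.mean() - PLANTED_DP_AC)),
    }


# ---------------------------------------------------------------------------
# ART ANOVA calibration, power, and degrees of freedom
# ---------------------------------------------------------------------------

_BASE_DURATION = {"A": 65.0, "B": 70.0, "C": 75.0, "D": 70.0}


def _simulated_metrics_table(
    seed: int,
    n_subjects: int = 27,
    bd_reduction: float = 0.0,
    noise_cv: float = 0.1,
) -> pd.DataFrame:
    """Per-subject duration table: 2 conditions x 4 templates.

    ``bd_reduction`` scales down the post-condition means of templates B
    and D (0.2 = the 20% effect used in power checks); ``noise_cv`` is the
    multiplicative noise coefficient of variation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for c in ("pre", "post"):
            for t in TEMPLATES:
                mu = _BASE_DURATION[t]
                if c == "post" and t in ("B", "D"):
                    mu *= 1.0 - bd_reduction
                rows.append({
                    "subject": s, "condition": c, "target": t,
                    "value": mu * (1.0 + noise_cv * rng.standard_normal()),
                })
    return pd.DataFrame(rows)


_METRICS_DESIGN = ARTDesign(
    response="value",
    factors={"condition": ("pre", "post"), "target": TEMPLATES},
)


def art_calibration_experiment(n_reps: int = 500, seed: int = 0) -> dict:
    """Type-I error of the Condition effect under a 27-subject null."""
    rejections = 0
    for i in range(n_reps):
        df = _simulated_metrics_table(seed + i)
        res = art_anova(df, _METRICS_DESIGN, effects=[("condition",)])
        rejections += res.table["p"].iloc[0] <= 0.05
    return {"n_reps": n_reps, "type_i_rate": rejections / n_reps}


def art_power_experiment(n_reps: int = 100, seed: int = 0) -> dict:
    """Power to detect a 20% post-condition B/D duration reduction.

    Reports the rate of Condition main effects at p < 0.01 and the rate
    of runs where the ART-C pre-vs-post contrasts flag B and D (and only
    B and D) after Bonferroni correction.
    """
    contrasts = [Contrast(("pre", t), ("post", t)) for t in TEMPLATES]
    condition_hits = 0
    selective_hits = 0
    for i in range(n_reps):
        df = _simulated_metrics_table(seed + 10_000 + i, bd_reduction=0.2)
        res = art_anova(df, _METRICS_DESIGN, effects=[("condition",)])
        condition_hits += res.table["p"].iloc[0] <= 0.01
        ct = art_c_contrasts(df, _METRICS_DESIGN, ("condition", "target"), contrasts)
        sig_down = {TEMPLATES[j] for j in ct.index
                    if ct.loc[j, "p_adj"] <= 0.05 and ct.loc[j, "t"] > 0}
        selective_hits += sig_down == {"B", "D"}
    return {
        "n_reps": n_reps,
        "condition_power": condition_hits / n_reps,
        "bd_selective_rate": selective_hits / n_reps,
    }


def art_df_experiment(seed: int = 0) -> dict:
    """Denominator dfs of the four standard design shapes (27 subjects).

    Metrics design (2 conditions x 4 templates): 216 observations, 8-cell
    full factorial; pairs design (2 x 6): 324 observations; each repeated
    with the r/l Side factor added (14 vs 13 subjects).
    """
    sides = ["r-TLE"] * 14 + ["l-TLE"] * 13
    rng = np.random.default_rng(seed)

    def table(levels):
        rows = []
        for s in range(27):
            for c in ("pre", "post"):
                for t in levels:
                    rows.append({"subject": s, "condition": c, "target": t,
                                 "side": sides[s], "value": rng.standard_normal()})
        return pd.DataFrame(rows)

    pair_levels = tuple(f"P{i}" for i in range(6))
    out = {}
    for name, levels, with_side in (
        ("metrics", TEMPLATES, False),
        ("metrics_side", TEMPLATES, True),
        ("pairs", pair_levels, False),
        ("pairs_side", pair_levels, True),
    ):
        factors = {"condition": ("pre", "post"), "target": levels}
        if with_side:
            factors["side"] = ("r-TLE", "l-TLE")
        design = ARTDesign(response="value", factors=factors)
        res = art_anova(table(levels), design, effects=[("condition",)])
        out[f"df_denominator_{name}"] = int(res.table["df2"].iloc[0])
    return out


# ---------------------------------------------------------------------------
# brute-force oracle for the polarity-invariant clustering
# ---------------------------------------------------------------------------

def _brute_force_best_ev(v: np.ndarray) -> float:
    """Globally optimal k=2 explained variance by exhaustive bipartition.

    For every nonempty bipartition the optimal templates are the first
    principal directions of the two blocks, so the partition's explained
    variance is the sum of leading eigenvalues over total map power.
    Independent of the iterative clustering path.
    """
    n = v.shape[0]
    total = float(np.einsum("ij,ij->i", v, v).sum())
    best = -1.0
    for bits in range(1, 2 ** (n - 1)):
        assign = np.array([(bits >> i) & 1 for i in range(n)])
        if assign.sum() in (0, n):
            continue
        ev = sum(
            float(np.linalg.eigvalsh(v[assign == c].T @ v[assign == c])[-1])
            for c in (0, 1)
        )
        best = max(best, ev / total)
    return best


def oracle_equivalence_experiment(
    n_instances: int = 50, seed: int = 0, n_restarts: int = 400
) -> dict:
    """Best-restart clustering vs exhaustive enumeration on tiny instances.

    Random average-referenced map sets (4-8 maps, 19 channels) are
    clustered at k=2; the attained explained variance is compared with the
    brute-force optimum over all bipartitions.
    """
    montage = standard_1020_19()
    matches = 0
    worst_gap = 0.0
    for i in range(n_instances):
        rng = np.random.default_rng(seed + i)
        n = int(rng.integers(4, 9))
        v = rng.standard_normal((n, montage.n_channels))
        v = v - v.mean(axis=1, keepdims=True)
        res = cluster_maps(v, 2, n_restarts=n_restarts, seed=seed + i,
                           montage=montage)
        ev = res.explained_variance / 100.0
        ev_opt = _brute_force_best_ev(v)
        gap = ev_opt - ev
        worst_gap = max(worst_gap, gap)
        matches += abs(gap) <= 1e-9
    return {
        "n_instances": n_instances,
        "optimal_fraction": matches / n_instances,
        "worst_ev_gap": worst_gap,
    }
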