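"""End-to-end study workflow.

Orchestrates the full microstate analysis over a cohort manifest:

1. load each subject's pre/post recordings (band-pass, average reference),
2. find GFP peaks and extract peak maps,
3. per-subject polarity-invariant clustering over a k range,
4. Krzanowski-Lai selection of the template count (modal choice across
   subjects), per-condition meta-clustering into condition template sets,
5. TANOVA between the condition-wise sets; when they do not differ the
   conditions are pooled into one global template set (the usual branch),
   otherwise each condition keeps its own set and the report flags it,
6. backfitting of the global templates to every recording and metric
   extraction,
7. ART ANOVA group statistics on the metric and directional-predominance
   designs.

Every artifact can be written to an output directory together with a
provenance record (config hash, seed, stage wall times).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .backfit import backfit, metrics_table
from .clustering import (
    TemplateSet,
    canonical_label,
    dispersion_curve,
    krzanowski_lai,
    meta_cluster,
    polarity_corr,
)
from .compare import TanovaResult, tanova
from .gfp import extract_peak_maps, find_gfp_peaks, global_field_power
from .io import bandpass_filter, read_recording
from .montage import get_montage
from .stats import ARTDesign, ARTResult, art_anova

log = logging.getLogger("microstates.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    manifest: pd.DataFrame | str | Path
    montage: str = "standard-1020-19"
    k_min: int = 2
    k_max: int = 12
    n_restarts: int = 10
    min_separation_ms: float = 10.0
    smoothing_ms: float = 0.0
    bandpass: tuple[float, float] | None = (1.0, 40.0)
    tanova_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not (2 <= self.k_min < self.k_max <= 12):
            raise ValueError("k range must satisfy 2 <= k_min < k_max <= 12")

    def resolved_manifest(self) -> pd.DataFrame:
        m = self.manifest
        if not isinstance(m, pd.DataFrame):
            m = pd.read_csv(m, sep="\t")
        required = {"subject", "condition", "side", "path"}
        missing = required - set(m.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for subject, grp in m.groupby("subject"):
            conds = set(grp["condition"])
            if conds != {"pre", "post"}:
                raise ValueError(
                    f"subject {subject!r} must have exactly one pre and one "
                    f"post recording, found conditions {sorted(conds)}"
                )
        return m

    def config_hash(self) -> str:
        payload = {
            k: (str(v) if isinstance(v, (Path,)) else v)
            for k, v in vars(self).items()
            if k != "manifest"
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    global_templates: TemplateSet
    condition_templates: dict[str, TemplateSet]
    chosen_k: int
    k_choices: dict[tuple[str, str], int]
    quality: dict[tuple[str, str], dict]
    tanova_result: TanovaResult
    conditions_pooled: bool
    metrics: pd.DataFrame
    art_reports: dict[str, ARTResult]
    provenance: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {error}")
        self.stage = stage


def _match_to_global(individual: TemplateSet, global_set: TemplateSet) -> np.ndarray:
    """Greedy one-to-one match of individual templates to global labels.

    Returns an array of per-global-label maps (k x channels), each the
    individual template best matching that global template, sign-aligned.
    """
    k = global_set.k
    score = np.zeros((k, individual.k))
    for g in range(k):
        for i in range(individual.k):
            _, a = polarity_corr(global_set.templates[g], individual.templates[i])
            score[g, i] = a
    out = np.zeros_like(global_set.templates)
    work = score.copy()
    for _ in range(min(k, individual.k)):
        g, i = np.unravel_index(np.argmax(work), work.shape)
        r, _ = polarity_corr(global_set.templates[g], individual.templates[i])
        out[g] = individual.templates[i] * (1.0 if r >= 0 else -1.0)
        work[g, :] = -np.inf
        work[:, i] = -np.inf
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; any stage error aborts naming the stage."""
    timings: dict[str, float] = {}
    montage = get_montage(config.montage)
    rng = np.random.default_rng(config.seed)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:
                raise StageError(name, err) from err
            timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, timings[name])
            return out
        return wrap

    manifest = stage("manifest")(config.resolved_manifest)

    def load_all():
        recs = {}
        for _, row in manifest.iterrows():
            rec = read_recording(row["path"], montage=montage)
            if config.bandpass is not None:
                rec = bandpass_filter(rec, *config.bandpass)
            rec.subject_id = str(row["subject"])
            rec.condition = row["condition"]
            rec.side = row["side"]
            recs[(str(row["subject"]), row["condition"])] = rec
        return recs

    recordings = stage("load")(load_all)

    def peaks_all():
        out = {}
        for key, rec in recordings.items():
            gfp = global_field_power(rec)
            idx = find_gfp_peaks(gfp, config.min_separation_ms, config.smoothing_ms)
            out[key] = (idx, extract_peak_maps(rec, idx, source_id=str(key)))
        return out

    peaks = stage("gfp_peaks")(peaks_all)

    def cluster_all():
        k_range = range(1, config.k_max + 1)  # k=1 anchors the KL criterion
        quality = {}
        per_subject_sets: dict[tuple[str, str], dict[int, TemplateSet]] = {}
        choices = {}
        for key, (_, pmaps) in peaks.items():
            disp, ev, results = dispersion_curve(
                pmaps, k_range, montage=montage,
                n_restarts=config.n_restarts,
                seed=int(rng.integers(2**31)),
            )
            kl, chosen, fallback = krzanowski_lai(disp, montage.n_channels)
            chosen = max(chosen, config.k_min)
            quality[key] = {"W": disp, "ev": ev, "kl": kl,
                            "chosen_k": chosen, "kl_fallback": fallback}
            choices[key] = chosen
            per_subject_sets[key] = {
                k: results[k].template_set for k in k_range if k >= config.k_min
            }
        return quality, per_subject_sets, choices

    quality, per_subject_sets, choices = stage("individual_clustering")(cluster_all)

    # modal chosen k across all subject x condition datasets (ties -> smaller)
    vals, counts = np.unique(list(choices.values()), return_counts=True)
    chosen_k = int(vals[np.argmax(counts)])

    def meta_all():
        cond_sets = {}
        for cond in ("pre", "post"):
            sets = [per_subject_sets[key][chosen_k]
                    for key in per_subject_sets if key[1] == cond]
            raw = meta_cluster(sets, chosen_k, provenance=f"global-{cond}",
                               n_restarts=config.n_restarts,
                               seed=int(rng.integers(2**31)))
            cond_sets[cond] = canonical_label(raw)
        return cond_sets

    condition_templates = stage("meta_clustering")(meta_all)

    def tanova_stage():
        subjects = sorted({key[0] for key in per_subject_sets})
        u, v = [], []
        for subject in subjects:
            u.append(_match_to_global(per_subject_sets[(subject, "pre")][chosen_k],
                                      condition_templates["pre"]))
            v.append(_match_to_global(per_subject_sets[(subject, "post")][chosen_k],
                                      condition_templates["post"]))
        return tanova(np.stack(u), np.stack(v),
                      n_perm=config.tanova_permutations,
                      seed=int(rng.integers(2**31)),
                      labels=condition_templates["pre"].labels)

    tanova_result = stage("tanova")(tanova_stage)
    pooled = tanova_result.global_p > config.alpha

    def global_stage():
        if pooled:
            all_sets = [per_subject_sets[key][chosen_k] for key in per_subject_sets]
            raw = meta_cluster(all_sets, chosen_k, provenance="global",
                               n_restarts=config.n_restarts,
                               seed=int(rng.integers(2**31)))
            return canonical_label(raw)
        log.warning(
            "TANOVA significant (p=%.4f <= %.2f): conditions keep their own "
            "template sets", tanova_result.global_p, config.alpha,
        )
        return None

    global_set = stage("global_templates")(global_stage)

    def backfit_stage():
        sequences = {}
        for (subject, cond), rec in recordings.items():
            tset = global_set if pooled else condition_templates[cond]
            idx, _ = peaks[(subject, cond)]
            seq = backfit(rec, tset, idx)
            sequences[(subject, cond, rec.side)] = seq
        return metrics_table(sequences)

    metrics = stage("backfit_metrics")(backfit_stage)

    def stats_stage():
        reports = {}
        labels = (global_set or condition_templates["pre"]).labels
        pair_levels = tuple(
            f"{a}->{b}"
            for i, a in enumerate(labels) for b in labels[i + 1:]
        )
        for metric, targets, factor in (
            ("duration_ms", labels, "target"),
            ("occurrence_hz", labels, "target"),
            ("coverage_pct", labels, "target"),
            ("dp_pct", pair_levels, "target"),
        ):
            sub = metrics[(metrics["metric"] == metric)
                          & metrics["target"].isin(targets)].copy()
            bad = sub.loc[sub["value"].isna(), "subject"].unique()
            if len(bad):
                log.warning("dropping subjects with undefined %s: %s",
                            metric, sorted(map(str, bad)))
                sub = sub[~sub["subject"].isin(bad)]
            sides = tuple(pd.unique(sub["side"]))
            factors = {"condition": ("pre", "post"), factor: targets}
            if len(sides) > 1:
                factors["side"] = sides
            design = ARTDesign(response="value", factors=factors)
            reports[metric] = art_anova(sub, design)
        return reports

    art_reports = stage("group_stats")(stats_stage)

    result = PipelineResult(
        global_templates=global_set or condition_templates["pre"],
        condition_templates=condition_templates,
        chosen_k=chosen_k,
        k_choices=choices,
        quality=quality,
        tanova_result=tanova_result,
        conditions_pooled=pooled,
        metrics=metrics,
        art_reports=art_reports,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "timings_s": timings,
        },
    )
    if config.output_dir is not None:
        write_bundle(result, config.output_dir)
    return result


def write_bundle(result: PipelineResult, output_dir: str | Path) -> None:
    """Serialize the result bundle (TSV/JSON artifacts) to a directory."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tset = result.global_templates
    pd.DataFrame(tset.templates.T, columns=list(tset.labels),
                 index=list(tset.montage.names)).to_csv(
        out / "global_templates.tsv", sep="\t")
    result.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    quality = {
        f"{s}/{c}": {
            "W": {str(k): v for k, v in q["W"].items()},
            "explained_variance": {str(k): v for k, v in q["ev"].items()},
            "kl": {str(k): v for k, v in q["kl"].items()},
            "chosen_k": q["chosen_k"],
            "kl_fallback": q["kl_fallback"],
        }
        for (s, c), q in result.quality.items()
    }
    (out / "quality.json").write_text(json.dumps(quality, indent=2))
    (out / "tanova.json").write_text(json.dumps({
        "observed_gd": result.tanova_result.observed_gd,
        "p_values": result.tanova_result.p_values,
        "global_p": result.tanova_result.global_p,
        "n_perm": result.tanova_result.n_perm,
        "conditions_pooled": result.conditions_pooled,
    }, indent=2))
    art = {
        metric: rep.table.to_dict(orient="records")
        for metric, rep in result.art_reports.items()
    }
    (out / "art_anova.json").write_text(json.dumps(art, indent=2))
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
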