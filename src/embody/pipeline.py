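"""End-to-end orchestration: data -> group maps -> metrics -> associations.

`run_pipeline` executes the full analysis on either a synthetic cohort or a
loaded map collection, writes every table as CSV plus the per-emotion t-map
grids (and optional PNG renders), and logs seed, package versions and the
record counts surviving each stage so the run is auditable and exactly
reproducible from its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    MapCollection,
    harmonize_schizotypy,
    load_collection,
    load_mask,
    subject_z_frame,
)
from .groupmaps import group_tmaps, render_tmap, save_tmap_grids
from .masks import make_body_mask
from .metrics import congruency_scores, diffusion_table, metric_table, subject_summary
from .preprocess import screen_collection, smooth_collection
from .stats import (
    PREDICTORS,
    fit_clarity_zinb,
    fit_diffusion_lmm,
    results_frame,
    spearman_holm,
)
from .synth import SynthConfig, generate_collection

__all__ = ["PipelineConfig", "run_pipeline"]


def association_suite(
    metrics: pd.DataFrame,
    diffusion: pd.DataFrame,
    congruency: pd.DataFrame,
    subjects_z: pd.DataFrame,
    models: tuple[str, ...] = ("spearman", "lmm", "zinb"),
) -> pd.DataFrame:
    """All association models of the analysis, as one results table.

    Spearman + Holm for intensity and size (overall and split by arousal
    group) and for the four congruency outcomes; the crossed-intercept
    mixed model for diffusion (with the zeros-excluded refit); ZINB for
    mixed-pixel counts over all, high-arousal-only and low-arousal-only
    emotions.
    """
    results = []
    if "spearman" in models:
        overall = subject_summary(metrics).join(subjects_z)
        results += spearman_holm(overall, ["intensity"], family="outcome")
        results += spearman_holm(overall, ["size"], family="outcome")
        for arousal in ("low", "high"):
            sub = subject_summary(metrics, arousal=arousal).join(subjects_z)
            sub = sub.rename(columns={"intensity": f"intensity_{arousal}",
                                      "size": f"size_{arousal}"})
            results += spearman_holm(sub, [f"intensity_{arousal}"], family="outcome")
            results += spearman_holm(sub, [f"size_{arousal}"], family="outcome")
        cong = congruency.join(subjects_z)
        results += spearman_holm(cong, list(congruency.columns), family="block")
    if "lmm" in models:
        long = diffusion.merge(subjects_z, on="subject_id")
        results += fit_diffusion_lmm(long)
        results += fit_diffusion_lmm(long, exclude_zeros=True)
    if "zinb" in models:
        for arousal, label in ((None, "mixed_pixels_all"),
                               ("high", "mixed_pixels_high"),
                               ("low", "mixed_pixels_low")):
            summ = subject_summary(metrics, arousal=arousal).join(subjects_z)
            results += fit_clarity_zinb(summ["mixed_pixels"], summ,
                                        outcome_label=label)
    return results_frame(results)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, in one reproducible record."""

    out_dir: str | Path
    seed: int = 0
    # either a synthetic cohort spec ...
    synth: SynthConfig | None = None
    mask_scale: float = 0.25
    # ... or paths to an on-disk collection
    manifest_path: str | Path | None = None
    mask_path: str | Path | None = None
    subjects_path: str | Path | None = None
    # stage options
    smoothing_sigma: float = 6.0
    fdr_alpha: float = 0.05
    screen_action: str = "exclude"
    render_maps: bool = False
    models: tuple[str, ...] = ("spearman", "lmm", "zinb")


def _get_collection(config: PipelineConfig) -> MapCollection:
    if config.synth is not None:
        synth = SynthConfig(**{**config.synth.__dict__, "seed": config.seed})
        return generate_collection(synth, mask=make_body_mask(config.mask_scale))
    if config.manifest_path is None:
        raise ValueError("either a synthetic spec or a manifest is required")
    if config.mask_path is None:
        raise ValueError("mask required to load a collection")
    mask = load_mask(config.mask_path)
    return load_collection(config.manifest_path, mask, config.subjects_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screening, group maps, metrics and association models.

    Returns a report dict (also written to ``report.json``) recording the
    seed, version, stage-by-stage record counts and the paths of all output
    tables.  Any stage failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "embody_version": __version__,
                    "numpy_version": np.__version__, "stages": {}, "outputs": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    @stage("load")
    def collection() -> MapCollection:
        coll = _get_collection(config)
        report["stages"]["load"] = {"status": "ok", "n_subjects": len(coll.subjects),
                                    "n_maps": len(coll), "mask_pixels": coll.mask.n_body_pixels}
        return coll

    @stage("screen")
    def screened() -> MapCollection:
        coll, reports = screen_collection(collection, action=config.screen_action)
        flagged = [r for r in reports if r.flags]
        pd.DataFrame([{"subject_id": r.subject_id, "emotion": r.emotion,
                       "polarity": r.polarity, "flags": ";".join(sorted(r.flags)),
                       "painted_pixel_count": r.painted_pixel_count}
                      for r in reports]).to_csv(out / "screening.csv", index=False)
        report["outputs"]["screening"] = "screening.csv"
        report["stages"]["screen"] = {"status": "ok", "action": config.screen_action,
                                      "n_flagged": len(flagged),
                                      "n_maps_surviving": len(coll)}
        return coll

    @stage("harmonize")
    def subjects_z() -> pd.DataFrame:
        harmonized = harmonize_schizotypy(screened.subjects)
        screened.subjects = harmonized
        zf = subject_z_frame(harmonized)
        zf.to_csv(out / "subjects_z.csv")
        report["outputs"]["subjects_z"] = "subjects_z.csv"
        report["stages"]["harmonize"] = {"status": "ok", "n_subjects": len(zf)}
        return zf

    @stage("group_maps")
    def tmaps():
        smoothed = smooth_collection(screened, sigma=config.smoothing_sigma)
        maps = group_tmaps(smoothed, alpha=config.fdr_alpha)
        grid_dir = out / "tmaps"
        for emotion, tm in maps.items():
            save_tmap_grids(tm, grid_dir)
            if config.render_maps:
                render_tmap(tm, screened.mask, grid_dir / f"{emotion}.png")
        report["outputs"]["tmaps"] = "tmaps/"
        report["stages"]["group_maps"] = {
            "status": "ok", "alpha": config.fdr_alpha,
            "n_significant_pixels": {e: int(t.sig_grid.sum()) for e, t in maps.items()},
        }
        return maps

    @stage("metrics")
    def tables():
        metrics = metric_table(screened)
        diffusion = diffusion_table(screened)
        congruency = congruency_scores(screened)
        metrics.to_csv(out / "metrics.csv", index=False)
        diffusion.to_csv(out / "diffusion.csv", index=False)
        congruency.to_csv(out / "congruency.csv")
        report["outputs"].update(metrics="metrics.csv", diffusion="diffusion.csv",
                                 congruency="congruency.csv")
        report["stages"]["metrics"] = {"status": "ok", "n_metric_rows": len(metrics),
                                       "n_diffusion_rows": len(diffusion)}
        return metrics, diffusion, congruency

    @stage("associations")
    def associations() -> pd.DataFrame:
        metrics, diffusion, congruency = tables
        assoc = association_suite(metrics, diffusion, congruency, subjects_z,
                                  models=config.models)
        assoc.to_csv(out / "associations.csv", index=False)
        report["outputs"]["associations"] = "associations.csv"
        report["stages"]["associations"] = {"status": "ok", "n_tests": len(assoc)}
        return assoc

    report["status"] = "ok"
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
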