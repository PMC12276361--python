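"""End-to-end orchestration of the synthetic micro-irradiation experiment.

``run_synthetic_experiment`` chains the full analysis exactly as it is run
on real track tables: simulate per-timepoint track collections with a
damage profile -> length filter -> per-track classification -> restrict to
the immobile (chromatin-bound) class -> per-region mean-jump statistics ->
bootstrap/KDE/Yuen-Welch comparison of every timepoint against "before".
``run_analysis`` is the same downstream chain for externally produced
tables. All randomness flows from one root seed split deterministically
per stage; every number in the report is computed from the emitted
intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .config import PipelineConfig
from .classifier.baseline import baseline_classify_segments
from .classifier.model import classify_batch
from .jumpstats import compare_conditions, jump_summary
from .msd import effective_diffusion, ensemble_msd, fit_anomalous
from .synthetic import simulate_damage_experiment, write_ground_truth
from .tracks import RectROI, filter_by_length, filter_by_roi

logger = logging.getLogger(__name__)


def default_roi(cfg: PipelineConfig) -> RectROI:
    """Irradiated band: 3 μm wide, full field height, in the left field half."""
    width, height = cfg.simulation.field_size
    return RectROI(center=(width / 4.0, height / 2.0), width=3.0, height=height)


def _classify_tracks(tracks, cfg: PipelineConfig, truth=None, model=None,
                     render_cfg=None, classifier=None):
    method = classifier or cfg.classifier
    if method == "truth":
        if truth is None:
            raise ValueError("classifier='truth' requires ground-truth labels")
        return [truth[t.track_id] for t in tracks], method
    if method == "baseline":
        return [baseline_classify_segments(
            t, d_threshold=cfg.render.d_thresholds[0]).label
            for t in tracks], method
    if method == "cnn":
        if model is None:
            raise ValueError("classifier='cnn' requires a trained model")
        return [r.label for r in classify_batch(model, tracks,
                                                render_cfg or cfg.render)], method
    raise ValueError(f"unknown classifier {method!r}")


def _condition_summary(collections, cfg: PipelineConfig, roi: RectROI,
                       model=None) -> dict:
    """Per-timepoint, per-region jump summaries for the selected class."""
    out = {}
    for tp, coll in collections.items():
        table = filter_by_length(coll.to_table(), cfg.analysis.min_track_points)
        tracks = list(table.trajectories())
        labels, method = _classify_tracks(
            tracks, cfg, truth=coll.label_of(), model=model)
        proportions = {
            name: sum(lab == name for lab in labels) / max(len(labels), 1)
            for name in ("immobile", "hybrid", "mobile")
        }
        selected = [t.track_id for t, lab in zip(tracks, labels)
                    if lab == cfg.analysis.jump_class]
        sel_table = table.subset(selected)
        regions = {}
        for mode in ("inside", "outside"):
            sub = filter_by_roi(sel_table, roi, mode=mode)
            values = jump_summary(list(sub.trajectories()))
            regions[mode] = {"values": values, "n_tracks": int(len(values))}
        out[tp] = {"proportions": proportions, "regions": regions,
                   "classifier": method, "n_classified": len(tracks)}
    return out


def _comparisons(summary: dict, cfg: PipelineConfig, seed_seq) -> dict:
    before = summary["before"]["regions"]
    rows = {}
    post = [tp for tp in summary if tp != "before"]
    children = seed_seq.spawn(2 * len(post))
    for i, tp in enumerate(post):
        rows[tp] = {}
        for j, mode in enumerate(("inside", "outside")):
            rep = compare_conditions(
                before[mode]["values"], summary[tp]["regions"][mode]["values"],
                n_resamples=cfg.analysis.n_resamples,
                trim_fraction=cfg.analysis.trim_fraction,
                seed=children[2 * i + j],
            )
            rows[tp][mode] = {
                "ratio": rep.ratio,
                "ratio_ci_95": list(rep.ratio_ci),
                "p_value": rep.test.p_value,
                "statistic": rep.test.statistic,
                "df": rep.test.df,
                "significance": rep.significance,
                "mean_before": rep.bootstrap_before.point_estimate,
                "mean_after": rep.bootstrap_after.point_estimate,
                "ci_before": list(rep.bootstrap_before.ci),
                "ci_after": list(rep.bootstrap_after.ci),
            }
    return rows


def _msd_section(collections, cfg: PipelineConfig) -> dict:
    """Ensemble MSD + anomalous fit of the immobile class before damage."""
    coll = collections["before"].subset_by_label("immobile")
    tracks = [t for t in coll.tracks if t.n_points >= cfg.analysis.min_track_points]
    if not tracks:
        return {}
    curve = ensemble_msd(tracks, cfg.analysis.msd_max_lag,
                         min_tracks_per_lag=cfg.analysis.min_pairs_per_lag)
    fit = fit_anomalous(curve, min_pairs=cfg.analysis.min_pairs_per_lag)
    eff = effective_diffusion(curve, fit)
    return {
        "n_tracks": len(tracks),
        "alpha": fit.alpha, "A": fit.A, "sigma": fit.sigma,
        "r_squared": fit.r_squared,
        "D_first4": eff.D_first4, "D_tangent": eff.D_tangent,
    }


def run_synthetic_experiment(cfg: PipelineConfig, outdir=None,
                             model=None) -> dict:
    """Simulate and analyze a full micro-irradiation experiment.

    Returns the experiment report as a JSON-serializable dict; with
    ``outdir`` all intermediates (config, per-timepoint track tables and
    ground truth, report) are written alongside.
    """
    sim = cfg.simulation
    if sim.roi is None:
        from dataclasses import replace
        sim = replace(sim, roi=default_roi(cfg))
    root = np.random.SeedSequence(cfg.seed)
    sim_seed, cmp_seed = root.spawn(2)
    profile = {tp: cfg.jump_ratio_profile.get(tp, 1.0) for tp in cfg.timepoints}
    collections = simulate_damage_experiment(
        sim, jump_ratio_profile=profile, seed=sim_seed)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .tracks import write_tracks
        for tp, coll in collections.items():
            write_tracks(coll.to_table(timepoint=tp), outdir / f"tracks_{tp}.csv")
            write_ground_truth(coll, outdir / f"truth_{tp}.csv")
    summary = _condition_summary(collections, cfg, sim.roi, model=model)
    report = {
        "provenance": {"package_version": _version, "seed": cfg.seed,
                       "config": cfg.to_dict(), "roi": asdict(sim.roi)},
        "conditions": {
            tp: {"proportions": s["proportions"],
                 "classifier": s["classifier"],
                 "n_classified": s["n_classified"],
                 "regions": {m: {"n_tracks": r["n_tracks"],
                                 "mean_jump_um": float(np.mean(r["values"]))
                                 if r["n_tracks"] else None}
                             for m, r in s["regions"].items()}}
            for tp, s in summary.items()
        },
        "comparisons": _comparisons(summary, cfg, cmp_seed),
        "msd_before_immobile": _msd_section(collections, cfg),
    }
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonify)
    return report


def run_analysis(tables: dict, cfg: PipelineConfig, labels: dict | None = None,
                 images=None, model=None, classifier: str | None = None,
                 outdir=None) -> dict:
    """Analyze externally produced per-timepoint track tables.

    ``tables`` maps timepoint labels (must include "before") to
    ``TrackTable``s; ``labels`` optionally maps track_id to a class name,
    otherwise the configured classifier is invoked (an explicit
    ``classifier`` or ``model`` is then required). ``images`` may be a
    ``NucleusImageSeries`` for the thickness section. Jump sections are
    marked absent when no tables are supplied.
    """
    report: dict = {"provenance": {"package_version": _version,
                                   "seed": cfg.seed, "config": cfg.to_dict()}}
    if tables:
        if "before" not in tables:
            raise ValueError("tables must include the 'before' timepoint")
        if labels is None and classifier is None and model is None:
            raise ValueError(
                "supply per-track labels or a classifier (baseline/cnn+model)")
        roi = cfg.simulation.roi or default_roi(cfg)
        root = np.random.SeedSequence(cfg.seed)
        (cmp_seed,) = root.spawn(1)
        summary = {}
        for tp, table in tables.items():
            filtered = filter_by_length(table, cfg.analysis.min_track_points)
            tracks = list(filtered.trajectories())
            if labels is not None:
                got = [labels[t.track_id] for t in tracks]
                method = "labels"
            else:
                got, method = _classify_tracks(
                    tracks, cfg, model=model,
                    classifier=classifier or ("cnn" if model else "baseline"))
            selected = [t.track_id for t, lab in zip(tracks, got)
                        if lab == cfg.analysis.jump_class]
            sel_table = filtered.subset(selected)
            regions = {}
            for mode in ("inside", "outside"):
                sub = filter_by_roi(sel_table, roi, mode=mode)
                values = jump_summary(list(sub.trajectories()))
                regions[mode] = {"values": values, "n_tracks": int(len(values))}
            proportions = {
                name: sum(lab == name for lab in got) / max(len(got), 1)
                for name in ("immobile", "hybrid", "mobile")}
            summary[tp] = {"proportions": proportions, "regions": regions,
                           "classifier": method, "n_classified": len(tracks)}
        report["conditions"] = {
            tp: {"proportions": s["proportions"], "classifier": s["classifier"],
                 "n_classified": s["n_classified"],
                 "regions": {m: {"n_tracks": r["n_tracks"],
                                 "mean_jump_um": float(np.mean(r["values"]))
                                 if r["n_tracks"] else None}
                             for m, r in s["regions"].items()}}
            for tp, s in summary.items()}
        report["comparisons"] = _comparisons(summary, cfg, cmp_seed)
    else:
        report["conditions"] = None
        report["comparisons"] = None
    if images is not None:
        from .imaging import thickness_series
        ts = thickness_series(images)
        report["thickness"] = {
            "thickness_um": [None if not np.isfinite(v) else float(v)
                             for v in ts.thickness_um],
            "normalized": [None if not np.isfinite(v) else float(v)
                           for v in ts.normalized],
            "reference_frame": ts.reference_frame,
        }
    else:
        report["thickness"] = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonify)
    return report


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
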