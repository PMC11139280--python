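"""End-to-end orchestration: extract -> measure -> link -> summarize -> stats.

One declarative configuration drives every stage; no stage reads parameters
from anywhere else.  The pipeline is deterministic given inputs and seeds,
each stage is re-runnable on its own, and record counts are logged at every
filter so that n_annotated = n_other + n_after_exclusion and
n_after_exclusion = n_outliers + n_retained always reconcile.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from nodphon._version import __version__
from nodphon.annotation_analysis import (
    NodEvent,
    classify_turn,
    events_from_document,
    link_manual_items,
    summarize_distribution,
    summarize_durations,
    validate_nod_tier,
)
from nodphon.kinematics import (
    FilterSpec,
    PeakSpec,
    compute_nod_measures,
    detect_extrema,
    normalize_pose,
    smooth_trajectory,
)
from nodphon.pose_io import (
    AnnotationDocument,
    PoseSequence,
    read_annotation_document,
    read_pose_stream,
    write_measurements,
)
from nodphon.stats import (
    bootstrap_median_diff,
    compare_groups,
    compare_models,
    fit_function_model,
    pearson_with_ci,
    remove_outliers,
    z_score,
)
from nodphon.synthetic import SessionConfig, config_to_dict, simulate_session

DEFAULT_TIERS = {
    "form": "nod_form",
    "function": "nod_function",
    "turn": "nod_turn",
    "gloss": "gloss",
    "mouth": "mouth",
}

MEASURE_COLUMNS = [
    "signer", "nod_id", "start_ms", "end_ms", "form", "function", "turn",
    "turn_classified", "manual_status", "mouth_status",
    "duration_s", "velocity_npix_s", "max_amplitude_npix",
    "n_peaks", "n_troughs", "peak_rate_hz", "amplitude_fallback",
    "interpolated_fraction",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class RunResult:
    """Everything a pipeline run produces."""

    measures: pd.DataFrame
    duration_summary: pd.DataFrame
    distributions: dict[str, pd.DataFrame]
    stats_report: dict
    manifest: dict
    warnings: list[str] = field(default_factory=list)


def measure_session(
    sequences: Mapping[str, PoseSequence],
    documents: Mapping[str, AnnotationDocument],
    filter_spec: FilterSpec = FilterSpec(),
    peak_spec: PeakSpec = PeakSpec(),
    tier_map: Mapping[str, str] = DEFAULT_TIERS,
) -> pd.DataFrame:
    """Per-nod measurement table for a set of signers.

    For each signer: normalize the pose stream, smooth it once globally,
    detect extrema once, then measure every annotated nod and link it to
    co-occurring manual and mouth activity.  Turn-taking is taken from the
    turn tier when annotated and always re-derived from the gloss tier into
    ``turn_classified`` for cross-checking.
    """
    rows = []
    for signer in sorted(sequences):
        seq = sequences[signer]
        doc = documents[signer]
        form_name = tier_map["form"]
        if form_name not in doc.tiers:
            raise PipelineError("measure", f"signer {signer}: no {form_name!r} tier")
        try:
            events = events_from_document(
                doc.tier(form_name),
                doc.tiers.get(tier_map["function"], []),
                doc.tiers.get(tier_map["turn"], []),
                signer=signer,
            )
        except ValueError as exc:
            raise PipelineError("measure", f"signer {signer}: {exc}") from exc
        if not events:
            continue
        traj = smooth_trajectory(normalize_pose(seq), filter_spec)
        extrema = detect_extrema(traj, peak_spec)
        gloss = doc.tiers.get(tier_map["gloss"], [])
        mouth = doc.tiers.get(tier_map["mouth"], [])
        cooc = link_manual_items(events, gloss, mouth)
        for k, (event, link) in enumerate(zip(events, cooc)):
            try:
                m = compute_nod_measures(traj, event.span, peak_spec, extrema)
            except ValueError as exc:
                raise PipelineError(
                    "measure", f"signer {signer}, nod {k} at {event.span.start} ms: {exc}"
                ) from exc
            rows.append(
                {
                    "signer": signer,
                    "nod_id": f"{signer}_{k:03d}",
                    "start_ms": event.span.start,
                    "end_ms": event.span.end,
                    "form": event.form,
                    "function": event.function,
                    "turn": event.turn,
                    "turn_classified": classify_turn(event, gloss) if event.function != "other" else "unset",
                    "manual_status": link.manual_status,
                    "mouth_status": link.mouth_status,
                    "duration_s": m.duration,
                    "velocity_npix_s": m.velocity,
                    "max_amplitude_npix": m.max_amplitude,
                    "n_peaks": m.n_peaks,
                    "n_troughs": m.n_troughs,
                    "peak_rate_hz": m.peak_rate,
                    "amplitude_fallback": m.amplitude_fallback,
                    "interpolated_fraction": traj.interpolated_fraction,
                }
            )
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def _events_from_measures(measures: pd.DataFrame) -> list[NodEvent]:
    from nodphon.pose_io import AnnotationSpan

    return [
        NodEvent(
            span=AnnotationSpan(r.start_ms, r.end_ms, r.form),
            form=r.form, function=r.function,
            turn=r.turn if r.function != "other" else "unset",
            signer=r.signer,
        )
        for r in measures.itertuples()
    ]


def analyze_measures(
    measures: pd.DataFrame,
    seed: int,
    n_boot: int = 2000,
    outlier_k: float = 5.0,
) -> tuple[dict, list[str]]:
    """The statistical battery on a measurement table.

    Restricts to feedback/affirmation nods, z-scores the three kinematic
    variables, removes joint IQR-fence outliers, then runs the two-group
    comparisons, the velocity-amplitude correlation, the mixed-model
    likelihood-ratio ladder, and the bootstrap of the median z-velocity
    difference (feedback minus affirmation).
    """
    warnings: list[str] = []
    report: dict = {"counts": {"n_annotated": int(len(measures))}}
    analysis = measures[measures["function"].isin(["feedback", "affirmation"])].copy()
    report["counts"]["n_other_excluded"] = int(len(measures) - len(analysis))
    report["counts"]["n_after_exclusion"] = int(len(analysis))

    if len(analysis) < 8 or analysis["function"].nunique() < 2:
        warnings.append("too few feedback/affirmation nods for statistics")
        report["counts"]["n_outliers_removed"] = 0
        report["counts"]["n_retained"] = int(len(analysis))
        return report, warnings

    kin = ["duration_s", "velocity_npix_s", "max_amplitude_npix"]
    for col in kin:
        analysis["z_" + col] = z_score(analysis[col].to_numpy())
    retained, removed, fences = remove_outliers(analysis, kin, k=outlier_k)
    report["counts"]["n_outliers_removed"] = int(len(removed))
    report["counts"]["n_retained"] = int(len(retained))
    report["outlier_fences"] = {c: list(map(float, f)) for c, f in fences.items()}
    # z-scores are refreshed on the retained analysis set
    for col in kin:
        retained["z_" + col] = z_score(retained[col].to_numpy())
    retained["is_affirmation"] = (retained["function"] == "affirmation").astype(float)

    aff = retained[retained["function"] == "affirmation"]
    fb = retained[retained["function"] == "feedback"]
    report["group_comparisons"] = {}
    for col, label in zip(kin, ["duration", "velocity", "amplitude"]):
        c = compare_groups(aff[col].to_numpy(), fb[col].to_numpy(), measure=label)
        report["group_comparisons"][label] = {
            "t": c.t_statistic, "t_p": c.t_p, "t_stars": c.t_stars,
            "rank_sum": c.rank_sum, "u": c.u_statistic,
            "wilcoxon_p": c.wilcoxon_p, "wilcoxon_stars": c.wilcoxon_stars,
            "n_affirmation": c.n_a, "n_feedback": c.n_b,
            "sign_convention": "affirmation minus feedback",
        }

    r, ci = pearson_with_ci(
        retained["velocity_npix_s"].to_numpy(), retained["max_amplitude_npix"].to_numpy()
    )
    report["velocity_amplitude_correlation"] = {"r": r, "ci95": list(ci)}

    fits = {}
    for name, effects in [
        ("baseline", []),
        ("velocity", ["z_velocity_npix_s"]),
        ("duration", ["z_duration_s"]),
        ("amplitude", ["z_max_amplitude_npix"]),
    ]:
        fits[name] = fit_function_model(retained, effects)
        if not fits[name].converged:
            warnings.append(f"model {name!r} did not converge: {fits[name].message}")
    lrt = {}
    for small, large in [
        ("baseline", "velocity"), ("baseline", "duration"), ("baseline", "amplitude"),
    ]:
        res = compare_models(fits[small], fits[large])
        lrt[f"{large}_vs_{small}"] = {"chi2": res.chi2, "df": res.df, "p": res.p}
    report["model_comparisons"] = lrt
    vfit = fits["velocity"]
    report["velocity_model"] = {
        "formula": vfit.formula,
        "coef": vfit.coef, "se": vfit.se, "sigma_u": vfit.sigma_u,
        "loglik": vfit.loglik, "method": vfit.method,
        "per_signer_adjustment": vfit.group_effects,
    }

    boot = bootstrap_median_diff(
        fb["z_velocity_npix_s"].to_numpy(), aff["z_velocity_npix_s"].to_numpy(),
        n_boot=n_boot, seed=seed,
    )
    report["velocity_median_difference"] = {
        "observed": boot["observed"], "ci95": list(boot["ci"]),
        "n_boot": boot["n_boot"],
        "sign_convention": "feedback minus affirmation, z-velocity units",
    }
    return report, warnings


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> RunResult:
    """Run the full analysis described by one declarative configuration.

    The configuration either names pose/annotation inputs::

        inputs:
          fps: 50
          signers:
            - id: S00
              pose: path/to/openpose.json     # file or per-frame directory
              eaf: path/to/annotations.eaf

    or asks for a synthetic session (``simulate:`` holding SessionConfig
    fields).  ``seed`` feeds every downstream source of randomness.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    cfg = dict(config)
    seed = int(cfg.get("seed", 0))
    filter_spec = FilterSpec(**cfg.get("filter", {}))
    peaks_cfg = cfg.get("peaks", {})
    peak_spec = PeakSpec(
        min_prominence=peaks_cfg.get("min_prominence_npix", 0.1),
        min_separation=peaks_cfg.get("min_separation_frames", 5),
    )
    tier_map = {**DEFAULT_TIERS, **cfg.get("tiers", {})}
    warnings: list[str] = []
    started = time.time()

    if "simulate" in cfg:
        sim_cfg = SessionConfig(**{"seed": seed, **cfg["simulate"]})
        session = simulate_session(sim_cfg)
        sequences, documents = session.sequences, session.documents
        input_desc: dict = {"simulate": config_to_dict(sim_cfg)}
    elif "inputs" in cfg:
        fps = float(cfg["inputs"]["fps"])
        sequences, documents = {}, {}
        for entry in cfg["inputs"]["signers"]:
            sid = entry["id"]
            try:
                sequences[sid] = read_pose_stream(
                    entry["pose"], fps=fps,
                    participant_selector=entry.get("participant_index"),
                    participant_id=sid,
                )
                documents[sid] = read_annotation_document(entry["eaf"], participant_id=sid)
            except Exception as exc:
                raise PipelineError("extract", f"signer {sid}: {exc}") from exc
        input_desc = {"inputs": cfg["inputs"]}
    else:
        raise PipelineError("configure", "config needs a 'simulate' or 'inputs' section")

    for sid, doc in documents.items():
        form_tier = doc.tiers.get(tier_map["form"], [])
        for v in validate_nod_tier(form_tier):
            warnings.append(f"signer {sid}: {v.kind}: {v.message}")

    measures = measure_session(sequences, documents, filter_spec, peak_spec, tier_map)
    if measures.empty:
        warnings.append("no annotated nods; tables are empty")
        events = []
    else:
        events = _events_from_measures(measures)

    duration_summary = summarize_durations(events)
    distributions = summarize_distribution(events)
    stats_report, stat_warnings = analyze_measures(measures, seed=seed, n_boot=cfg.get("n_boot", 2000)) \
        if not measures.empty else ({"counts": {"n_annotated": 0}}, [])
    warnings.extend(stat_warnings)

    manifest = {
        "software": f"nodphon {__version__}",
        "seed": seed,
        "configuration": {
            "filter": {"order": filter_spec.order, "cutoff_hz": filter_spec.cutoff_hz},
            "peaks": {
                "min_prominence_npix": peak_spec.min_prominence,
                "min_separation_frames": peak_spec.min_separation,
            },
            "tiers": tier_map,
        },
        "input": input_desc,
        "timestamps": {"started": started, "finished": time.time()},
        "record_counts": stats_report.get("counts", {}),
        "warnings": warnings,
    }

    result = RunResult(
        measures=measures,
        duration_summary=duration_summary,
        distributions=distributions,
        stats_report=stats_report,
        manifest=manifest,
        warnings=warnings,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: RunResult, out_dir: str | Path) -> None:
    """Write the report bundle: measures CSV, summary CSVs, JSON reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "software": result.manifest["software"],
        "seed": result.manifest["seed"],
        "filter.order": result.manifest["configuration"]["filter"]["order"],
        "filter.cutoff_hz": result.manifest["configuration"]["filter"]["cutoff_hz"],
        "peaks.min_prominence_npix": result.manifest["configuration"]["peaks"]["min_prominence_npix"],
        "peaks.min_separation_frames": result.manifest["configuration"]["peaks"]["min_separation_frames"],
        "velocity_unit": "npix_per_second",
    }
    write_measurements(result.measures, out / "measures.csv", metadata=meta)
    result.duration_summary.to_csv(out / "duration_by_form.csv", index=False)
    for name, table in result.distributions.items():
        table.to_csv(out / f"distribution_{name}.csv")
    (out / "stats_report.json").write_text(json.dumps(result.stats_report, indent=2, default=float))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=float))
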