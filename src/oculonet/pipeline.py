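"""End-to-end orchestration: simulate → detect → score → stats → network.

A run is described by a :class:`RunConfig` (JSON/YAML-compatible mapping)
holding either a simulation block or input paths, plus stage parameters
and a seed.  Stages execute in the analysis order of the study this
package models: trial scoring applies the latency filter, influence-based
subject exclusion precedes the accuracy–latency correlations, and the
network is built on the patient group only.  Every artifact is a plain
CSV / GraphML / JSON file in the output directory and the whole run is
bit-reproducible from config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .events import DetectionParams, GazeRecording, detect_events, events_to_dataframe
from .exceptions import ComputationError, SummaryError
from .measures import COGNITIVE_MEASURES, DOMAINS
from .network import CorrelationNetworkModel, CorrelationNetworkResults
from .scoring import ScoringParams, score_trial, summaries_to_dataframe, summarize_subject
from .simulate import SimulationConfig, generate_gaze_trace, simulate_cohort
from .stats import InfluenceCutoffs, pearson, regression_influence, students_t, variance_f_test

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

logger = logging.getLogger("oculonet")


def _package_version() -> str:
    try:
        return _pkg_version("oculonet")
    except Exception:
        return "unknown"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (cohort-simulation settings) or
    ``inputs`` (paths to existing artifacts, or ``{"tables": "packaged"}``
    for the published correlation tables) must be present.
    """

    outdir: str = "run"
    seed: int = 0
    simulation: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    detection: dict[str, Any] = field(default_factory=dict)
    scoring: dict[str, Any] = field(default_factory=dict)
    alpha: float = 0.05
    tau: float = 0.4
    group_filter: str = "patient"
    influence_cutoffs: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulation' and 'inputs' must be configured"
            )
        if self.inputs is not None:
            for key, path in self.inputs.items():
                if key == "tables" and path == "packaged":
                    continue
                if not Path(path).exists():
                    raise ValueError(f"input {key!r}: no such file {path!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, Mapping):
            raise ValueError(f"config {path} must hold a mapping")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **(self.simulation or {}))

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)

    def scoring_params(self) -> ScoringParams:
        sc = dict(self.scoring)
        if "latency_window_ms" in sc:
            sc["latency_window_ms"] = tuple(sc["latency_window_ms"])
        return ScoringParams(**sc)


@dataclass
class RunReport:
    """Reproducible record of one run."""

    seed: int
    config: dict[str, Any]
    config_hash: str
    version: str
    stage_counts: dict[str, Any] = field(default_factory=dict)
    exclusions: list[dict[str, Any]] = field(default_factory=list)
    statistics: dict[str, Any] = field(default_factory=dict)
    network_summary: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _test_result_dict(res) -> dict[str, Any]:
    return {
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "n": res.n,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all configured stages; returns the run report.

    Artifacts land in ``config.outdir``.  A stage failure raises with the
    stage name; artifacts written so far are kept alongside a
    ``FAILED_<stage>`` marker file.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        seed=config.seed,
        config=config.to_dict(),
        config_hash=config.config_hash(),
        version=_package_version(),
    )
    stage = "init"
    try:
        if config.inputs is not None and config.inputs.get("tables") == "packaged":
            stage = "network"
            _network_stage_from_tables(config, outdir, report)
        else:
            if config.simulation is not None:
                stage = "simulate"
                cohort, recordings = _simulate_stage(config, outdir, report)
                stage = "detect"
                events_by_trial = _detect_stage(config, recordings, outdir, report)
                stage = "score"
                summary_df = _score_stage(
                    config, cohort, events_by_trial, outdir, report
                )
                measures_df = _merge_measures(cohort, summary_df)
            else:
                stage = "load"
                measures_df = pd.read_csv(config.inputs["measures"])
                report.stage_counts["load"] = {"subjects": len(measures_df)}
            stage = "stats"
            _stats_stage(config, measures_df, outdir, report)
            stage = "network"
            _network_stage(config, measures_df, outdir, report)
        stage = "report"
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.txt").write_text(_human_report(report))
    except Exception as exc:
        (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _simulate_stage(config: RunConfig, outdir: Path, report: RunReport):
    sim = config.simulation_config()
    cohort = simulate_cohort(sim, seed=config.seed)
    cohort.measures.to_csv(outdir / "measures.csv", index=False)
    cog = cohort.measures[["subject_id", "group", *COGNITIVE_MEASURES]]
    cog.to_csv(outdir / "scores.csv", index=False)

    trial_rows = []
    truth_rows = []
    recordings: list[tuple[str, str, GazeRecording, Any, Any]] = []
    rng_root = np.random.SeedSequence([config.seed, 0xA5])
    gaze_frames = []
    trial_seeds = iter(rng_root.spawn(len(cohort.measures) * 160 + 16))
    for sid in cohort.subject_ids:
        for task in ("AS", "GnG"):
            for k, (trial, outcome) in enumerate(
                zip(cohort.designs[sid][task], cohort.outcomes[sid][task])
            ):
                tid = f"{task}{k:03d}"
                rec = generate_gaze_trace(
                    trial,
                    outcome,
                    next(trial_seeds),
                    sampling_rate=sim.sampling_rate,
                    noise_sd=sim.noise_sd,
                    subject_id=sid,
                    trial_id=tid,
                )
                recordings.append((sid, tid, rec, trial, outcome))
                gaze_frames.append(rec.to_dataframe())
                trial_rows.append(
                    {
                        "subject_id": sid,
                        "trial_id": tid,
                        "task": trial.task,
                        "condition": trial.condition,
                        "ps_x_deg": trial.ps_x_deg,
                        "ps_y_deg": trial.ps_y_deg,
                        "ps_onset_ms": trial.ps_onset_ms,
                    }
                )
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "trial_id": tid,
                        "label": outcome.label,
                        "latency_ms": outcome.latency_ms,
                    }
                )
    pd.DataFrame(trial_rows).to_csv(outdir / "trials.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    pd.concat(gaze_frames, ignore_index=True).to_csv(
        outdir / "gaze.csv", index=False
    )
    report.stage_counts["simulate"] = {
        "subjects": len(cohort.measures),
        "trials": len(trial_rows),
    }
    logger.info("simulated %d subjects, %d trials", len(cohort.measures), len(trial_rows))
    return cohort, recordings


def _detect_stage(config: RunConfig, recordings, outdir: Path, report: RunReport):
    params = config.detection_params()
    frames = []
    events_by_trial = {}
    n_events = 0
    for sid, tid, rec, trial, outcome in recordings:
        evs = detect_events(rec, params)
        events_by_trial[(sid, tid)] = (trial, evs)
        frames.append(events_to_dataframe(evs, sid, tid))
        n_events += len(evs)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "events.csv", index=False)
    report.stage_counts["detect"] = {
        "trials": len(events_by_trial),
        "events": n_events,
    }
    return events_by_trial


def _score_stage(config: RunConfig, cohort, events_by_trial, outdir: Path, report: RunReport):
    params = config.scoring_params()
    score_rows = []
    summaries = []
    discarded = 0
    by_subject: dict[str, dict[str, list]] = {}
    group_of = dict(
        zip(cohort.measures["subject_id"], cohort.measures["group"])
    )
    for (sid, tid), (trial, evs) in events_by_trial.items():
        score = score_trial(trial, evs, params, trial_id=tid)
        discarded += score.classification == "discarded"
        by_subject.setdefault(sid, {"AS": [], "GnG": []})[trial.task].append(score)
        score_rows.append(
            {
                "subject_id": sid,
                "trial_id": tid,
                "task": score.task,
                "condition": score.condition,
                "classification": score.classification,
                "latency_ms": score.latency_ms,
                "discard_reason": score.discard_reason,
            }
        )
    for sid, per_task in by_subject.items():
        try:
            summaries.append(
                summarize_subject(
                    sid,
                    group_of[sid],
                    per_task["AS"],
                    per_task["GnG"],
                    params.count_discarded_in_pa,
                )
            )
        except (SummaryError, ComputationError) as exc:
            logger.warning("subject %s dropped from summaries: %s", sid, exc)
    pd.DataFrame(score_rows).to_csv(outdir / "trial_scores.csv", index=False)
    summary_df = summaries_to_dataframe(summaries)
    summary_df.to_csv(outdir / "subject_summary.csv", index=False)
    report.stage_counts["score"] = {
        "trials": len(score_rows),
        "discarded_by_latency": int(discarded),
        "subjects_summarized": len(summary_df),
    }
    return summary_df


def _merge_measures(cohort, summary_df: pd.DataFrame) -> pd.DataFrame:
    """Join simulated cognitive scores with scored oculomotor summaries."""
    cog = cohort.measures[["subject_id", "group", *COGNITIVE_MEASURES]]
    ocu = summary_df[
        ["subject_id", "as_pa", "go_pa", "nogo_pa",
         "ASLs", "ASELs", "ASEs", "GnGLs", "GnGELs", "GnGEs"]
    ]
    return cog.merge(ocu, on="subject_id", how="inner")


def _stats_stage(config: RunConfig, measures: pd.DataFrame, outdir: Path, report: RunReport):
    stats: dict[str, Any] = {}
    cuts = InfluenceCutoffs(**config.influence_cutoffs)
    has_pa = "as_pa" in measures.columns

    if "group" in measures.columns and measures["group"].nunique() == 2:
        pat = measures[measures["group"] == "patient"]
        ctl = measures[measures["group"] == "control"]
        for col in ("ASLs", "GnGLs"):
            a = pat[col].dropna().to_numpy()
            b = ctl[col].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                stats[f"t_{col}_patients_vs_controls"] = _test_result_dict(
                    students_t(a, b)
                )
                stats[f"F_{col}_patients_vs_controls"] = _test_result_dict(
                    variance_f_test(a, b)
                )

    # influence-based exclusion precedes the accuracy-latency correlation
    for group, sub in measures.groupby("group") if "group" in measures else []:
        pa_col = "as_pa" if has_pa else None
        if pa_col is None or sub[pa_col].isna().all():
            continue
        pair = sub[[pa_col, "ASLs"]].dropna()
        if len(pair) < 4 or pair[pa_col].nunique() < 2:
            continue
        infl = regression_influence(
            pair[pa_col].to_numpy(), pair["ASLs"].to_numpy(), cuts
        )
        keep = ~infl.flagged
        ids = sub.loc[pair.index, "subject_id"].to_numpy()
        for i in infl.flagged_indices:
            report.exclusions.append(
                {
                    "subject_id": str(ids[i]),
                    "group": group,
                    "reasons": list(infl.reasons[i]),
                }
            )
        kept = pair[keep]
        if len(kept) >= 3 and kept[pa_col].nunique() > 1 and kept["ASLs"].nunique() > 1:
            stats[f"pearson_ASL_vs_AS_PA_{group}"] = _test_result_dict(
                pearson(kept[pa_col].to_numpy(), kept["ASLs"].to_numpy())
            )
    (outdir / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True, default=_jsonify)
    )
    report.statistics = stats
    report.stage_counts["stats"] = {
        "tests": len(stats),
        "excluded_subjects": len(report.exclusions),
    }


def _network_outputs(config: RunConfig, results: CorrelationNetworkResults, outdir: Path, report: RunReport):
    full = results.full_network(config.alpha)
    thr = results.thresholded_network(config.tau)
    results.corr.to_csv(outdir / "correlations.csv")
    full.export(outdir / "network_full.graphml")
    thr.export(outdir / "network_thresholded.graphml")
    thr.export(outdir / "network_thresholded_edges.csv", format="edge-list")
    cent = pd.concat(
        [
            full.centrality_table().assign(network="full"),
            thr.centrality_table().assign(network="thresholded"),
        ],
        ignore_index=True,
    )
    cent.to_csv(outdir / "centrality.csv", index=False)
    report.network_summary = {
        "full_edges": full.n_edges,
        "full_cross_domain_edges": full.n_cross_domain_edges,
        "full_central_nodes": sorted(full.central_nodes()) if full.n_edges else [],
        "thresholded_edges": thr.n_edges,
        "thresholded_cross_domain_edges": thr.n_cross_domain_edges,
        "thresholded_central_nodes": sorted(thr.central_nodes())
        if thr.n_edges
        else [],
    }
    report.stage_counts["network"] = {
        "nodes": full.graph.number_of_nodes(),
        "full_edges": full.n_edges,
        "thresholded_edges": thr.n_edges,
    }


def _network_stage(config: RunConfig, measures: pd.DataFrame, outdir: Path, report: RunReport):
    model = CorrelationNetworkModel.from_dataframe(
        measures, DOMAINS, group=config.group_filter
    )
    results = model.fit()
    _network_outputs(config, results, outdir, report)


def _network_stage_from_tables(config: RunConfig, outdir: Path, report: RunReport):
    results = CorrelationNetworkResults.from_printed_tables()
    _network_outputs(config, results, outdir, report)


def _human_report(report: RunReport) -> str:
    lines = [
        "oculonet run report",
        "===================",
        f"version: {report.version}   seed: {report.seed}   config: {report.config_hash}",
        "",
        "stage counts:",
    ]
    for stage, counts in report.stage_counts.items():
        lines.append(f"  {stage}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    if report.exclusions:
        lines.append("")
        lines.append("excluded subjects (influence diagnostics):")
        for ex in report.exclusions:
            lines.append(
                f"  {ex['subject_id']} ({ex['group']}): {', '.join(ex['reasons'])}"
            )
    if report.statistics:
        lines.append("")
        lines.append("statistics:")
        for name, res in report.statistics.items():
            lines.append(
                f"  {name}: stat={res['statistic']:.3f}, p={res['p_value']:.4g}"
            )
    if report.network_summary:
        ns = report.network_summary
        lines.append("")
        lines.append(
            f"network: full {ns['full_edges']} edges "
            f"({ns['full_cross_domain_edges']} cross-domain), "
            f"thresholded {ns['thresholded_edges']} edges "
            f"({ns['thresholded_cross_domain_edges']} cross-domain)"
        )
        lines.append(
            f"central nodes: full={ns['full_central_nodes']}, "
            f"thresholded={ns['thresholded_central_nodes']}"
        )
    lines.append("")
    return "\n".join(lines)
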