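"""End-to-end analysis: runs in, lameness report out.

Ties the stages together: read (or receive) pressure-mat runs, segment
each into paw contacts, apply run QC, compute per-run symmetry ratios,
summarise per animal and day, build the physiological range from the
preoperative days, classify postoperative values against it, test
timepoint differences, and relate the instrument to the visual score.
Every input run appears in the report exactly once — either with metrics
or with its rejection reason, mirroring how evaluable runs are accounted
for in a study log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats
from .mat_io import FrameSequence, read_frame_sequence, read_scores
from .metrics import run_metrics
from .segmentation import AmbiguousDirectionError, SegmentationConfig, segment_run
from .stats import PhysiologicalRange

__all__ = [
    "PipelineConfig",
    "load_config",
    "process_run",
    "analyze_runs",
    "analyze_cohort",
    "write_report",
    "load_runs",
]

PREOP_POOLED = "preop_pooled"


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters with their defaults; YAML-overridable.

    ``preop_sessions`` empty means "every session whose id starts with
    'preop'"; ``comparisons`` empty means the standard set — pooled
    preoperative against each postoperative session and the postoperative
    sessions against each other.
    """

    threshold_kpa: float | None = None
    connectivity: int = 26
    min_pair_overlap: float = 0.5
    max_single_paw_area: int = 40
    max_stance_frames: int = 6
    track_axis: str = "cols"
    direction_slope_tol: float = 0.05
    q_low: float = 2.5
    q_high: float = 97.5
    wilcoxon_mode: str = "auto"
    preop_sessions: tuple[str, ...] = ()
    comparisons: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            threshold_kpa=self.threshold_kpa,
            connectivity=self.connectivity,
            min_pair_overlap=self.min_pair_overlap,
            max_single_paw_area=self.max_single_paw_area,
            max_stance_frames=self.max_stance_frames,
            track_axis=self.track_axis,
            direction_slope_tol=self.direction_slope_tol,
        )


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file.

    File values override defaults; keyword overrides beat the file.
    Unknown keys are rejected rather than silently ignored.
    """
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a key-value mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("preop_sessions",):
        if key in values and values[key] is not None:
            values[key] = tuple(values[key])
    if "comparisons" in values and values["comparisons"] is not None:
        values["comparisons"] = tuple(tuple(p) for p in values["comparisons"])
    return PipelineConfig(**values)


def process_run(seq: FrameSequence, config: PipelineConfig = PipelineConfig()) -> dict:
    """Segment and measure one run; never raises for a rejectable run.

    Returns a record with identification, QC outcome and (for accepted
    runs) the load metrics.  An unresolvable travel direction is reported
    as rejection reason ``ambiguous_direction`` rather than an exception,
    so a cohort analysis can keep going.
    """
    run_id = seq.meta.get("run", "")
    record: dict = {
        "run_id": run_id,
        "animal_id": seq.meta.get("animal", ""),
        "session_id": seq.meta.get("session", ""),
        "qc_accepted": False,
        "qc_reasons": "",
    }
    try:
        contacts, pair, qc, direction = segment_run(seq, config.segmentation())
    except AmbiguousDirectionError:
        record["qc_reasons"] = "ambiguous_direction"
        return record
    record["direction"] = direction
    record["n_contacts"] = len(contacts)
    record["qc_accepted"] = qc.accepted
    record["qc_reasons"] = ";".join(qc.reasons)
    if qc.accepted and pair is not None:
        m = run_metrics(
            pair,
            seq.grid,
            run_id=run_id,
            animal_id=record["animal_id"],
            session_id=record["session_id"],
        )
        record.update(
            peak_pressure_left=m.peak_pressure_left,
            peak_pressure_right=m.peak_pressure_right,
            tfi_left=m.tfi_left,
            tfi_right=m.tfi_right,
            ratio_pressure=m.ratio_pressure,
            ratio_force=m.ratio_force,
        )
    return record


def analyze_runs(
    seqs: list[FrameSequence], config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Per-run table over a collection of runs, accepted and rejected."""
    if not seqs:
        raise ValueError("no runs to analyze")
    return pd.DataFrame([process_run(seq, config) for seq in seqs])


def _preop_ids(session_ids, config: PipelineConfig) -> list[str]:
    if config.preop_sessions:
        return [s for s in config.preop_sessions if s in set(session_ids)]
    return sorted(s for s in set(session_ids) if str(s).startswith("preop"))


def _with_pooled_preop(summaries: pd.DataFrame, preop: list[str]) -> pd.DataFrame:
    """Append a pooled pseudo-session of per-animal across-day means."""
    pooled = (
        summaries[summaries["session_id"].isin(preop)]
        .groupby("animal_id", as_index=False)
        .agg(
            n_runs=("n_runs", "sum"),
            mean_ratio_pressure=("mean_ratio_pressure", "mean"),
            mean_ratio_force=("mean_ratio_force", "mean"),
        )
    )
    pooled["session_id"] = PREOP_POOLED
    pooled["sd_ratio_pressure"] = np.nan
    pooled["sd_ratio_force"] = np.nan
    return pd.concat([summaries, pooled[summaries.columns]], ignore_index=True)


def analyze_cohort(
    seqs: list[FrameSequence],
    scores: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Full study analysis over a collection of runs.

    Returns a report dictionary with: the per-run table (``runs``),
    per-animal/day summaries, per-metric cohort tables, physiological
    ranges with per-session in-range fractions, timepoint comparisons and
    (when scores are supplied) instrument-vs-score agreement.
    """
    run_table = analyze_runs(seqs, config)
    accepted = run_table[run_table["qc_accepted"]]
    if accepted.empty:
        raise ValueError("no accepted runs in the cohort")
    summaries = stats.session_summaries(run_table)
    session_ids = list(dict.fromkeys(run_table["session_id"]))
    preop = _preop_ids(session_ids, config)
    postop = [s for s in session_ids if s not in preop and s in set(accepted["session_id"])]

    report: dict = {
        "runs": run_table,
        "summaries": summaries,
        "preop_sessions": preop,
        "postop_sessions": postop,
        "n_runs": int(len(run_table)),
        "n_accepted": int(accepted.shape[0]),
        "rejections": run_table.loc[~run_table["qc_accepted"], ["run_id", "qc_reasons"]],
    }

    ranges: dict[str, PhysiologicalRange] = {}
    in_range: list[dict] = []
    if preop:
        for metric in stats.RATIO_METRICS:
            preop_mask = accepted["session_id"].isin(preop)
            values = accepted.loc[preop_mask, metric].to_numpy()
            prange = stats.physiological_range(values, metric, config.q_low, config.q_high)
            ranges[metric] = prange
            for sid in session_ids:
                singles = accepted.loc[accepted["session_id"] == sid, metric].to_numpy()
                means = summaries.loc[
                    summaries["session_id"] == sid, f"mean_{metric}"
                ].to_numpy()
                if singles.size == 0:
                    continue
                _, frac_single = stats.classify_in_range(singles, prange)
                _, frac_mean = stats.classify_in_range(means, prange)
                in_range.append(
                    {
                        "metric": metric,
                        "session_id": sid,
                        "n_single": int(singles.size),
                        "fraction_single_in_range": frac_single,
                        "n_mean": int(means.size),
                        "fraction_mean_in_range": frac_mean,
                    }
                )
        report["cohort_tables"] = {
            metric: stats.cohort_table(summaries, run_table, session_ids, metric, preop)
            for metric in stats.RATIO_METRICS
        }
    report["physiological_ranges"] = ranges
    report["in_range"] = pd.DataFrame(in_range)

    comparisons = list(config.comparisons)
    summaries_aug = summaries
    if not comparisons and preop and postop:
        summaries_aug = _with_pooled_preop(summaries, preop)
        comparisons = [(PREOP_POOLED, s) for s in postop]
        comparisons += [
            (postop[i], postop[j])
            for i in range(len(postop))
            for j in range(i + 1, len(postop))
        ]
    elif comparisons:
        summaries_aug = _with_pooled_preop(summaries, preop) if preop else summaries
    if comparisons:
        report["comparisons"] = stats.compare_timepoints(
            summaries_aug, comparisons, mode=config.wilcoxon_mode
        )

    if scores is not None and postop:
        report["scores"] = scores
        post_scores = scores[scores["session_id"].isin(postop)]
        post_summaries = summaries[summaries["session_id"].isin(postop)]
        if not post_scores.empty:
            try:
                report["score_agreement"] = stats.score_agreement(post_scores, post_summaries)
            except stats.UndefinedStatisticError as exc:
                warnings.warn(f"score agreement undefined: {exc}", stacklevel=2)
                report["score_agreement"] = None
    return report


def save_plots(report: dict, outdir) -> list:
    """Write diagnostic figures: per-day boxplots and score scatter plots.

    Returns the paths written.  Boxplots show the per-animal day means of
    each ratio; the scatter relates postoperative visual scores to mean
    ratios, the physiological range shaded.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    summaries = report["summaries"]
    sessions = report["preop_sessions"] + report["postop_sessions"]
    for metric in stats.RATIO_METRICS:
        fig, ax = plt.subplots(figsize=(6, 4))
        data = [
            summaries.loc[summaries["session_id"] == sid, f"mean_{metric}"].to_numpy()
            for sid in sessions
        ]
        ax.boxplot(data, tick_labels=sessions)
        prange = report["physiological_ranges"].get(metric)
        if prange is not None:
            ax.axhspan(prange.lower, prange.upper, alpha=0.15)
        ax.set_ylabel(f"mean {metric}")
        ax.set_ylim(-1.05, 1.05)
        fig.autofmt_xdate(rotation=30)
        path = outdir / f"boxplot_{metric}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    scores = report.get("scores")
    if scores is not None and report.get("score_agreement"):
        merged = scores.merge(summaries, on=["animal_id", "session_id"], how="inner")
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, metric in zip(axes, stats.RATIO_METRICS):
            ax.scatter(merged["score"], merged[f"mean_{metric}"], alpha=0.7)
            prange = report["physiological_ranges"].get(metric)
            if prange is not None:
                ax.axhspan(prange.lower, prange.upper, alpha=0.15)
            res = report["score_agreement"][metric]
            ax.set_title(f"rho={res['rho']:.3f}, R^2={res['r_squared']:.3f}")
            ax.set_xlabel("lameness score")
            ax.set_ylabel(f"mean {metric}")
        path = outdir / "score_scatter.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def load_runs(metadata_path) -> list[FrameSequence]:
    """Load every run listed in a metadata CSV (paths relative to it)."""
    base = Path(metadata_path).parent
    metadata = pd.read_csv(metadata_path, dtype=str)
    return [read_frame_sequence(base / p) for p in metadata["path"]]


def _range_to_dict(prange: PhysiologicalRange) -> dict:
    return asdict(prange)


def write_report(report: dict, outdir) -> None:
    """Persist a report as CSV tables plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["runs"].to_csv(outdir / "run_metrics.csv", index=False)
    report["summaries"].to_csv(outdir / "session_summaries.csv", index=False)
    report["rejections"].to_csv(outdir / "rejected_runs.csv", index=False)
    if not report["in_range"].empty:
        report["in_range"].to_csv(outdir / "in_range_fractions.csv", index=False)
    for metric, table in report.get("cohort_tables", {}).items():
        table.to_csv(outdir / f"cohort_table_{metric}.csv", index=False)
    if "comparisons" in report:
        report["comparisons"].to_csv(outdir / "timepoint_comparisons.csv", index=False)
    summary = {
        "n_runs": report["n_runs"],
        "n_accepted": report["n_accepted"],
        "preop_sessions": report["preop_sessions"],
        "postop_sessions": report["postop_sessions"],
        "physiological_ranges": {
            m: _range_to_dict(r) for m, r in report["physiological_ranges"].items()
        },
    }
    agreement = report.get("score_agreement")
    if agreement:
        summary["score_agreement"] = {
            metric: {
                "rho": res["rho"],
                "r_squared": res["r_squared"],
                "n": res["n"],
                "per_score": res["per_score"].to_dict(orient="records"),
            }
            for metric, res in agreement.items()
        }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
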