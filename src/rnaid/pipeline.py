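"""End-to-end analysis: trace -> events -> annotations -> sized events -> summary.

Thin orchestration over the stage modules, shared by the command-line
interface, the tests and the reproduction script.  All stage thresholds are
gathered in :class:`AnalysisConfig` so a run is fully described by (trace,
design, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import IDDesign
from .events import (
    ECD_MAX_FC,
    MAX_MEAN_DROP_PA,
    MIN_DURATION_MS,
    EventRecord,
    Trace,
    detect_events,
    estimate_baseline,
    filter_events,
)
from .population import PopulationSummary, summarize_classes
from .simulate import SimParams, simulate_trace
from .sizing import SizedEvent, size_and_classify
from .spikes import (
    EventAnnotation,
    annotate_event,
    classify_spikes,
    compute_population_stats,
    detect_spikes,
    flag_folded,
)

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_trace", "simulate_dataset"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Detection / classification thresholds for one pipeline run.

    ``baseline_pA`` / ``noise_sd_pA`` override the robust estimates when
    set; all other defaults are the module defaults documented with each
    stage.
    """

    baseline_pA: float | None = None
    noise_sd_pA: float | None = None
    k_sigma: float = 5.0
    floor_pA: float = 50.0
    min_gap_ms: float = 0.02
    ecd_max_fC: float = ECD_MAX_FC
    min_duration_ms: float = MIN_DURATION_MS
    max_mean_drop_pA: float = MAX_MEAN_DROP_PA
    spike_k_sigma: float = 4.0
    spike_prominence_frac: float = 0.3
    spike_min_width_samples: int = 3
    r_ratio: float = 1.5
    fold_ratio: float = 1.7
    fold_min_frac: float = 0.10
    fold_resid_nsd: float = 3.0
    tau_tail_kbp: float = 0.8
    tau_oric_kbp: float = 0.5
    hist_bin_kbp: float = 0.1


@dataclass
class AnalysisResult:
    baseline_pA: float
    noise_sd_pA: float
    events: pd.DataFrame          # every detected event with kept flag / reject reason
    annotations: list[EventAnnotation]
    sized: pd.DataFrame           # one row per kept event
    summary: PopulationSummary


def _events_df(
    events: list[EventRecord], kept: list[EventRecord], reasons: dict[int, str]
) -> pd.DataFrame:
    kept_ids = {e.event_id for e in kept}
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "start_ms": [e.start_ms for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "mean_drop_pA": [e.mean_drop_pA for e in events],
            "ecd_fC": [e.ecd_fC for e in events],
            "start_idx": [e.start_idx for e in events],
            "end_idx": [e.end_idx for e in events],
            "kept": [e.event_id in kept_ids for e in events],
            "reject_reason": [reasons.get(e.event_id, "") for e in events],
        }
    )


def annotate_events(
    trace: Trace,
    kept: list[EventRecord],
    design: IDDesign,
    baseline_pA: float,
    noise_sd_pA: float,
    config: AnalysisConfig,
) -> list[EventAnnotation]:
    """Spike-call, classify, fold-flag and orient every kept event."""
    dt = trace.sample_interval_ms
    per_event = []
    for ev in kept:
        seg = trace.samples[ev.start_idx : ev.end_idx]
        plateau_drop, raw = detect_spikes(
            seg,
            dt,
            baseline_pA,
            noise_sd_pA,
            k_sigma=config.spike_k_sigma,
            prominence_frac=config.spike_prominence_frac,
            min_width_samples=config.spike_min_width_samples,
        )
        per_event.append((ev, seg, plateau_drop, classify_spikes(raw, r_ratio=config.r_ratio)))

    stats = compute_population_stats([ev for ev, *_ in per_event], [p for _, _, p, _ in per_event])
    annotations = []
    for ev, seg, plateau_drop, spikes in per_event:
        folded = flag_folded(
            ev,
            seg,
            baseline_pA,
            stats,
            fold_ratio=config.fold_ratio,
            min_frac=config.fold_min_frac,
            resid_nsd=config.fold_resid_nsd,
        )
        annotations.append(
            annotate_event(ev.event_id, ev.duration_ms, list(spikes), design, plateau_drop, folded)
        )
    return annotations


def _sized_df(
    kept: list[EventRecord], annotations: list[EventAnnotation], sized: list[SizedEvent]
) -> pd.DataFrame:
    by_id = {e.event_id: e for e in kept}
    return pd.DataFrame(
        {
            "event_id": [s.event_id for s in sized],
            "duration_ms": [by_id[s.event_id].duration_ms for s in sized],
            "ecd_fC": [by_id[s.event_id].ecd_fC for s in sized],
            "mean_drop_pA": [by_id[s.event_id].mean_drop_pA for s in sized],
            "conversion_kbp_per_ms": [s.conversion_kbp_per_ms for s in sized],
            "length_kbp": [s.length_kbp for s in sized],
            "n_cycles": [s.n_cycles for s in sized],
            "orientation": [a.orientation for a in annotations],
            "folded": [a.folded for a in annotations],
            "termination_class": [s.termination_class for s in sized],
        }
    )


def analyze_trace(
    trace: Trace, design: IDDesign, config: AnalysisConfig | None = None
) -> AnalysisResult:
    """Run the full analysis on one trace.

    Stages: robust baseline -> event detection -> screening filters ->
    spike calling / classification -> fold flagging -> orientation ->
    per-event calibration, sizing and termination classification ->
    population summary.
    """
    cfg = config or AnalysisConfig()
    if cfg.baseline_pA is not None and cfg.noise_sd_pA is not None:
        baseline, noise_sd = cfg.baseline_pA, cfg.noise_sd_pA
    else:
        baseline, noise_sd = estimate_baseline(trace)
        if cfg.baseline_pA is not None:
            baseline = cfg.baseline_pA
        if cfg.noise_sd_pA is not None:
            noise_sd = cfg.noise_sd_pA
    events = detect_events(
        trace,
        baseline,
        noise_sd,
        k_sigma=cfg.k_sigma,
        min_gap_ms=cfg.min_gap_ms,
        floor_pA=cfg.floor_pA,
    )
    kept, rejected = filter_events(
        events,
        ecd_max_fC=cfg.ecd_max_fC,
        min_duration_ms=cfg.min_duration_ms,
        max_mean_drop_pA=cfg.max_mean_drop_pA,
    )
    reasons = {ev.event_id: why for ev, why in rejected}
    annotations = annotate_events(trace, kept, design, baseline, noise_sd, cfg)
    sized = [
        size_and_classify(a, design, tau_tail_kbp=cfg.tau_tail_kbp, tau_oric_kbp=cfg.tau_oric_kbp)
        for a in annotations
    ]
    sized_df = _sized_df(kept, annotations, sized)
    summary = summarize_classes(sized_df, bin_width_kbp=cfg.hist_bin_kbp)
    return AnalysisResult(
        baseline_pA=baseline,
        noise_sd_pA=noise_sd,
        events=_events_df(events, kept, reasons),
        annotations=annotations,
        sized=sized_df,
        summary=summary,
    )


def simulate_dataset(
    design: IDDesign,
    params: SimParams,
    n_events: int,
    contaminant_fraction: float = 0.0,
    seed: int | None = None,
):
    """Convenience wrapper: simulate a trace plus its ground-truth table."""
    return simulate_trace(
        design, params, n_events, contaminant_fraction=contaminant_fraction, seed=seed
    )
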