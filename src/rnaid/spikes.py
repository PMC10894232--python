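"""Label-spike calling and per-event annotation.

Within a kept translocation event, downward spikes below the duplex plateau
mark streptavidin labels.  Spikes are called by prominence, classified as
repeats labels ``R`` versus ``1`` bits by depth (an ``R`` carries two
streptavidins and blocks about twice the current of a bit), and the ordered
kind pattern fixes the translocation direction: reading ``R,1,1`` per cycle
along time means the molecule entered 5' first; the mirrored pattern means
3' first.  The number of ``R`` calls is the rolling-circle cycle count.

Folded molecules (entering the pore doubled over) block roughly twice the
duplex current over part of the event; they are flagged and excluded from
sizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import medfilt
from scipy.stats import linregress

from .design import IDDesign
from .events import EventRecord

__all__ = [
    "SpikeCall",
    "EventAnnotation",
    "PopulationPlateauStats",
    "detect_spikes",
    "classify_spikes",
    "compute_population_stats",
    "flag_folded",
    "annotate_event",
]

KIND_R = "R"
KIND_BIT1 = "BIT1"
KIND_UNKNOWN = "UNKNOWN"

ORIENT_FORWARD = "forward_5to3"
ORIENT_REVERSE = "reverse_3to5"
ORIENT_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SpikeCall:
    """One called label spike, relative to the event start."""

    time_ms: float
    depth_pA: float  # drop below the duplex plateau
    width_ms: float
    kind: str = KIND_UNKNOWN


@dataclass(frozen=True)
class EventAnnotation:
    """Spike calls, orientation, fold flag and cycle count for one event.

    ``spikes`` are stored in canonical 5'->3' order: for events that
    translocated 3' first, calls are mirrored (time -> duration - time) and
    reversed, so downstream calibration always sees transcript coordinates.
    """

    event_id: int
    plateau_drop_pA: float
    spikes: tuple[SpikeCall, ...]
    folded: bool
    orientation: str
    n_cycles: int
    duration_ms: float


@dataclass(frozen=True)
class PopulationPlateauStats:
    """Population-level references used by the folded-event rule."""

    plateau_drop_pA: float
    ecd_slope_fC_per_ms: float = 0.0
    ecd_intercept_fC: float = 0.0
    resid_sd_fC: float = math.inf


def detect_spikes(
    samples: np.ndarray,
    sample_interval_ms: float,
    baseline_pA: float,
    noise_sd_pA: float,
    k_sigma: float = 4.0,
    prominence_frac: float = 0.3,
    min_width_samples: int = 3,
) -> tuple[float, list[SpikeCall]]:
    """Call downward spikes within one event's samples.

    The duplex plateau is the median of the event; spikes are excursions of
    the (median-filtered) signal below the plateau by more than
    ``max(k_sigma * noise_sd, prominence_frac * plateau_drop)`` lasting at
    least ``min_width_samples``.  Excursions closer than one spike width are
    merged.  Returns ``(plateau_drop_pA, calls)`` with all kinds UNKNOWN.
    """
    x = np.asarray(samples, dtype=float)
    dt = sample_interval_ms
    plateau_level = float(np.median(x))
    plateau_drop = baseline_pA - plateau_level
    if x.size < min_width_samples or plateau_drop <= 0:
        return plateau_drop, []
    sm = medfilt(x, 3) if x.size >= 3 else x
    thr = plateau_level - max(k_sigma * noise_sd_pA, prominence_frac * plateau_drop)
    below = sm < thr
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return plateau_drop, []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]
    runs = [(s, e) for s, e in runs if e - s >= min_width_samples]
    if not runs:
        return plateau_drop, []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        prev = merged[-1]
        if s - prev[1] < max(prev[1] - prev[0], e - s):
            prev[1] = e
        else:
            merged.append([s, e])
    calls = []
    for s, e in merged:
        depth = plateau_level - float(sm[s:e].min())
        calls.append(
            SpikeCall(
                time_ms=0.5 * (s + e) * dt,
                depth_pA=depth,
                width_ms=(e - s) * dt,
            )
        )
    return plateau_drop, calls


def _two_means_lower_mask(depths: np.ndarray) -> np.ndarray:
    """1-D two-means split; True marks the shallower cluster."""
    c_lo, c_hi = float(depths.min()), float(depths.max())
    lower = depths <= (c_lo + c_hi) / 2.0
    for _ in range(25):
        if lower.all() or not lower.any():
            break
        c_lo = float(depths[lower].mean())
        c_hi = float(depths[~lower].mean())
        new_lower = depths <= (c_lo + c_hi) / 2.0
        if np.array_equal(new_lower, lower):
            break
        lower = new_lower
    return lower


def classify_spikes(spikes: list[SpikeCall], r_ratio: float = 1.5) -> list[SpikeCall]:
    """Assign R / BIT1 kinds by depth.

    The reference depth is the median of the shallower cluster of a 1-D
    two-means split (three or more spikes); a spike deeper than ``r_ratio``
    times the reference is an ``R``.  A lone spike has no reference and
    stays UNKNOWN; for two spikes the deeper one is ``R`` only if the depth
    ratio exceeds ``r_ratio``.
    """
    if not spikes:
        return []
    if len(spikes) == 1:
        return [replace(spikes[0], kind=KIND_UNKNOWN)]
    depths = np.array([s.depth_pA for s in spikes])
    if len(spikes) == 2:
        lo, hi = depths.min(), depths.max()
        if lo > 0 and hi / lo > r_ratio:
            return [
                replace(s, kind=KIND_R if s.depth_pA == hi else KIND_BIT1) for s in spikes
            ]
        return [replace(s, kind=KIND_BIT1) for s in spikes]
    lower = _two_means_lower_mask(depths)
    if not lower.any():  # degenerate: all depths identical
        lower = np.ones_like(lower, dtype=bool)
    ref = float(np.median(depths[lower]))
    return [
        replace(s, kind=KIND_R if s.depth_pA > r_ratio * ref else KIND_BIT1) for s in spikes
    ]


def compute_population_stats(
    events: list[EventRecord], plateau_drops: list[float]
) -> PopulationPlateauStats:
    """Median unfolded duplex level and the ECD-vs-duration regression.

    With fewer than three events the regression is undefined and the
    residual-based folded rule is disabled (infinite residual scale).
    """
    plateau = float(np.median(plateau_drops)) if plateau_drops else 0.0
    if len(events) < 3:
        return PopulationPlateauStats(plateau_drop_pA=plateau)
    dur = np.array([e.duration_ms for e in events])
    ecd = np.array([e.ecd_fC for e in events])
    if np.allclose(dur, dur[0]):
        return PopulationPlateauStats(plateau_drop_pA=plateau)
    fit = linregress(dur, ecd)
    resid = ecd - (fit.slope * dur + fit.intercept)
    resid_sd = float(np.std(resid, ddof=2)) if len(events) > 2 else math.inf
    return PopulationPlateauStats(
        plateau_drop_pA=plateau,
        ecd_slope_fC_per_ms=float(fit.slope),
        ecd_intercept_fC=float(fit.intercept),
        resid_sd_fC=resid_sd,
    )


def flag_folded(
    event: EventRecord,
    samples: np.ndarray,
    baseline_pA: float,
    stats: PopulationPlateauStats,
    fold_ratio: float = 1.7,
    min_frac: float = 0.10,
    resid_nsd: float = 3.0,
) -> bool:
    """Flag partially folded molecules.

    Two-part rule: (a) a contiguous region of at least ``min_frac`` of the
    event, starting near one end, sits deeper than ``fold_ratio`` times the
    population's unfolded duplex level; or (b) the event's (duration, ECD)
    point lies more than ``resid_nsd`` residual SDs above the population
    regression line.  Either triggers the flag.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    level = baseline_pA - fold_ratio * stats.plateau_drop_pA
    idx = np.flatnonzero(x < level)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for s, e in zip(starts, ends):
            run_start, run_end = int(idx[s]), int(idx[e]) + 1
            if run_end - run_start >= min_frac * n and (
                run_start <= 0.05 * n or run_end >= 0.95 * n
            ):
                return True
    if math.isfinite(stats.resid_sd_fC) and stats.resid_sd_fC > 0:
        pred = stats.ecd_slope_fC_per_ms * event.duration_ms + stats.ecd_intercept_fC
        if event.ecd_fC - pred > resid_nsd * stats.resid_sd_fC:
            return True
    return False


def annotate_event(
    event_id: int,
    duration_ms: float,
    spikes: list[SpikeCall],
    design: IDDesign,
    plateau_drop_pA: float,
    folded: bool,
) -> EventAnnotation:
    """Infer orientation and cycle count; canonicalize spike order to 5'->3'.

    The per-cycle kind pattern comes from the design (e.g. ``R,1,1``).  A
    time-ordered kind sequence equal to ``pattern * n`` reads 5'->3'
    (forward); the mirrored sequence reads 3'->5'.  Anything else --
    including any UNKNOWN call -- is ambiguous.  ``n_cycles`` is the number
    of R calls regardless of orientation.
    """
    kinds = [s.kind for s in spikes]
    pattern = [lab.kind.value for lab in design.labels]
    n_r = kinds.count(KIND_R)
    orientation = ORIENT_AMBIGUOUS
    if n_r >= 1 and KIND_UNKNOWN not in kinds:
        if kinds == pattern * n_r:
            orientation = ORIENT_FORWARD
        elif kinds == list(reversed(pattern)) * n_r:
            orientation = ORIENT_REVERSE
    canonical = tuple(spikes)
    if orientation == ORIENT_REVERSE:
        canonical = tuple(
            replace(s, time_ms=duration_ms - s.time_ms) for s in reversed(spikes)
        )
    return EventAnnotation(
        event_id=event_id,
        plateau_drop_pA=plateau_drop_pA,
        spikes=canonical,
        folded=folded,
        orientation=orientation,
        n_cycles=n_r,
        duration_ms=duration_ms,
    )
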