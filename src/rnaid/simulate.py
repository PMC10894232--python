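"""Synthetic nanopore traces of RNA ID translocations with ground truth.

Emulates a single-channel ionic-current recording of RNA-DNA duplexes
(RNA IDs) translocating a glass nanopore: an open-pore baseline with
Gaussian noise, a roughly rectangular blockade per molecule, and downward
spikes superimposed at streptavidin-label positions -- the repeats label
``R`` about twice as deep as a ``1`` bit.  Transcript lengths follow the
termination model of the construct: per-cycle premature termination at the
OriC, stochastic polymerase dissociation, or run-off at the template end.

Every event is logged in a ground-truth table so downstream detection,
classification and sizing can be scored without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .design import IDDesign, LabelKind, Topology, layout_for_truth
from .events import Trace

__all__ = [
    "SimParams",
    "GroundTruthRecord",
    "draw_transcript",
    "simulate_event",
    "simulate_trace",
    "format_time_list",
    "parse_time_list",
]

TERM_ORIC = "ORIC_PT"
TERM_END = "END"
TERM_DISSOCIATION = "DISSOCIATION"


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults define the reference study conditions.

    Units: currents pA, times ms, lengths kbp, speeds kbp/ms.

    Magnitudes are chosen to be mutually consistent with the event filters
    applied downstream (mean drop beyond -100 pA with margin, event charge
    deficit of the longest modelled multi-cycle transcripts below 400 fC,
    durations well above 0.05 ms).
    """

    baseline_pA: float = 1000.0
    noise_sd_pA: float = 10.0
    duplex_drop_pA: float = 120.0
    bit_extra_drop_pA: float = 60.0
    r_depth_ratio: float = 2.0
    spike_width_kbp: float = 0.10
    speed_kbp_per_ms: float = 4.0
    speed_cv: float = 0.10
    intra_event_drift: float = 0.10
    sample_interval_ms: float = 0.005
    p_reverse: float = 0.5
    p_fold: float = 0.10
    p_term_per_cycle: float = 0.47
    dissociation_rate_per_kbp: float = 0.02
    dissociation_mode: str = "uniform"  # or "end_of_cycle"
    inter_event_gap_ms: float = 2.0
    lowpass_tau_ms: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_reverse", "p_fold", "p_term_per_cycle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "baseline_pA",
            "duplex_drop_pA",
            "bit_extra_drop_pA",
            "spike_width_kbp",
            "speed_kbp_per_ms",
            "sample_interval_ms",
            "inter_event_gap_ms",
        ):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("noise_sd_pA", "speed_cv", "intra_event_drift", "dissociation_rate_per_kbp"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.r_depth_ratio <= 1.0:
            raise ValueError(f"r_depth_ratio must be > 1, got {self.r_depth_ratio}")
        if self.dissociation_mode not in ("uniform", "end_of_cycle"):
            raise ValueError(f"unknown dissociation_mode {self.dissociation_mode!r}")

    def with_overrides(self, overrides: dict) -> "SimParams":
        return replace(self, **overrides)


@dataclass
class GroundTruthRecord:
    """Per-event ground truth written alongside the simulated trace."""

    index: int
    contaminant: bool = False
    true_length_kbp: float = math.nan
    orientation: str = "forward"
    n_cycles: int = 0
    termination: str = ""
    folded: bool = False
    fold_fraction: float = 0.0
    start_ms: float = math.nan
    duration_ms: float = math.nan
    spike_times_ms: tuple[float, ...] = ()


def format_time_list(times: Iterable[float]) -> str:
    return ";".join(f"{t:.6f}" for t in times)


def parse_time_list(text: str) -> list[float]:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return []
    return [float(tok) for tok in str(text).split(";") if tok]


def draw_transcript(
    design: IDDesign, params: SimParams, rng: np.random.Generator
) -> tuple[float, str, int]:
    """Draw one transcript: (length kbp, termination class, cycle count).

    Linear templates terminate at the OriC point with probability
    ``p_term_per_cycle``, otherwise run off at the template end.  Circular
    templates are walked cycle by cycle: each OriC encounter terminates with
    that probability; a survivor is exposed to a dissociation hazard over
    the remainder of the cycle before re-entering the next one.  The walk is
    capped at the last modelled cycle, whose OriC encounter is forced.
    """
    if design.topology is Topology.LINEAR:
        if rng.random() < params.p_term_per_cycle:
            return design.oric_term_offset_kbp, TERM_ORIC, 1
        return float(design.full_length_kbp), TERM_END, 1

    starts = design.cycle_starts_kbp
    for i, start in enumerate(starts):
        oric_point = start + design.oric_term_offset_kbp
        last = i == len(starts) - 1
        terminated = rng.random() < params.p_term_per_cycle
        if terminated or last:  # the last modelled OriC encounter is forced
            return oric_point, TERM_ORIC, i + 1
        span = starts[i + 1] - oric_point
        p_diss = -math.expm1(-params.dissociation_rate_per_kbp * span)
        if rng.random() < p_diss:
            if params.dissociation_mode == "end_of_cycle":
                return starts[i + 1], TERM_DISSOCIATION, i + 1
            return oric_point + rng.uniform(0.0, span), TERM_DISSOCIATION, i + 1
    raise AssertionError("unreachable: capped at last modelled cycle")


def _lognormal_speed(params: SimParams, rng: np.random.Generator) -> float:
    if params.speed_cv <= 0:
        return params.speed_kbp_per_ms
    sigma2 = math.log1p(params.speed_cv**2)
    mu = math.log(params.speed_kbp_per_ms) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def simulate_event(
    design: IDDesign,
    truth: GroundTruthRecord,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruthRecord]:
    """Render one translocation event as a block of current samples.

    The molecule moves at a per-event lognormal speed with an optional
    linear intra-event drift; the backbone blocks ``duplex_drop_pA`` and
    each label adds a rectangular spike (``R`` = ``r_depth_ratio`` x the
    ``1``-bit extra drop).  Folded molecules get a prefix (10-50 % of the
    event) at twice the backbone drop.  Gaussian noise is added everywhere.
    """
    L = truth.true_length_kbp
    if params.spike_width_kbp >= L:
        raise ValueError(
            f"spike_width_kbp={params.spike_width_kbp} is not smaller than the "
            f"transcript length {L} kbp"
        )
    v0 = _lognormal_speed(params, rng)
    d = rng.uniform(-params.intra_event_drift, params.intra_event_drift) if params.intra_event_drift > 0 else 0.0
    T = L / v0
    dt = params.sample_interval_ms
    n = max(int(round(T / dt)), 2)
    # linear speed ramp v(t) = a + 2 b t, integrating to x(T) = L exactly
    a = v0 * (1.0 - d)
    b = d * v0 / T

    def time_of(p: float) -> float:
        if abs(b) < 1e-12:
            return p / v0
        return (-a + math.sqrt(a * a + 4.0 * b * p)) / (2.0 * b)

    block = np.full(n, -params.duplex_drop_pA)
    times: list[float] = []
    for p, kind in layout_for_truth(design, L, truth.orientation):
        t = time_of(p)
        v_local = a + 2.0 * b * t
        w = params.spike_width_kbp / v_local
        extra = params.bit_extra_drop_pA * (params.r_depth_ratio if kind is LabelKind.R else 1.0)
        i0 = max(0, int(round((t - w / 2.0) / dt)))
        i1 = min(n, max(i0 + 1, int(round((t + w / 2.0) / dt))))
        block[i0:i1] -= extra
        times.append(t)
    if truth.folded:
        f = rng.uniform(0.10, 0.50)
        truth.fold_fraction = float(f)
        block[: max(1, int(round(f * n)))] -= params.duplex_drop_pA
    samples = params.baseline_pA + block
    if params.noise_sd_pA > 0:
        samples = samples + rng.normal(0.0, params.noise_sd_pA, n)
    truth.duration_ms = n * dt
    truth.spike_times_ms = tuple(times)
    return samples, truth


def _contaminant_block(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """A blockade that fails the event filters: too short or too shallow."""
    dt = params.sample_interval_ms
    if rng.random() < 0.5:
        dur = rng.uniform(0.010, 0.035)       # below the 0.05 ms duration filter
        drop = rng.uniform(150.0, 300.0)
    else:
        dur = rng.uniform(0.2, 1.0)
        drop = rng.uniform(55.0, 85.0)        # above the -100 pA mean-drop filter
    n = max(1, int(round(dur / dt)))
    samples = np.full(n, params.baseline_pA - drop)
    if params.noise_sd_pA > 0:
        samples = samples + rng.normal(0.0, params.noise_sd_pA, n)
    return samples


def simulate_trace(
    design: IDDesign,
    params: SimParams,
    n_events: int,
    contaminant_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[Trace, pd.DataFrame]:
    """Simulate a full trace of ``n_events`` translocations plus ground truth.

    Events are separated by exponential open-pore gaps.  Exactly
    ``round(contaminant_fraction * n_events)`` events are contaminants
    (short or shallow blockades mimicking RNA blobs / loose streptavidin),
    flagged in the truth table.  The truth table stores per-event spike
    times relative to the event start, semicolon-joined.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not 0.0 <= contaminant_fraction <= 1.0:
        raise ValueError("contaminant_fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = params.sample_interval_ms
    n_cont = int(round(contaminant_fraction * n_events))
    cont_idx = set(rng.permutation(n_events)[:n_cont].tolist()) if n_cont else set()

    segments: list[np.ndarray] = []
    truths: list[GroundTruthRecord] = []
    cursor = 0.0

    def emit_gap() -> None:
        nonlocal cursor
        g_ms = 0.2 + rng.exponential(params.inter_event_gap_ms)
        m = max(1, int(round(g_ms / dt)))
        seg = np.full(m, params.baseline_pA)
        if params.noise_sd_pA > 0:
            seg = seg + rng.normal(0.0, params.noise_sd_pA, m)
        segments.append(seg)
        cursor += m * dt

    emit_gap()
    for i in range(n_events):
        if i in cont_idx:
            seg = _contaminant_block(params, rng)
            truth = GroundTruthRecord(
                index=i, contaminant=True, start_ms=cursor, duration_ms=len(seg) * dt
            )
        else:
            length, term, n_cyc = draw_transcript(design, params, rng)
            orientation = "reverse" if rng.random() < params.p_reverse else "forward"
            folded = rng.random() < params.p_fold
            truth = GroundTruthRecord(
                index=i,
                true_length_kbp=length,
                orientation=orientation,
                n_cycles=n_cyc,
                termination=term,
                folded=folded,
                start_ms=cursor,
            )
            seg, truth = simulate_event(design, truth, params, rng)
        truths.append(truth)
        segments.append(seg)
        cursor += len(seg) * dt
        emit_gap()

    total = sum(len(s) for s in segments)
    if total < 1000:  # keep baseline estimation well-posed on tiny traces
        m = 1000 - total
        seg = np.full(m, params.baseline_pA)
        if params.noise_sd_pA > 0:
            seg = seg + rng.normal(0.0, params.noise_sd_pA, m)
        segments.append(seg)

    samples = np.concatenate(segments) if segments else np.empty(0)
    if params.lowpass_tau_ms:
        from scipy.signal import lfilter

        alpha = dt / (params.lowpass_tau_ms + dt)
        samples = lfilter([alpha], [1.0, alpha - 1.0], samples, zi=None)
        samples[0] = params.baseline_pA

    truth_df = pd.DataFrame(
        {
            "event_index": [t.index for t in truths],
            "contaminant": [t.contaminant for t in truths],
            "true_length_kbp": [t.true_length_kbp for t in truths],
            "orientation": [t.orientation for t in truths],
            "n_cycles": [t.n_cycles for t in truths],
            "termination": [t.termination for t in truths],
            "folded": [t.folded for t in truths],
            "fold_fraction": [t.fold_fraction for t in truths],
            "start_ms": [t.start_ms for t in truths],
            "duration_ms": [t.duration_ms for t in truths],
            "spike_times_ms": [format_time_list(t.spike_times_ms) for t in truths],
        }
    )
    return Trace(samples, dt), truth_df
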