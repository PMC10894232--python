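"""Time-to-length conversion and termination classification.

Each event carries its own ruler: the base-pair distance between design
labels is known, so the time between their spikes yields a per-event
conversion factor (kbp/ms).  The whole event duration times that factor is
the transcript length estimate.  Multi-cycle events calibrate each cycle's
label set independently and average the factors weighted by spanned length,
which damps intra-event speed drift.

Termination classes:

* ``ORIC_PT``  -- premature termination at the alternative terminator in the
  OriC.  Linear constructs: the translocation ends right after the last
  label (no plateau tail).  Circular constructs: the residual of the last
  cycle matches the OriC offset.
* ``END``      -- run-off at the template end (linear only): a long
  label-free plateau follows the last spike.
* ``DISSOCIATION`` -- circular constructs, residual close to a full cycle.
* ``UNCLASSIFIED`` -- no usable calibration or a residual matching neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design import IDDesign, Topology
from .spikes import ORIENT_AMBIGUOUS, EventAnnotation

__all__ = [
    "SizedEvent",
    "TERM_ORIC",
    "TERM_END",
    "TERM_DISSOCIATION",
    "TERM_UNCLASSIFIED",
    "calibrate_event",
    "size_event",
    "classify_termination",
    "size_and_classify",
]

TERM_ORIC = "ORIC_PT"
TERM_END = "END"
TERM_DISSOCIATION = "DISSOCIATION"
TERM_UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class SizedEvent:
    event_id: int
    conversion_kbp_per_ms: float
    length_kbp: float
    n_cycles: int
    termination_class: str


def calibrate_event(annotation: EventAnnotation, design: IDDesign) -> float | None:
    """Per-event base-pair-to-time conversion factor (kbp/ms).

    Spikes (in canonical 5'->3' order) are matched positionally to the
    design fiducials; the factor for each cycle is the known span between
    its first and last label divided by the time between their spikes --
    algebraically the span-weighted mean of adjacent pairwise factors.
    Cycles are then combined, weighted by span.  Returns ``None`` (event
    unclassifiable) for folded or ambiguous events, fewer than two usable
    fiducials, or a spike count that does not match the design.
    """
    if annotation.folded or annotation.orientation == ORIENT_AMBIGUOUS:
        return None
    k = len(design.labels)
    n = annotation.n_cycles
    if k < 2 or n < 1 or n > design.n_cycles_max:
        return None
    if len(annotation.spikes) != n * k:
        return None
    offsets = [lab.position_kbp for lab in design.labels]
    span = offsets[-1] - offsets[0]
    num = 0.0
    den = 0.0
    for c in range(n):
        group = annotation.spikes[c * k : (c + 1) * k]
        dt = group[-1].time_ms - group[0].time_ms
        if dt <= 0:
            return None
        num += span * (span / dt)
        den += span
    return num / den


def size_event(annotation: EventAnnotation, conversion_kbp_per_ms: float) -> float:
    """Transcript length estimate: event duration times the conversion factor."""
    if conversion_kbp_per_ms is None or conversion_kbp_per_ms <= 0:
        raise ValueError("conversion factor must be a positive number")
    return annotation.duration_ms * conversion_kbp_per_ms


def classify_termination(
    length_kbp: float,
    annotation: EventAnnotation,
    design: IDDesign,
    conversion_kbp_per_ms: float,
    tau_tail_kbp: float = 0.8,
    tau_oric_kbp: float = 0.5,
) -> str:
    """Assign the termination class of a sized event.

    Linear: the label-free tail after the last spike, converted to kbp,
    separates premature termination (short tail, "no plateau") from run-off
    (long plateau) at ``tau_tail_kbp``.  Circular: the residual of the last
    started cycle, ``length - cycle_start[n-1]``, is compared to the OriC
    offset (``ORIC_PT``) and to a full cycle (``DISSOCIATION``) within
    ``tau_oric_kbp``.
    """
    if design.topology is Topology.LINEAR:
        tail_kbp = (annotation.duration_ms - annotation.spikes[-1].time_ms) * conversion_kbp_per_ms
        return TERM_ORIC if tail_kbp <= tau_tail_kbp else TERM_END
    n = annotation.n_cycles
    starts = design.cycle_starts_kbp
    if n < 1 or n > len(starts):
        return TERM_UNCLASSIFIED
    residual = length_kbp - starts[n - 1]
    if abs(residual - design.oric_term_offset_kbp) <= tau_oric_kbp:
        return TERM_ORIC
    if abs(residual - design.cycle_length_kbp(n - 1)) <= tau_oric_kbp:
        return TERM_DISSOCIATION
    return TERM_UNCLASSIFIED


def size_and_classify(
    annotation: EventAnnotation,
    design: IDDesign,
    tau_tail_kbp: float = 0.8,
    tau_oric_kbp: float = 0.5,
) -> SizedEvent:
    """Calibrate, size and classify one annotated event.

    Events without a usable calibration come back with NaN conversion and
    length and the ``UNCLASSIFIED`` class rather than raising.
    """
    conversion = calibrate_event(annotation, design)
    if conversion is None:
        return SizedEvent(
            event_id=annotation.event_id,
            conversion_kbp_per_ms=math.nan,
            length_kbp=math.nan,
            n_cycles=annotation.n_cycles,
            termination_class=TERM_UNCLASSIFIED,
        )
    length = size_event(annotation, conversion)
    term = classify_termination(
        length, annotation, design, conversion, tau_tail_kbp=tau_tail_kbp, tau_oric_kbp=tau_oric_kbp
    )
    return SizedEvent(
        event_id=annotation.event_id,
        conversion_kbp_per_ms=conversion,
        length_kbp=length,
        n_cycles=annotation.n_cycles,
        termination_class=term,
    )
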