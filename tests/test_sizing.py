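"""Calibration, sizing and termination classification."""

import math

import numpy as np
import pytest

from rnaid import SimParams, analyze_trace, simulate_event, simulate_trace
from rnaid.events import Trace
from rnaid.simulate import GroundTruthRecord
from rnaid.sizing import (
    TERM_DISSOCIATION,
    TERM_END,
    TERM_ORIC,
    TERM_UNCLASSIFIED,
    calibrate_event,
    classify_termination,
    size_and_classify,
    size_event,
)
from rnaid.spikes import ORIENT_FORWARD, EventAnnotation, SpikeCall


def _annotation(times, kinds, duration, n_cycles=None, folded=False, orientation=ORIENT_FORWARD):
    depth = {"R": 120.0, "BIT1": 60.0, "UNKNOWN": 70.0}
    spikes = tuple(
        SpikeCall(time_ms=t, depth_pA=depth[k], width_ms=0.02, kind=k)
        for t, k in zip(times, kinds)
    )
    n = kinds.count("R") if n_cycles is None else n_cycles
    return EventAnnotation(
        event_id=0,
        plateau_drop_pA=120.0,
        spikes=spikes,
        folded=folded,
        orientation=orientation,
        n_cycles=n,
        duration_ms=duration,
    )


def test_conversion_from_label_spacings(linear_design):
    """Spikes at 1.0/2.0/3.2 ms spanning 1.1 kbp give 0.5 kbp/ms."""
    ann = _annotation([1.0, 2.0, 3.2], ["R", "BIT1", "BIT1"], duration=4.0)
    assert calibrate_event(ann, linear_design) == pytest.approx(0.5)


def test_size_event_arithmetic(linear_design):
    ann = _annotation([1.0, 2.0, 3.2], ["R", "BIT1", "BIT1"], duration=6.38)
    assert size_event(ann, 0.5) == pytest.approx(3.19)


def test_bit_pair_calibration_recovers_r_span(linear_design, noiseless_params):
    """Calibrating on the 0.6 kbp bit-bit spacing alone, the measured
    R-to-adjacent-bit span comes out as the designed 0.5 kbp."""
    from rnaid.spikes import classify_spikes, detect_spikes

    rng = np.random.default_rng(0)
    truth = GroundTruthRecord(index=0, true_length_kbp=3.19, orientation="forward")
    samples, truth = simulate_event(linear_design, truth, noiseless_params, rng)
    dt = noiseless_params.sample_interval_ms
    _, calls = detect_spikes(samples, dt, noiseless_params.baseline_pA, 0.0)
    calls = classify_spikes(calls)
    t_r, t_b1, t_b2 = [c.time_ms for c in calls]
    conv_bits = 0.6 / (t_b2 - t_b1)
    r_span = (t_b1 - t_r) * conv_bits
    assert r_span == pytest.approx(0.5, abs=2 * dt * conv_bits)


def test_drift_sizing_within_five_percent(linear_design):
    """Span-weighted calibration sizes a noiseless PT event within 5 % of
    truth under a +/-10 % linear speed drift.

    Oracle: integrate the drifting speed profile directly to place the
    spike times, bypassing the renderer."""
    v0, L = 4.0, 1.75
    for d in (-0.10, 0.10):
        T = L / v0
        a, b = v0 * (1 - d), d * v0 / T

        def time_of(p):
            if abs(b) < 1e-15:
                return p / v0
            return (-a + math.sqrt(a * a + 4 * b * p)) / (2 * b)

        times = [time_of(p) for p in (0.10, 0.60, 1.20)]
        ann = _annotation(times, ["R", "BIT1", "BIT1"], duration=T)
        conv = calibrate_event(ann, linear_design)
        sized = size_event(ann, conv)
        assert abs(sized - L) / L < 0.05


def test_multi_cycle_calibration_span_weighted(circular_design):
    """Two cycles at different local speeds average by spanned length."""
    # cycle 1 at 0.5 kbp/ms (offsets 0.1->1.2 over 2.2 ms), cycle 2 at 0.55
    t1 = [0.2, 1.2, 2.4]
    dt2 = 1.1 / 0.55
    t2 = [5.0, 5.0 + dt2 * (0.5 / 1.1), 5.0 + dt2]
    ann = _annotation(t1 + t2, ["R", "BIT1", "BIT1"] * 2, duration=8.0)
    conv = calibrate_event(ann, circular_design)
    assert conv == pytest.approx((0.5 + 0.55) / 2)


@pytest.mark.parametrize(
    "times, kinds, orientation, reason",
    [
        ([1.0], ["UNKNOWN"], ORIENT_FORWARD, "single spike"),
        ([1.0, 2.0], ["BIT1", "BIT1"], "ambiguous", "ambiguous orientation"),
        ([1.0, 2.0, 3.0, 4.0], ["R", "BIT1", "BIT1", "BIT1"], "ambiguous", "extra spike"),
    ],
)
def test_uncalibratable_events_are_unclassified(linear_design, times, kinds, orientation, reason):
    ann = _annotation(times, kinds, duration=5.0, orientation=orientation)
    assert calibrate_event(ann, linear_design) is None
    sized = size_and_classify(ann, linear_design)
    assert sized.termination_class == TERM_UNCLASSIFIED
    assert math.isnan(sized.length_kbp)


def test_folded_events_excluded_from_sizing(linear_design):
    ann = _annotation([1.0, 2.0, 3.2], ["R", "BIT1", "BIT1"], duration=4.0, folded=True)
    assert calibrate_event(ann, linear_design) is None


def test_linear_termination_tail_rule(linear_design):
    # PT: translocation ends 0.15 kbp after the second bit -> no plateau
    ann = _annotation([1.0, 2.0, 3.2], ["R", "BIT1", "BIT1"], duration=3.5)
    assert classify_termination(1.75, ann, linear_design, 0.5) == TERM_ORIC
    # END: 1.9 kbp label-free plateau after the last spike
    ann = _annotation([1.0, 2.0, 3.2], ["R", "BIT1", "BIT1"], duration=7.0)
    assert classify_termination(3.5, ann, linear_design, 0.5) == TERM_END


def test_circular_termination_by_residual(circular_design):
    ann1 = _annotation([0.2, 1.2, 2.4], ["R", "BIT1", "BIT1"], duration=3.2)
    # n=1 at ~1.6 kbp: OriC premature termination
    assert classify_termination(1.6, ann1, circular_design, 0.5) == TERM_ORIC
    # n=1 at ~3.1 kbp: nearly a full cycle -> polymerase dissociation
    assert classify_termination(3.1, ann1, circular_design, 0.5) == TERM_DISSOCIATION
    # n=1 at 2.4 kbp: matches neither
    assert classify_termination(2.4, ann1, circular_design, 0.5) == TERM_UNCLASSIFIED
    ann2 = _annotation(
        [0.2, 1.2, 2.4, 6.2, 7.2, 8.4], ["R", "BIT1", "BIT1"] * 2, duration=12.0
    )
    # n=2 at ~4.6 kbp: OriC; at ~5.9 kbp: dissociation
    assert classify_termination(4.6, ann2, circular_design, 0.5) == TERM_ORIC
    assert classify_termination(5.9, ann2, circular_design, 0.5) == TERM_DISSOCIATION


def test_time_rescaling_leaves_lengths_unchanged(linear_design, noiseless_params, matcher):
    """Doubling the sampling interval (all times scale by two) changes
    durations and conversions but not sized lengths."""
    trace, truth = simulate_trace(linear_design, noiseless_params, 20)
    slow = Trace(trace.samples, trace.sample_interval_ms * 2)
    res_a = analyze_trace(trace, linear_design)
    res_b = analyze_trace(slow, linear_design)
    a = res_a.sized.dropna(subset=["length_kbp"])
    b = res_b.sized.dropna(subset=["length_kbp"])
    assert len(a) == len(b) > 0
    np.testing.assert_allclose(
        b["duration_ms"].to_numpy(), 2 * a["duration_ms"].to_numpy(), rtol=1e-12
    )
    np.testing.assert_allclose(
        b["length_kbp"].to_numpy(), a["length_kbp"].to_numpy(), rtol=1e-9
    )


def test_orientation_invariance_of_sizing(linear_design, noiseless_params):
    """The same molecule sized forward and reverse gives equal lengths
    within sampling quantization."""
    from rnaid.pipeline import AnalysisConfig

    lengths = {}
    for orientation in ("forward", "reverse"):
        rng = np.random.default_rng(9)
        truth = GroundTruthRecord(index=0, true_length_kbp=3.19, orientation=orientation)
        samples, _ = simulate_event(linear_design, truth, noiseless_params, rng)
        pad = np.full(2000, noiseless_params.baseline_pA)
        trace = Trace(np.concatenate([pad, samples, pad]), noiseless_params.sample_interval_ms)
        res = analyze_trace(trace, linear_design)
        lengths[orientation] = float(res.sized["length_kbp"].iloc[0])
    dt = noiseless_params.sample_interval_ms
    quantum = 2 * dt * noiseless_params.speed_kbp_per_ms
    assert abs(lengths["forward"] - lengths["reverse"]) <= quantum


def test_sizing_is_unbiased_per_class(linear_run, matcher):
    """Mean sized-minus-truth within +/-0.05 kbp for both PT and END."""
    trace, truth, result = linear_run
    kept = result.events[result.events["kept"]].reset_index(drop=True)
    idx = matcher(kept, truth)
    sized = result.sized.copy()
    sized["truth_kbp"] = truth.loc[idx, "true_length_kbp"].to_numpy()
    ok = sized.dropna(subset=["length_kbp"])
    for cls in (TERM_ORIC, TERM_END):
        grp = ok[ok["termination_class"] == cls]
        assert len(grp) > 30
        bias = (grp["length_kbp"] - grp["truth_kbp"]).mean()
        assert abs(bias) < 0.05
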