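"""Spike calling, R/bit classification, fold flagging, orientation."""

import numpy as np
import pytest

from rnaid import SimParams, analyze_trace, simulate_event, simulate_trace
from rnaid.design import IDDesign, LabelKind, LabelSpec, Topology
from rnaid.events import EventRecord
from rnaid.simulate import GroundTruthRecord, parse_time_list
from rnaid.spikes import (
    ORIENT_AMBIGUOUS,
    ORIENT_FORWARD,
    ORIENT_REVERSE,
    PopulationPlateauStats,
    SpikeCall,
    annotate_event,
    classify_spikes,
    detect_spikes,
    flag_folded,
)

DT = 0.005


def _plateau_event(n=400, baseline=1000.0, drop=120.0):
    return np.full(n, baseline - drop)


def test_plateau_only_event_has_no_spikes():
    samples = _plateau_event()
    plateau_drop, calls = detect_spikes(samples, DT, 1000.0, 0.0)
    assert plateau_drop == pytest.approx(120.0)
    assert calls == []


def test_noiseless_event_spikes_match_ground_truth(linear_design, noiseless_params):
    rng = np.random.default_rng(0)
    truth = GroundTruthRecord(index=0, true_length_kbp=3.19, orientation="forward")
    samples, truth = simulate_event(linear_design, truth, noiseless_params, rng)
    plateau_drop, calls = detect_spikes(samples, DT, noiseless_params.baseline_pA, 0.0)
    assert len(calls) == 3
    half_width = noiseless_params.spike_width_kbp / noiseless_params.speed_kbp_per_ms / 2
    for call, t_true in zip(calls, truth.spike_times_ms):
        assert abs(call.time_ms - t_true) <= half_width


def test_labels_closer_than_one_width_merge_to_single_call():
    samples = _plateau_event(n=600)
    # two rectangular spikes 3 samples apart, each 6 samples wide
    samples[200:206] -= 60.0
    samples[209:215] -= 60.0
    _, calls = detect_spikes(samples, DT, 1000.0, 0.0)
    assert len(calls) == 1


@pytest.mark.parametrize(
    "depths, expected",
    [
        ([50.0, 50.0, 100.0], ["BIT1", "BIT1", "R"]),
        ([48.0, 53.0, 97.0], ["BIT1", "BIT1", "R"]),
        ([70.0], ["UNKNOWN"]),
        ([60.0, 130.0], ["BIT1", "R"]),
        ([60.0, 70.0], ["BIT1", "BIT1"]),
        ([55.0, 60.0, 58.0], ["BIT1", "BIT1", "BIT1"]),
    ],
)
def test_depth_classification(depths, expected):
    spikes = [SpikeCall(time_ms=i * 0.1, depth_pA=d, width_ms=0.02) for i, d in enumerate(depths)]
    assert [s.kind for s in classify_spikes(spikes)] == expected


def test_classification_matches_threshold_oracle():
    """Against a brute-force oracle: with known bit depths, a call is R iff
    its depth exceeds 1.5x the median of the shallower cluster."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        n_bits = rng.integers(2, 5)
        n_r = rng.integers(1, 3)
        bits = rng.normal(60, 5, n_bits)
        rs = rng.normal(120, 8, n_r)
        depths = np.concatenate([bits, rs])
        rng.shuffle(depths)
        spikes = [SpikeCall(i * 0.1, float(d), 0.02) for i, d in enumerate(depths)]
        got = [s.kind for s in classify_spikes(spikes)]
        ref = float(np.median(sorted(depths)[:n_bits]))
        oracle = ["R" if d > 1.5 * ref else "BIT1" for d in depths]
        assert got == oracle


def _stats(plateau=120.0):
    return PopulationPlateauStats(plateau_drop_pA=plateau)


def _record(samples, dt=DT):
    ecd = float(np.sum(1000.0 - samples) * dt)
    return EventRecord(0, 0, len(samples), 0.0, len(samples) * dt, len(samples) * dt,
                       float(samples.mean() - 1000.0), ecd)


def test_folded_prefix_is_flagged():
    samples = _plateau_event(n=500)
    samples[:150] -= 120.0  # 30 % prefix at twice the duplex drop
    assert flag_folded(_record(samples), samples, 1000.0, _stats())


def test_unfolded_event_not_flagged():
    samples = _plateau_event(n=500)
    samples[50:55] -= 120.0  # an R spike is deep but far too short
    assert not flag_folded(_record(samples), samples, 1000.0, _stats())


def test_folded_population_recovery(linear_design, matcher):
    """On 100 events with 10 % folds the flag recovers >=90 % with <=5 % false."""
    params = SimParams(seed=5, p_fold=0.10, p_term_per_cycle=0.47)
    trace, truth = simulate_trace(linear_design, params, 100)
    result = analyze_trace(trace, linear_design)
    kept = result.events[result.events["kept"]].reset_index(drop=True)
    idx = matcher(kept, truth)
    true_folded = truth.loc[idx, "folded"].to_numpy()
    flagged = result.sized["folded"].to_numpy()
    assert true_folded.sum() > 0
    assert (flagged & true_folded).sum() >= 0.9 * true_folded.sum()
    assert (flagged & ~true_folded).sum() <= 0.05 * (~true_folded).sum()


def _spike_seq(kinds, t0=0.1, spacing=0.15):
    depth = {"R": 120.0, "BIT1": 60.0, "UNKNOWN": 70.0}
    return [
        SpikeCall(time_ms=t0 + i * spacing, depth_pA=depth[k], width_ms=0.02, kind=k)
        for i, k in enumerate(kinds)
    ]


@pytest.mark.parametrize(
    "kinds, orientation, n",
    [
        (["R", "BIT1", "BIT1"], ORIENT_FORWARD, 1),
        (["BIT1", "BIT1", "R"], ORIENT_REVERSE, 1),
        (["BIT1", "BIT1", "R", "BIT1", "BIT1", "R"], ORIENT_REVERSE, 2),
        (["R", "BIT1", "BIT1", "R", "BIT1", "BIT1"], ORIENT_FORWARD, 2),
        (["BIT1", "R", "BIT1"], ORIENT_AMBIGUOUS, 1),
        (["UNKNOWN"], ORIENT_AMBIGUOUS, 0),
    ],
)
def test_orientation_from_kind_pattern(linear_design, kinds, orientation, n):
    ann = annotate_event(0, 2.0, _spike_seq(kinds), linear_design, 120.0, folded=False)
    assert ann.orientation == orientation
    assert ann.n_cycles == n


def test_reverse_annotation_is_canonicalized(linear_design):
    spikes = _spike_seq(["BIT1", "BIT1", "R"])
    ann = annotate_event(0, 2.0, spikes, linear_design, 120.0, folded=False)
    assert [s.kind for s in ann.spikes] == ["R", "BIT1", "BIT1"]
    # mirrored times: t -> duration - t, re-sorted ascending
    assert [round(s.time_ms, 6) for s in ann.spikes] == [
        round(2.0 - s.time_ms, 6) for s in reversed(spikes)
    ]


def test_time_reversal_preserves_cycle_count(circular_design, noiseless_params):
    """Reversing an event's samples flips orientation but not n_cycles."""
    rng = np.random.default_rng(3)
    truth = GroundTruthRecord(index=0, true_length_kbp=4.6, orientation="forward", n_cycles=2)
    samples, _ = simulate_event(circular_design, truth, noiseless_params, rng)

    def annotate(x):
        _, calls = detect_spikes(x, DT, noiseless_params.baseline_pA, 0.0)
        calls = classify_spikes(calls)
        return annotate_event(0, len(x) * DT, calls, circular_design, 120.0, folded=False)

    fwd = annotate(samples)
    rev = annotate(samples[::-1].copy())
    assert fwd.n_cycles == rev.n_cycles == 2
    assert {fwd.orientation, rev.orientation} == {ORIENT_FORWARD, ORIENT_REVERSE}


def test_spike_count_exact_for_noiseless_population(circular_design, noiseless_params, matcher):
    """Noiseless unfolded events: called spikes equal ground-truth labels."""
    trace, truth = simulate_trace(circular_design, noiseless_params, 40)
    result = analyze_trace(trace, circular_design)
    kept = result.events[result.events["kept"]].reset_index(drop=True)
    idx = matcher(kept, truth)
    for ann, ti in zip(result.annotations, idx):
        expected = len(parse_time_list(truth.loc[ti, "spike_times_ms"]))
        assert len(ann.spikes) == expected
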