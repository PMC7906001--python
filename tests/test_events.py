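"""Velocity computation, adaptive thresholding and event classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazehand as gh
from gazehand.errors import FormatError, InsufficientDataError
from gazehand.events import (
    GAP,
    RAPID,
    STABLE,
    ClassifierConfig,
    classify_trajectory,
    compute_velocity,
    estimate_threshold,
    refine_runs,
)

from _oracles import oracle_refine_labels


# ---------------------------------------------------------------------- velocity

def test_constant_position_zero_speed():
    t = np.arange(10) * 10.0
    vel = compute_velocity(t, np.full((10, 2), 7.0))
    assert np.all(vel.speed == 0.0)


def test_uniform_motion_speed_value():
    # 5 px steps at 60 Hz -> 300 px/s
    t = np.arange(20) * (1000.0 / 60.0)
    pos = np.stack([5.0 * np.arange(20), np.zeros(20)], axis=1)
    vel = compute_velocity(t, pos)
    assert vel.speed == pytest.approx(300.0)
    assert len(vel.speed) == 19


def test_velocity_single_sample_errors():
    with pytest.raises(InsufficientDataError):
        compute_velocity([0.0], [[1.0, 1.0]])


def test_velocity_duplicate_timestamp_errors():
    with pytest.raises(FormatError):
        compute_velocity([0.0, 10.0, 10.0], np.zeros((3, 2)))


# ---------------------------------------------------------------------- threshold

def test_all_zero_speeds_floor_threshold():
    est = estimate_threshold(np.zeros(50))
    assert est.converged
    assert est.theta == ClassifierConfig().floor


def test_identical_speeds_converged():
    est = estimate_threshold(np.full(50, 42.0))
    assert est.converged and est.theta == pytest.approx(42.0)


def test_bimodal_threshold_separates_modes(rng):
    noise = rng.normal(10.0, 1.0, 950)
    spikes = rng.normal(1000.0, 10.0, 50)
    est = estimate_threshold(rng.permutation(np.concatenate([noise, spikes])))
    assert est.converged
    # brute-force check against both modes: essentially all noise below,
    # every spike above
    assert np.mean(noise < est.theta) > 0.99
    assert np.all(spikes > est.theta)
    assert noise.mean() < est.theta < spikes.min()


def test_threshold_insufficient_data():
    with pytest.raises(InsufficientDataError):
        estimate_threshold(np.arange(5.0))


def test_threshold_scales_with_data(rng):
    speeds = np.abs(rng.normal(10.0, 3.0, 500))
    cfg = ClassifierConfig(tolerance=1e-6)
    est1 = estimate_threshold(speeds, cfg)
    est2 = estimate_threshold(speeds * 7.0, cfg)
    assert est2.theta == pytest.approx(7.0 * est1.theta, rel=1e-6)


# ---------------------------------------------------------------------- refinement

def _run_refine(labels, unit_ms=10.0, min_stable=25.0, min_rapid=15.0):
    runs = refine_runs(labels, np.full(len(labels), unit_ms), min_stable, min_rapid)
    return [(k, b - a) for k, a, b in runs]


@pytest.mark.parametrize("n", range(1, 9))
def test_refinement_matches_bruteforce_ternary(n):
    """Grouping + filtering equals a literal rule-by-rule oracle on every
    ternary label sequence of length n."""
    for labels in itertools.product((STABLE, RAPID, GAP), repeat=n):
        got = _run_refine(list(labels))
        want = oracle_refine_labels(labels, 10.0, 25.0, 15.0)
        assert got == want, f"sequence {labels}"


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([STABLE, RAPID, GAP]), min_size=1, max_size=40))
def test_refinement_matches_bruteforce_random_long(labels):
    assert _run_refine(labels) == oracle_refine_labels(labels, 10.0, 25.0, 15.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([STABLE, RAPID, GAP]), min_size=1, max_size=30))
def test_refinement_preserves_total_duration(labels):
    runs = refine_runs(labels, np.full(len(labels), 10.0), 25.0, 15.0)
    assert sum(b - a for _, a, b in runs) == len(labels)
    for (_, _, b1), (_, a2, _) in zip(runs, runs[1:]):
        assert b1 == a2  # contiguous partition
    assert all(k1 != k2 for (k1, _, _), (k2, _, _) in zip(runs, runs[1:]))


def test_gap_never_merges_into_stable():
    got = _run_refine([STABLE] * 5 + [GAP] + [STABLE] * 5)
    assert got == [(STABLE, 5), (GAP, 1), (STABLE, 5)]


# ---------------------------------------------------------------------- classification

def test_constant_stream_single_stable_event():
    t = np.arange(120) * (1000.0 / 60.0)
    pos = np.full((120, 2), 500.0)
    seq = classify_trajectory(t, pos)
    assert [e.kind for e in seq.events] == [STABLE]
    assert seq.events[0].t_start == t[0] and seq.events[0].t_end == t[-1]
    np.testing.assert_allclose(seq.events[0].centroid, [500.0, 500.0])


def test_partition_property(analyzed_participant):
    """Events tile the classified window exactly, without overlap."""
    _, _, eye_ev, hand_ev = analyzed_participant
    for seq in (eye_ev, hand_ev):
        assert seq.events[0].t_start == seq.window[0]
        assert seq.events[-1].t_end == seq.window[1]
        for a, b in zip(seq.events, seq.events[1:]):
            assert a.t_end == b.t_start
        total = sum(e.duration for e in seq.events)
        assert total == pytest.approx(seq.window[1] - seq.window[0])


def test_scale_invariance_of_labels(intermediate_participant):
    """Uniformly rescaling positions leaves the event labeling unchanged."""
    hand = intermediate_participant.hand
    seq1 = gh.classify_events(hand)
    import dataclasses

    scaled = dataclasses.replace(hand, tool=hand.tool * 13.0, cam=hand.cam * 13.0)
    seq2 = gh.classify_events(scaled)
    assert [e.kind for e in seq1.events] == [e.kind for e in seq2.events]
    assert [e.t_start for e in seq1.events] == [e.t_start for e in seq2.events]


def test_invalid_samples_become_gaps():
    t = np.arange(60) * 10.0
    pos = np.full((60, 2), 100.0)
    valid = np.ones(60, bool)
    valid[25:30] = False
    seq = classify_trajectory(t, pos, valid=valid)
    kinds = [e.kind for e in seq.events]
    assert kinds == [STABLE, GAP, STABLE]


def test_binocular_conjunction_vs_disjunction(default_spec):
    """A movement seen by one eye only breaks stability under conjunction
    but not under disjunction."""
    rng = np.random.default_rng(5)
    t = np.arange(300) * (1000.0 / 60.0)
    moving = np.full((300, 2), 400.0) + rng.normal(0, 0.2, (300, 2))
    quiet = np.full((300, 2), 408.0) + rng.normal(0, 0.2, (300, 2))
    moving[140:160, 0] += np.linspace(0, 300, 20)  # one-eye excursion
    moving[160:, 0] += 300
    g = gh.GazeStream(t=t, left=moving, right=quiet)
    conj = gh.classify_events(g, ClassifierConfig(binocular_rule="conjunction"))
    disj = gh.classify_events(g, ClassifierConfig(binocular_rule="disjunction"))
    assert any(e.kind == RAPID for e in conj.events)
    assert all(e.kind == STABLE for e in disj.events)


def test_classify_too_short_errors():
    with pytest.raises(InsufficientDataError):
        classify_trajectory([0.0], [[0.0, 0.0]])


def test_planted_events_recovered_with_tight_boundaries(analyzed_participant):
    """Classifier output matches generator ground truth event-for-event,
    with boundaries within one sample period."""
    p, _, eye_ev, hand_ev = analyzed_participant
    for seq, truth, rate in (
        (eye_ev, p.truth_eye, 60.0),
        (hand_ev, p.truth_hand, 100.0),
    ):
        got = [e for e in seq.events if e.kind != GAP]
        want = [e for e in truth.events if e.kind != GAP]
        assert [e.kind for e in got] == [e.kind for e in want]
        tol = 1000.0 / rate + 1.0
        for a, b in zip(got, want):
            assert abs(a.t_start - b.t_start) <= tol
            assert abs(a.t_end - b.t_end) <= tol
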