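"""Fibre generator arithmetic and track classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sphasetools import (
    AnalysisParams,
    ClusterSizePMF,
    Fiber,
    FiberClass,
    FiberConfig,
    FiberTrack,
    NormalSpec,
    classify_fiber,
    cohort_report,
    estimate_fork_rate,
    gen_fibers,
    inter_origin_distances,
    kbp_to_um,
    segment_primary_cluster,
    um_to_kbp,
)

ONE_REPLICON = ClusterSizePMF(sizes=(1,), probs=(1.0,))


def fixed_rate_config(**kw):
    base = dict(
        fork_rate_kbp_per_min=(1.5, 1.5),
        noise_sd_kbp=0.0,
        replicons_per_cluster=ONE_REPLICON,
        class_mix=(1.0, 0.0, 0.0),
    )
    base.update(kw)
    return FiberConfig(**base)


def test_um_kbp_conversion_values():
    assert um_to_kbp(1.0) == pytest.approx(2.59)
    assert um_to_kbp(0.0) == 0.0
    assert um_to_kbp(34.7) == pytest.approx(89.873)


@given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_um_kbp_roundtrip_identity(x):
    assert kbp_to_um(um_to_kbp(x)) == pytest.approx(x, abs=1e-9)


def test_single_replicon_track_arithmetic():
    """One origin, 1.5 kbp/min, 30 min pulse: the bidirectional channel-1
    track is 90 kbp; after a 60 min chase each channel-2 fork track starts
    90 kbp beyond the channel-1 end and is 30 kbp long."""
    cfg = fixed_rate_config()
    (f,) = gen_fibers(cfg, 1, seed=1)
    ch1 = f.channel_tracks(1)
    ch2 = f.channel_tracks(2)
    assert len(ch1) == 1 and len(ch2) == 2
    assert um_to_kbp(ch1[0].length) == pytest.approx(90.0, abs=1e-6)
    for t in ch2:
        assert um_to_kbp(t.length) == pytest.approx(30.0, abs=1e-6)
        gap = max(ch1[0].start - t.end, t.start - ch1[0].end)
        assert um_to_kbp(gap) == pytest.approx(90.0, abs=1e-6)
    assert classify_fiber(f) is FiberClass.EXTENDING


def test_zero_second_pulse_gives_no_channel2():
    cfg = fixed_rate_config(pulse2_min=0.0)
    fibers = gen_fibers(cfg, 5, seed=2)
    assert all(not f.channel_tracks(2) for f in fibers)


@pytest.mark.parametrize("seed", range(5))
def test_noise_free_classification_matches_ground_truth(seed):
    cfg = FiberConfig(noise_sd_kbp=0.0)
    fibers = gen_fibers(cfg, 200, seed=seed)
    for f in fibers:
        assert classify_fiber(f).value == f.truth_class


def test_segment_primary_cluster_gap_rule():
    """Channel-1 runs split at gaps > threshold (brute-force gap scan)."""
    tracks = [
        FiberTrack("f", 1, 0.0, 90.0),
        FiberTrack("f", 1, 150.0, 240.0),
        FiberTrack("f", 1, 600.0, 690.0),
    ]
    f = Fiber("f", tracks, unit="kbp")
    seg = segment_primary_cluster(f, AnalysisParams(cluster_gap_kbp=250.0))
    # gap 600-240=360 > 250: cluster is the first two tracks
    assert seg.cluster == (0.0, 240.0)
    assert seg.cluster_tracks.shape[0] == 2
    assert seg.left_flank == (-250.0, 0.0) and seg.right_flank == (240.0, 490.0)


def test_classify_rule_applications():
    params = AnalysisParams()
    # 3 separated channel-2 tracks in a flank -> secondary activation
    f = Fiber("s", [
        FiberTrack("s", 1, 500.0, 590.0),
        FiberTrack("s", 2, 640.0, 670.0),
        FiberTrack("s", 2, 700.0, 730.0),
        FiberTrack("s", 2, 760.0, 790.0),
    ], unit="kbp")
    assert classify_fiber(f, params) is FiberClass.SECONDARY
    # lone channel-2 track 300 kbp from the nearest channel-1 -> uncoupled
    f = Fiber("u", [
        FiberTrack("u", 1, 0.0, 90.0),
        FiberTrack("u", 2, 150.0, 180.0),
        FiberTrack("u", 2, 390.0, 430.0),
    ], unit="kbp")
    assert classify_fiber(f, params) is FiberClass.UNCOUPLED
    # channel-2-only fiber routes to uncoupled
    f = Fiber("o", [FiberTrack("o", 2, 0.0, 40.0)], unit="kbp")
    assert classify_fiber(f, params) is FiberClass.UNCOUPLED


def test_inter_origin_distances_midpoint_rule():
    f = Fiber("f", [FiberTrack("f", 1, 0.0, 90.0), FiberTrack("f", 1, 150.0, 240.0)],
              unit="kbp")
    assert inter_origin_distances(f, AnalysisParams()) == pytest.approx([150.0])
    single = Fiber("g", [FiberTrack("g", 1, 0.0, 90.0)], unit="kbp")
    assert inter_origin_distances(single, AnalysisParams()).size == 0


def test_inter_origin_recovery_from_generator():
    """With wide fixed spacings and no noise the recovered midpoint
    separations equal the planted origin spacings."""
    cfg = fixed_rate_config(
        replicons_per_cluster=ClusterSizePMF(sizes=(4,), probs=(1.0,)),
        origin_spacing_extending=NormalSpec(200.0, 1.0),
    )
    params = AnalysisParams(kbp_per_um=cfg.kbp_per_um)
    for f in gen_fibers(cfg, 20, seed=3):
        planted = np.diff(np.sort(f.truth_origins_kbp[:4]))
        got = inter_origin_distances(f, params)
        np.testing.assert_allclose(got, planted, atol=1e-6)


def test_fork_rate_estimates_and_flags():
    r = estimate_fork_rate(90.0, 30.0, bidirectional=True)
    assert r.rate_kbp_per_min == pytest.approx(1.5) and not r.implausible
    r = estimate_fork_rate(30.0, 20.0, bidirectional=False)
    assert r.rate_kbp_per_min == pytest.approx(1.5) and not r.implausible
    r = estimate_fork_rate(300.0, 30.0, bidirectional=True)
    assert r.rate_kbp_per_min == pytest.approx(5.0) and r.implausible


def test_cohort_all_extending_proportions():
    cfg = fixed_rate_config()
    fibers = gen_fibers(cfg, 50, seed=4)
    rep = cohort_report(fibers)
    assert rep.class_proportions["extending"] == 1.0
    assert rep.class_proportions["secondary_activation"] == 0.0
    assert sum(rep.class_proportions.values()) == pytest.approx(1.0)
    assert rep.fork_rate["mean"] == pytest.approx(1.5, abs=1e-6)


def test_unlabeled_fiber_changes_nothing():
    cfg = fixed_rate_config()
    fibers = gen_fibers(cfg, 30, seed=5)
    rep1 = cohort_report(fibers)
    rep2 = cohort_report(fibers + [Fiber("empty", [], unit="um")])
    assert rep1.to_dict() == rep2.to_dict()


def test_short_fibers_excluded_by_length_filter():
    short = Fiber("s", [FiberTrack("s", 1, 0.0, 90.0)], unit="kbp", length=500.0)
    keep = Fiber("k", [FiberTrack("k", 1, 0.0, 90.0)], unit="kbp", length=900.0)
    rep = cohort_report([short, keep])
    assert rep.n_fibers == 1 and rep.n_excluded_short == 1


def test_cohort_spacing_ordering_matches_generator():
    """Extending clusters have wider origin spacing than secondary ones."""
    cfg = FiberConfig(noise_sd_kbp=0.0)
    rep = cohort_report(gen_fibers(cfg, 400, seed=6))
    assert (
        rep.inter_origin_kbp["extending"]["mean"]
        > rep.inter_origin_kbp["secondary_activation"]["mean"]
    )
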