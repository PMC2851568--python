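"""Nearest-neighbour statistics, co-association, occupancy, co-localization."""

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from sphasetools import (
    DistanceSample,
    NucleusConfig,
    coassociation_fraction,
    colocalization_fraction,
    compare_conditions,
    gen_nuclear_foci,
    nn_cross_channel,
    nn_within_channel,
    summarize,
    volume_occupancy,
)

from .conftest import make_points_set

BIG = NucleusConfig(nucleus_diameter_um=100.0, focus_diameter_nm=500.0,
                    foci_per_zone=1, n_zones=1)


def _brute_cross(a, b):
    return cdist(a, b).min(axis=1)


def _brute_within(a):
    d = cdist(a, a)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def test_cross_channel_345_triangle():
    a = make_points_set([[0, 0, 0]], nucleus=BIG)
    b = make_points_set([[300, 400, 0]], nucleus=BIG)
    assert nn_cross_channel(a, b).values[0] == pytest.approx(500.0)


def test_cross_channel_identical_coordinates_zero():
    pts = np.random.default_rng(0).uniform(-1000, 1000, (20, 3))
    a = make_points_set(pts, nucleus=BIG)
    b = make_points_set(pts.copy(), nucleus=BIG)
    assert np.all(nn_cross_channel(a, b).values == 0.0)
    assert coassociation_fraction(a, b, 1.0) == 1.0


@pytest.mark.parametrize("seed", range(20))
def test_nn_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    na, nb = rng.integers(2, 200, size=2)
    pa = rng.uniform(-4000, 4000, (na, 3))
    pb = rng.uniform(-4000, 4000, (nb, 3))
    a = make_points_set(pa, nucleus=BIG)
    b = make_points_set(pb, nucleus=BIG)
    np.testing.assert_allclose(nn_cross_channel(a, b).values, _brute_cross(pa, pb), rtol=1e-12)
    np.testing.assert_allclose(nn_within_channel(a).values, _brute_within(pa), rtol=1e-12)


def test_within_channel_pair_and_triangle():
    a = make_points_set([[0, 0, 0], [500, 0, 0]], nucleus=BIG)
    assert np.all(nn_within_channel(a).values == pytest.approx(500.0))
    d = 700.0
    tri = make_points_set(
        [[0, 0, 0], [d, 0, 0], [d / 2, d * np.sqrt(3) / 2, 0]], nucleus=BIG
    )
    assert np.all(np.abs(nn_within_channel(tri).values - d) < 1e-9)
    with pytest.raises(ValueError):
        nn_within_channel(make_points_set([[0, 0, 0]], nucleus=BIG))


def test_summarize_small_samples():
    s = summarize(DistanceSample(np.array([1.0, 2.0, 3.0])))
    assert (s.mean, s.sd, s.n) == (2.0, 1.0, 3)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        single = summarize(DistanceSample(np.array([7.0])))
    assert single == (7.0, 0.0, 1) or (single.mean, single.sd, single.n) == (7.0, 0.0, 1)
    assert caught


def test_summarize_normal_sample_clt_bounds():
    rng = np.random.default_rng(123)
    s = summarize(DistanceSample(np.abs(rng.normal(350, 100, 10_000))))
    assert abs(s.mean - 350) < 3 and abs(s.sd - 100) < 3


def test_welch_identical_and_degenerate_samples():
    same = DistanceSample(np.array([1.0, 2.0, 3.0]))
    res = compare_conditions(same, same)
    assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)
    flat = DistanceSample(np.array([5.0, 5.0]))
    res = compare_conditions(flat, DistanceSample(np.array([5.0, 5.0, 5.0])))
    assert res.p_value == 1.0
    res = compare_conditions(flat, DistanceSample(np.array([9.0, 9.0])))
    assert res.p_value == 0.0


def test_welch_separated_samples_significant():
    d1 = DistanceSample(np.array([0.0, 1e-6, 0.0, 2e-6]))
    d2 = DistanceSample(np.array([10.0, 10.0 + 1e-6, 10.0, 10.0 - 1e-6]))
    assert compare_conditions(d1, d2).p_value < 1e-6
    # analytic power at the Fig 3G-like scale: n=200 each, far-apart means
    rng = np.random.default_rng(5)
    a = DistanceSample(np.abs(rng.normal(150, 75, 200)))
    b = DistanceSample(np.abs(rng.normal(350, 110, 200)))
    assert compare_conditions(a, b).p_value < 1e-20


def test_coassociation_monotone_in_threshold():
    rng = np.random.default_rng(2)
    a = make_points_set(rng.uniform(-3000, 3000, (50, 3)), nucleus=BIG)
    b = make_points_set(rng.uniform(-3000, 3000, (60, 3)), nucleus=BIG)
    fracs = [coassociation_fraction(a, b, t) for t in (100, 300, 500, 1000, 5000)]
    assert fracs == sorted(fracs)


def test_volume_occupancy_default_and_degenerate():
    fs = gen_nuclear_foci(NucleusConfig(), "random", seed=0)
    assert volume_occupancy(fs) == pytest.approx(0.4375, abs=1e-12)
    empty = fs.subset(np.zeros(len(fs), dtype=bool))
    assert volume_occupancy(empty) == 0.0
    one = make_points_set([[0, 0, 0]], diameters=10_000.0,
                          nucleus=NucleusConfig(nucleus_diameter_um=10.0,
                                                focus_diameter_nm=9_999.999))
    one.diameters[:] = 10_000.0
    assert volume_occupancy(one) == pytest.approx(1.0)


def test_volume_occupancy_additive_over_disjoint_subsets():
    fs = gen_nuclear_foci(NucleusConfig(foci_per_zone=30, n_zones=4), "random", seed=1)
    mask = np.zeros(len(fs), dtype=bool)
    mask[::2] = True
    total = volume_occupancy(fs)
    assert volume_occupancy(fs.subset(mask)) + volume_occupancy(fs.subset(~mask)) == pytest.approx(total)


def test_colocalization_identical_and_disjoint():
    a = make_points_set([[0, 0, 0]], diameters=1000.0, nucleus=BIG)
    assert colocalization_fraction(a, a, voxel_nm=50.0) == 1.0
    b = make_points_set([[20_000, 0, 0]], diameters=1000.0, nucleus=BIG)
    assert colocalization_fraction(a, b, voxel_nm=50.0) == 0.0


def test_colocalization_lens_overlap_closed_form():
    """Two equal spheres of radius r with centres r apart share a lens of
    5/16 of a sphere volume."""
    r = 1000.0
    a = make_points_set([[0, 0, 0]], diameters=2 * r, nucleus=BIG)
    b = make_points_set([[r, 0, 0]], diameters=2 * r, nucleus=BIG)
    frac = colocalization_fraction(a, b, voxel_nm=20.0)
    assert frac == pytest.approx(5 / 16, rel=0.02)
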