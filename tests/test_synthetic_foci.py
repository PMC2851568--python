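"""Nuclear-foci generator: counts, geometry, chains, segregation, plasticity."""

import numpy as np
import pytest

from sphasetools import (
    ActivationModel,
    CapacityError,
    NucleusConfig,
    apply_plasticity,
    apply_segregation,
    gen_nuclear_foci,
)
from sphasetools.synthetic_data import _uniform_in_sphere


@pytest.mark.parametrize("model", ["random", "spatial", "genetic"])
def test_counts_and_containment(small_nucleus, model):
    fs = gen_nuclear_foci(small_nucleus, model, seed=11, n_chains=5)
    assert len(fs) == small_nucleus.foci_per_zone * small_nucleus.n_zones
    # every focus fully inside the nucleus
    r = np.linalg.norm(fs.centers, axis=1)
    assert np.all(r + fs.diameters / 2 <= small_nucleus.radius_nm + 1e-9)
    # exactly foci_per_zone per zone
    counts = np.bincount(fs.zones, minlength=small_nucleus.n_zones + 1)[1:]
    assert np.all(counts == small_nucleus.foci_per_zone)
    fs.validate()


def test_zero_zones_gives_empty_set():
    cfg = NucleusConfig(foci_per_zone=10, n_zones=0)
    fs = gen_nuclear_foci(cfg, "random", seed=0)
    assert len(fs) == 0


def test_rejection_sampler_capacity_error():
    rng = np.random.default_rng(0)
    with pytest.raises(CapacityError):
        _uniform_in_sphere(rng, 5, 0.0)


def test_genetic_chains_next_zone_within_two_steps():
    """Every zone-1 focus has a zone-2 focus within 2 chain steps.

    Verified by brute-force traversal of the generated chain structure
    (2 zones x 5 foci over 2 chains).
    """
    cfg = NucleusConfig(foci_per_zone=5, n_zones=2)
    fs = gen_nuclear_foci(cfg, "genetic", seed=3, n_chains=2)
    by_chain = {}
    for i in range(len(fs)):
        by_chain.setdefault(int(fs.chain_ids[i]), {})[int(fs.chain_pos[i])] = int(fs.zones[i])
    for i in np.flatnonzero(fs.zones == 1):
        chain = by_chain[int(fs.chain_ids[i])]
        pos = int(fs.chain_pos[i])
        near = [chain.get(pos + d) for d in (-2, -1, 1, 2)]
        assert 2 in near


@pytest.mark.parametrize("seed", range(5))
def test_genetic_wave_adjacency_invariant(seed):
    """Along each chain the zone advances by one per focus (wrapping), so the
    last zone-z focus of a chain is chain-adjacent to a zone-(z+1) focus for
    every z < n_zones, except possibly at the chain terminus."""
    cfg = NucleusConfig(foci_per_zone=12, n_zones=4)
    fs = gen_nuclear_foci(cfg, "genetic", seed=seed, n_chains=4)
    for c in np.unique(fs.chain_ids):
        m = fs.chain_ids == c
        order = np.argsort(fs.chain_pos[m])
        zones = fs.zones[m][order]
        nxt = zones % cfg.n_zones + 1
        assert np.all(zones[1:] == nxt[:-1])


def test_spatial_zones_cluster_around_seeds(small_nucleus):
    fs = gen_nuclear_foci(small_nucleus, "spatial", seed=7, n_chains=5)
    # same-zone foci are spatially tighter than the full set on average
    whole = fs.centers.std()
    spreads = []
    for z in range(1, small_nucleus.n_zones + 1):
        sub = fs.zone(z)
        spreads.append(np.linalg.norm(sub.centers - sub.centers.mean(0), axis=1).mean())
    full = np.linalg.norm(fs.centers - fs.centers.mean(0), axis=1).mean()
    assert np.mean(spreads) < full


def test_segregation_keep_all_identity(small_nucleus):
    fs = gen_nuclear_foci(small_nucleus, "genetic", seed=5, n_chains=5)
    kept = apply_segregation(fs, 5, seed=9)
    assert np.array_equal(kept.ids, fs.ids)
    assert np.array_equal(kept.centers, fs.centers)


def test_segregation_counts_and_errors():
    fs = gen_nuclear_foci(NucleusConfig(foci_per_zone=46, n_zones=2), "genetic", seed=1)
    kept = apply_segregation(fs, 3, seed=2)
    assert np.unique(kept.chain_ids).size == 3
    empty = apply_segregation(fs, 0, seed=2)
    assert len(empty) == 0
    with pytest.raises(ValueError):
        apply_segregation(fs, 47, seed=2)


def test_plasticity_zero_is_identity(small_nucleus):
    fs = gen_nuclear_foci(small_nucleus, "genetic", seed=4, n_chains=5)
    moved = apply_plasticity(fs, 0.0, seed=8)
    assert np.array_equal(moved.centers, fs.centers)


def test_plasticity_displacement_matches_chi_mean():
    """Independent 3D Gaussian displacement has mean norm sigma*sqrt(8/pi).

    A large nucleus keeps boundary clamping negligible.
    """
    cfg = NucleusConfig(nucleus_diameter_um=60.0, foci_per_zone=500, n_zones=2)
    fs = gen_nuclear_foci(cfg, "random", seed=10)
    sd = 300.0
    moved = apply_plasticity(fs, sd, seed=11)
    disp = np.linalg.norm(moved.centers - fs.centers, axis=1)
    expected = sd * np.sqrt(8 / np.pi)
    assert abs(disp.mean() - expected) / expected < 0.05


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_plasticity_preserves_chain_connectivity(seed):
    """With local jitter, chain-adjacent separations stay within 1.5x the
    original value (checked exhaustively over all adjacent pairs)."""
    cfg = NucleusConfig(foci_per_zone=20, n_zones=5)
    fs = gen_nuclear_foci(cfg, "genetic", seed=seed, n_chains=4)
    moved = apply_plasticity(fs, 300.0, seed=seed + 100, local_jitter_nm=300.0)
    for c in np.unique(fs.chain_ids):
        m = fs.chain_ids == c
        order = np.argsort(fs.chain_pos[m])
        before = fs.centers[m][order]
        after = moved.centers[m][order]
        d0 = np.linalg.norm(np.diff(before, axis=0), axis=1)
        d1 = np.linalg.norm(np.diff(after, axis=0), axis=1)
        assert np.all(d1 <= 1.5 * d0 + 1e-6)
    # still inside the nucleus
    r = np.linalg.norm(moved.centers, axis=1)
    assert np.all(r + moved.diameters / 2 <= cfg.radius_nm + 1e-6)


@pytest.mark.parametrize("model", ["random", "spatial", "genetic"])
def test_generation_is_reproducible(small_nucleus, model):
    a = gen_nuclear_foci(small_nucleus, model, seed=42, n_chains=5)
    b = gen_nuclear_foci(small_nucleus, model, seed=42, n_chains=5)
    c = gen_nuclear_foci(small_nucleus, model, seed=43, n_chains=5)
    assert np.array_equal(a.centers, b.centers)
    assert np.array_equal(a.zones, b.zones)
    assert not np.array_equal(a.centers, c.centers)
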