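import numpy as np
import pytest

from sphasetools import ActivationModel, FociSet, NucleusConfig, gen_nuclear_foci


@pytest.fixture
def small_nucleus() -> NucleusConfig:
    """A light configuration: 5 zones x 20 foci in a 10 um nucleus."""
    return NucleusConfig(foci_per_zone=20, n_zones=5)


@pytest.fixture
def default_nucleus() -> NucleusConfig:
    return NucleusConfig()


def make_points_set(centers, diameters=500.0, nucleus=None, zones=None) -> FociSet:
    """Hand-built FociSet for geometry tests."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    n = centers.shape[0]
    nucleus = nucleus or NucleusConfig()
    diam = np.full(n, diameters, dtype=float) if np.isscalar(diameters) else np.asarray(diameters)
    zones = np.ones(n, dtype=int) if zones is None else np.asarray(zones)
    ids = np.arange(n)
    return FociSet(
        nucleus=nucleus,
        model=ActivationModel.RANDOM,
        seed=0,
        ids=ids,
        centers=centers,
        diameters=diam,
        zones=zones,
        chain_ids=ids.copy(),
        chain_pos=np.zeros(n, dtype=int),
    )
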