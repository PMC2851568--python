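"""Generators for every input the pipeline consumes.

Three families of synthetic data stand in for the microscopy and
genome-wide inputs:

* nuclear configurations of replication foci under three S-phase
  activation models (genetic / spatial / random continuity), emulating
  Monte-Carlo nuclei of 350 spherical foci per 1-h time zone, 10 zones,
  500 nm focus diameter inside a 10 um nucleus;
* binned replication-timing profiles with planted triangular domains;
* pulse-chase-pulse labeled DNA fibres (30 min label, 1 h chase, 20 min
  label; fork rates 1-2 kbp/min) with per-fibre ground-truth classes.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .fiber_analysis import KBP_PER_UM, Fiber, FiberTrack
from .replicon_clusters import ClusterSizePMF
from .timing_domains import TimingProfile

__all__ = [
    "CapacityError",
    "NucleusConfig",
    "ActivationModel",
    "Focus",
    "FociSet",
    "FiberConfig",
    "NormalSpec",
    "TimingProfileSpec",
    "gen_nuclear_foci",
    "apply_segregation",
    "apply_plasticity",
    "gen_timing_profile",
    "gen_fibers",
]


class CapacityError(RuntimeError):
    """The nucleus cannot hold the requested foci configuration."""


# ---------------------------------------------------------------------------
# nuclear foci
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucleusConfig:
    """Geometry of the simulated nucleus and its S-phase time zones."""

    nucleus_diameter_um: float = 10.0
    focus_diameter_nm: float = 500.0
    foci_per_zone: int = 350
    n_zones: int = 10
    zone_duration_h: float = 1.0

    def __post_init__(self) -> None:
        if self.nucleus_diameter_um <= 0 or self.focus_diameter_nm <= 0:
            raise ValueError("diameters must be positive")
        if self.foci_per_zone < 0 or self.n_zones < 0:
            raise ValueError("counts must be non-negative")
        if self.zone_duration_h <= 0:
            raise ValueError("zone duration must be positive")
        if self.focus_diameter_nm >= self.nucleus_diameter_um * 1000:
            raise ValueError("focus diameter must be smaller than the nucleus")

    @property
    def radius_nm(self) -> float:
        return self.nucleus_diameter_um * 500.0

    @property
    def focus_radius_nm(self) -> float:
        return self.focus_diameter_nm / 2.0

    @property
    def placement_radius_nm(self) -> float:
        """Radius available to focus centres so spheres stay fully inside."""
        return self.radius_nm - self.focus_radius_nm


class ActivationModel(str, enum.Enum):
    GENETIC = "genetic"
    SPATIAL = "spatial"
    RANDOM = "random"


@dataclass(frozen=True)
class Focus:
    id: int
    center: tuple[float, float, float]
    diameter: float
    zone: int
    chain_id: int
    chain_pos: int


@dataclass
class FociSet:
    """A labeled 3D point set of spherical foci inside a spherical nucleus.

    Column-oriented: ``centers`` is (n, 3) in nm with the nucleus centred at
    the origin; ``zones`` are 1-based time-zone indices; ``chain_ids`` and
    ``chain_pos`` encode the chromosome-territory chain each focus belongs
    to and its position along that chain.
    """

    nucleus: NucleusConfig
    model: ActivationModel
    seed: int
    ids: np.ndarray
    centers: np.ndarray
    diameters: np.ndarray
    zones: np.ndarray
    chain_ids: np.ndarray
    chain_pos: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.zones = np.asarray(self.zones, dtype=np.int64)
        self.chain_ids = np.asarray(self.chain_ids, dtype=np.int64)
        self.chain_pos = np.asarray(self.chain_pos, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.ids.size)

    def validate(self) -> None:
        radii = np.linalg.norm(self.centers, axis=1)
        if np.any(radii + self.diameters / 2 > self.nucleus.radius_nm + 1e-6):
            bad = int(np.argmax(radii + self.diameters / 2))
            raise ValueError(f"focus id {self.ids[bad]} extends outside the nucleus")
        if self.nucleus.n_zones and len(self):
            if self.zones.min() < 1 or self.zones.max() > self.nucleus.n_zones:
                raise ValueError("zone index outside [1, n_zones]")
        for c in np.unique(self.chain_ids):
            pos = self.chain_pos[self.chain_ids == c]
            if np.unique(pos).size != pos.size:
                raise ValueError(f"duplicate chain_pos in chain {c}")

    def subset(self, mask: np.ndarray) -> "FociSet":
        return FociSet(
            nucleus=self.nucleus,
            model=self.model,
            seed=self.seed,
            ids=self.ids[mask],
            centers=self.centers[mask],
            diameters=self.diameters[mask],
            zones=self.zones[mask],
            chain_ids=self.chain_ids[mask],
            chain_pos=self.chain_pos[mask],
        )

    def zone(self, z: int) -> "FociSet":
        """Foci active in time zone ``z`` (a labelling channel)."""
        return self.subset(self.zones == z)

    @property
    def foci(self) -> list[Focus]:
        return [
            Focus(
                id=int(self.ids[i]),
                center=tuple(self.centers[i]),
                diameter=float(self.diameters[i]),
                zone=int(self.zones[i]),
                chain_id=int(self.chain_ids[i]),
                chain_pos=int(self.chain_pos[i]),
            )
            for i in range(len(self))
        ]


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform points in a ball, by rejection from the bounding cube."""
    if n == 0:
        return np.zeros((0, 3))
    if radius <= 0:
        raise CapacityError("no room for focus centres inside the nucleus")
    out = np.empty((n, 3))
    got = 0
    for _ in range(1000):
        m = max(2 * (n - got), 16)
        pts = rng.uniform(-radius, radius, size=(m, 3))
        pts = pts[np.einsum("ij,ij->i", pts, pts) <= radius * radius]
        take = min(pts.shape[0], n - got)
        out[got : got + take] = pts[:take]
        got += take
        if got == n:
            return out
    raise CapacityError("rejection sampling failed to place the requested foci")


def _chain_walk(
    rng: np.random.Generator, length: int, step: float, radius: float
) -> np.ndarray:
    """Fixed-step random walk inside a ball, reflected radially at the wall."""
    pts = np.empty((length, 3))
    pts[0] = _uniform_in_sphere(rng, 1, radius)[0]
    for i in range(1, length):
        d = rng.normal(size=3)
        norm = np.linalg.norm(d)
        while norm < 1e-12:
            d = rng.normal(size=3)
            norm = np.linalg.norm(d)
        q = pts[i - 1] + step * d / norm
        r = np.linalg.norm(q)
        if r > radius:
            q *= max(2 * radius - r, 0.0) / r if r > 0 else 0.0
            r2 = np.linalg.norm(q)
            if r2 > radius:  # pathological step size
                q *= radius / r2
        pts[i] = q
    return pts


def _chain_lengths(total: int, n_chains: int) -> np.ndarray:
    base, rem = divmod(total, n_chains)
    return np.array([base + (1 if i < rem else 0) for i in range(n_chains)])


def gen_nuclear_foci(
    config: NucleusConfig,
    model: ActivationModel | str,
    seed: int,
    n_chains: int = 46,
    chain_step_nm: float | None = None,
) -> FociSet:
    """Generate one simulated nucleus of labeled replication foci.

    Model semantics:

    random
        centres uniform in the nucleus; zone labels a random permutation
        with exactly ``foci_per_zone`` per zone, independent of position;
        each focus is its own chain.
    spatial
        centres from chromosome-territory chain walks; zone labels by
        proximity to one uniformly placed seed point per zone (rebalanced
        to exact per-zone counts), so same-zone foci cluster in space.
    genetic
        centres from chain walks; along each chain the zone label advances
        by one per focus, wrapping after the last zone, so that every focus
        is chain-adjacent to a focus of the next time zone.  Each wrap is
        one replication wave, mimicking alternating early/late bands.

    ``chain_step_nm`` defaults to 0.75 x focus diameter, the measured
    centre-to-centre separation of foci labeled in consecutive intervals
    (350-390 nm for 500 nm foci).  Sphere overlap is permitted: the 44%
    occupancy figure for the default configuration is the naive volume-sum
    ratio.
    """
    model = ActivationModel(model)
    rng = np.random.default_rng(seed)
    n = config.foci_per_zone * config.n_zones
    step = chain_step_nm if chain_step_nm is not None else 0.75 * config.focus_diameter_nm

    def _empty() -> FociSet:
        z = np.zeros(0, dtype=np.int64)
        return FociSet(config, model, seed, z, np.zeros((0, 3)), np.zeros(0), z, z, z)

    if n == 0:
        return _empty()
    if config.placement_radius_nm <= 0:
        raise CapacityError("focus radius exceeds nucleus radius")

    ids = np.arange(n, dtype=np.int64)
    diameters = np.full(n, config.focus_diameter_nm)

    if model is ActivationModel.RANDOM:
        centers = _uniform_in_sphere(rng, n, config.placement_radius_nm)
        zones = rng.permutation(np.repeat(np.arange(1, config.n_zones + 1), config.foci_per_zone))
        return FociSet(config, model, seed, ids, centers, diameters, zones, ids.copy(), np.zeros(n, dtype=np.int64))

    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_chains > n:
        raise ValueError("more chains than foci requested")

    lengths = _chain_lengths(n, n_chains)
    centers = np.empty((n, 3))
    chain_ids = np.empty(n, dtype=np.int64)
    chain_pos = np.empty(n, dtype=np.int64)
    off = 0
    for c, lc in enumerate(lengths):
        centers[off : off + lc] = _chain_walk(rng, int(lc), step, config.placement_radius_nm)
        chain_ids[off : off + lc] = c
        chain_pos[off : off + lc] = np.arange(lc)
        off += lc

    if model is ActivationModel.GENETIC:
        # one global cyclic wave 1..Z,1..Z,... cut into chains: exact per-zone
        # counts and every non-terminal focus is followed by the next zone
        zones = np.tile(np.arange(1, config.n_zones + 1), config.foci_per_zone)
    else:  # spatial
        zones = _spatial_zones(rng, centers, config)
    return FociSet(config, model, seed, ids, centers, diameters, zones, chain_ids, chain_pos)


def _spatial_zones(
    rng: np.random.Generator, centers: np.ndarray, config: NucleusConfig
) -> np.ndarray:
    """Zone of the nearest per-zone seed point, rebalanced to exact counts."""
    nz, per = config.n_zones, config.foci_per_zone
    seeds = _uniform_in_sphere(rng, nz, config.placement_radius_nm)
    d = np.linalg.norm(centers[:, None, :] - seeds[None, :, :], axis=2)
    assign = np.argmin(d, axis=1)
    counts = np.bincount(assign, minlength=nz)
    while counts.max() > per:
        z_over = int(np.argmax(counts))
        members = np.flatnonzero(assign == z_over)
        worst = members[int(np.argmax(d[members, z_over]))]
        under = np.flatnonzero(counts < per)
        assign[worst] = under[int(np.argmin(d[worst, under]))]
        counts = np.bincount(assign, minlength=nz)
    return assign + 1


def apply_segregation(fs: FociSet, n_keep_chains: int, seed: int) -> FociSet:
    """Mitotic segregation: keep the foci of a random subset of chains.

    After many division cycles only a few labeled chromosome territories
    remain per cell (~3 in the experiments this emulates).
    """
    chains = np.unique(fs.chain_ids)
    if n_keep_chains > chains.size:
        raise ValueError(f"cannot keep {n_keep_chains} of {chains.size} chains")
    if n_keep_chains == chains.size:
        return fs.subset(np.ones(len(fs), dtype=bool))
    rng = np.random.default_rng(seed)
    keep = rng.choice(chains, size=n_keep_chains, replace=False)
    return fs.subset(np.isin(fs.chain_ids, keep))


def _clamp_to_nucleus(centers: np.ndarray, radius: float) -> np.ndarray:
    r = np.linalg.norm(centers, axis=1)
    out = r > radius
    if out.any():
        centers = centers.copy()
        centers[out] *= (radius / r[out])[:, None]
    return centers


def apply_plasticity(
    fs: FociSet,
    step_sd_nm: float,
    seed: int,
    local_jitter_nm: float = 0.0,
) -> FociSet:
    """Structural plasticity of chromosome territories.

    Genetic-model sets move each chain rigidly (random rotation about the
    chain centroid plus an isotropic Gaussian translation of sd
    ``step_sd_nm`` per axis), modelling the 0.2-0.6 um territory shifts
    that leave neighbour relations intact; optional ``local_jitter_nm``
    adds per-focus noise, repaired so chain-adjacent separations stay
    within 1.5 x their original value.  Random/spatial sets displace every
    focus independently.  All foci are re-projected inside the nucleus.
    """
    if step_sd_nm < 0 or local_jitter_nm < 0:
        raise ValueError("perturbation scales must be non-negative")
    if step_sd_nm == 0 and local_jitter_nm == 0:
        return fs.subset(np.ones(len(fs), dtype=bool))
    rng = np.random.default_rng(seed)
    radius = fs.nucleus.placement_radius_nm
    old = fs.centers
    new = old.copy()

    if fs.model is ActivationModel.GENETIC:
        for c in np.unique(fs.chain_ids):
            m = fs.chain_ids == c
            pts = old[m]
            centroid = pts.mean(axis=0)
            quat = rng.normal(size=4)
            rot = Rotation.from_quat(quat / np.linalg.norm(quat))
            shift = rng.normal(0.0, step_sd_nm, size=3)
            new[m] = rot.apply(pts - centroid) + centroid + shift
        if local_jitter_nm > 0:
            new += rng.normal(0.0, local_jitter_nm, size=new.shape)
        new = _clamp_to_nucleus(new, radius)
        if local_jitter_nm > 0:
            new = _repair_chain_separations(fs, old, new, cap=1.5 * 0.999)
    else:
        new = old + rng.normal(0.0, step_sd_nm, size=old.shape)
        new = _clamp_to_nucleus(new, radius)

    out = fs.subset(np.ones(len(fs), dtype=bool))
    out.centers = new
    return out


def _repair_chain_separations(
    fs: FociSet, old: np.ndarray, new: np.ndarray, cap: float
) -> np.ndarray:
    """Pull chain-adjacent foci back within ``cap`` x original separation.

    Processed in chain order; each focus is moved along the segment towards
    its (already repaired) predecessor, which stays inside the nucleus by
    convexity.
    """
    new = new.copy()
    for c in np.unique(fs.chain_ids):
        idx = np.flatnonzero(fs.chain_ids == c)
        idx = idx[np.argsort(fs.chain_pos[idx])]
        for a, b in zip(idx, idx[1:]):
            orig = np.linalg.norm(old[b] - old[a])
            v = new[b] - new[a]
            d = np.linalg.norm(v)
            if orig > 0 and d > cap * orig:
                new[b] = new[a] + v * (cap * orig / d)
    return new


# ---------------------------------------------------------------------------
# timing profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingProfileSpec:
    """Planted-domain specification for a synthetic timing profile.

    Each domain becomes one unimodal triangular peak: the profile rises
    linearly from ~0 at the domain edge to the apex height at its centre.
    Domain boundaries are therefore valleys, recorded as ground truth.
    """

    domain_lengths_kbp: tuple[float, ...]
    peak_heights: tuple[float, ...]
    bin_size_bp: int = 10_000
    noise_sd: float = 0.0
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if len(self.domain_lengths_kbp) != len(self.peak_heights):
            raise ValueError("need one peak height per domain")
        if any(l <= 0 for l in self.domain_lengths_kbp):
            raise ValueError("domain lengths must be positive")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_timing_profile(spec: TimingProfileSpec) -> TimingProfile:
    """Emit the binned profile for a planted-domain specification."""
    rng = np.random.default_rng(spec.seed)
    chunks: list[np.ndarray] = []
    boundaries: list[int] = []
    apexes: list[int] = []
    pos_bins = 0
    for length, height in zip(spec.domain_lengths_kbp, spec.peak_heights):
        nb = max(1, int(round(length * 1000 / spec.bin_size_bp)))
        centers = np.arange(nb) + 0.5
        half = nb / 2.0
        vals = height * (1.0 - np.abs(centers - half) / half)
        chunks.append(vals)
        apexes.append(int((pos_bins + np.argmax(vals)) * spec.bin_size_bp + spec.bin_size_bp // 2))
        pos_bins += nb
        boundaries.append(pos_bins * spec.bin_size_bp)
    if not chunks:
        return TimingProfile.uniform(
            spec.chrom, np.zeros(0), spec.bin_size_bp,
            truth_boundaries_bp=np.zeros(0, dtype=np.int64),
            truth_apexes_bp=np.zeros(0, dtype=np.int64),
        )
    values = np.concatenate(chunks)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.size)
    return TimingProfile.uniform(
        spec.chrom,
        values,
        spec.bin_size_bp,
        truth_boundaries_bp=np.asarray(boundaries[:-1], dtype=np.int64),
        truth_apexes_bp=np.asarray(apexes, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# DNA fibres
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalSpec:
    """A clipped normal distribution specification (lengths in kbp)."""

    mean: float
    sd: float

    def sample(
        self,
        rng: np.random.Generator,
        n: int,
        lo: float | None = None,
        hi: float | None = None,
    ) -> np.ndarray:
        draws = rng.normal(self.mean, self.sd, size=n)
        return np.clip(draws, lo, hi)


@dataclass(frozen=True)
class FiberConfig:
    """Study conditions of the fibre-labelling simulation.

    Defaults follow the pulse-chase-pulse protocol (30 min first pulse, 1 h
    chase, 20 min second pulse), fork rates uniform in 1-2 kbp/min, primary
    inter-origin spacings of 181.2 +/- 87.5 kbp for extending clusters and
    119.6 +/- 47.0 kbp for clusters with secondary activation, a class mix
    of 55% extending / 40% secondary / 5% uncoupled, the 250 kbp uncoupling
    distance, 2.59 kbp/um, and 5 kbp measurement noise on track ends.
    """

    pulse1_min: float = 30.0
    chase_min: float = 60.0
    pulse2_min: float = 20.0
    fork_rate_kbp_per_min: tuple[float, float] = (1.0, 2.0)
    origin_spacing_extending: NormalSpec = NormalSpec(181.2, 87.5)
    origin_spacing_secondary: NormalSpec = NormalSpec(119.6, 47.0)
    replicons_per_cluster: ClusterSizePMF = field(default_factory=ClusterSizePMF)
    class_mix: tuple[float, float, float] = (0.55, 0.40, 0.05)
    exclusion_kbp: float = 250.0
    kbp_per_um: float = KBP_PER_UM
    noise_sd_kbp: float = 5.0
    min_span_kbp: float = 850.0

    def __post_init__(self) -> None:
        if min(self.pulse1_min, self.chase_min, self.pulse2_min) < 0:
            raise ValueError("durations must be non-negative")
        lo, hi = self.fork_rate_kbp_per_min
        if lo <= 0 or hi < lo:
            raise ValueError("fork rate range must be positive and ordered")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise ValueError("class_mix must be a probability vector")
        if self.kbp_per_um <= 0:
            raise ValueError("kbp_per_um must be positive")
        if self.noise_sd_kbp < 0:
            raise ValueError("noise_sd_kbp must be non-negative")

    @property
    def uncoupled_fraction(self) -> float:
        return self.class_mix[2]


_CLASSES = ("extending", "secondary_activation", "uncoupled")


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1e-9:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out if e - s > 1e-9]


def _simulate_fiber(cfg: FiberConfig, rng: np.random.Generator, fid: str) -> Fiber:
    t1, tc, t2 = cfg.pulse1_min, cfg.chase_min, cfg.pulse2_min
    t_p2 = t1 + tc
    T = t1 + tc + t2
    v = rng.uniform(*cfg.fork_rate_kbp_per_min)
    cls = _CLASSES[rng.choice(3, p=cfg.class_mix)]
    spacing = (
        cfg.origin_spacing_secondary
        if cls == "secondary_activation"
        else cfg.origin_spacing_extending
    )

    k = int(cfg.replicons_per_cluster.sample(1, rng)[0])
    # keep the primary cluster a single cluster at the analysis gap threshold
    gap_hi = cfg.exclusion_kbp + 2 * v * t1 - 5.0
    gaps = spacing.sample(rng, k - 1, lo=30.0, hi=max(35.0, gap_hi))
    origins = np.concatenate([[0.0], np.cumsum(gaps)])
    truth_origins = list(origins)

    ch1: list[tuple[float, float]] = []
    ch2: list[tuple[float, float]] = []

    def fork(x: float, sign: int, stop: float) -> None:
        """Label the DNA a fork synthesises before ``stop`` minutes."""
        e1 = min(t1, stop)
        if e1 > 0:
            iv = sorted((x, x + sign * v * e1))
            ch1.append(tuple(iv))
        if stop > t_p2 and t2 > 0:
            e2 = min(T, stop)
            iv = sorted((x + sign * v * t_p2, x + sign * v * e2))
            ch2.append(tuple(iv))

    for i, x in enumerate(origins):
        lstop = np.inf if i == 0 else (x - origins[i - 1]) / (2 * v)
        rstop = np.inf if i == k - 1 else (origins[i + 1] - x) / (2 * v)
        fork(x, -1, lstop)
        fork(x, +1, rstop)

    if cls == "secondary_activation" and t2 > 0:
        both = rng.random() < 0.5
        sides = [-1, +1] if both else [int(rng.choice([-1, 1]))]
        for sign in sides:
            o_out = origins[0] if sign < 0 else origins[-1]
            k2 = max(2, int(cfg.replicons_per_cluster.sample(1, rng)[0]))
            # first neighbour origin beyond the outgoing fork front, close
            # enough to stay genetically coupled to the primary cluster
            g_lo = v * (t1 + tc + 2 * t2) + 5.0
            g_hi = cfg.exclusion_kbp + v * (t1 + t2) - 5.0
            g = float(spacing.sample(rng, 1, lo=g_lo, hi=max(g_hi, g_lo + 1.0))[0])
            s = o_out + sign * g
            for j in range(k2):
                if j > 0:
                    d_lo = 2 * v * t2 + 5.0
                    d_hi = cfg.exclusion_kbp + 2 * v * t2 - 5.0
                    d = float(spacing.sample(rng, 1, lo=d_lo, hi=max(d_hi, d_lo + 1.0))[0])
                    s = s + sign * d
                ch2.append((s - v * t2, s + v * t2))
                truth_origins.append(s)
    elif cls == "uncoupled" and t2 > 0:
        sign = int(rng.choice([-1, 1]))
        o_out = origins[0] if sign < 0 else origins[-1]
        offset = v * T + v * t2 + cfg.exclusion_kbp + 10.0 + rng.uniform(0.0, 100.0)
        s = o_out + sign * offset
        ch2.append((s - v * t2, s + v * t2))
        truth_origins.append(s)

    ch1 = _merge_intervals(ch1)
    ch2 = _merge_intervals(ch2)

    if not ch1 and not ch2:  # degenerate zero-duration protocol
        return Fiber(
            fiber_id=fid,
            tracks=[],
            unit="um",
            length=cfg.min_span_kbp / cfg.kbp_per_um,
            truth_class=cls,
            truth_origins_kbp=np.asarray(truth_origins),
        )

    lo = min(s for s, _ in ch1 + ch2)
    hi = max(e for _, e in ch1 + ch2)
    buf_l = rng.uniform(60.0, 150.0)
    buf_r = rng.uniform(60.0, 150.0)
    span = hi - lo + buf_l + buf_r
    if span < cfg.min_span_kbp:
        extra = (cfg.min_span_kbp - span) / 2
        buf_l += extra
        buf_r += extra
        span = cfg.min_span_kbp
    shift = lo - buf_l

    def emit(ivs: list[tuple[float, float]], channel: int) -> list[FiberTrack]:
        tracks = []
        for s, e in ivs:
            s, e = s - shift, e - shift
            if cfg.noise_sd_kbp > 0:
                s += rng.normal(0.0, cfg.noise_sd_kbp)
                e += rng.normal(0.0, cfg.noise_sd_kbp)
                if e - s < 0.5:
                    e = s + 0.5
                s = max(s, 0.0)
            tracks.append((s, e, channel))
        merged = _merge_intervals([(s, e) for s, e, _ in tracks])
        return [
            FiberTrack(fid, channel, s / cfg.kbp_per_um, e / cfg.kbp_per_um)
            for s, e in merged
        ]

    tracks = emit(ch1, 1) + emit(ch2, 2)
    return Fiber(
        fiber_id=fid,
        tracks=tracks,
        unit="um",
        length=span / cfg.kbp_per_um,
        truth_class=cls,
        truth_origins_kbp=np.asarray(truth_origins) - shift,
    )


def gen_fibers(cfg: FiberConfig, n_fibers: int, seed: int) -> list[Fiber]:
    """Simulate labeled DNA fibres, one replicon cluster per fibre.

    Origins of the primary cluster fire at the start of the first pulse and
    bidirectional forks elongate at the fibre's rate until converging forks
    fuse; DNA synthesised during each pulse becomes a track in the matching
    channel.  Depending on the drawn ground-truth class, neighbouring
    origins fire during the second pulse (secondary activation), only the
    outgrowing forks continue (extending), or an isolated second-pulse-only
    origin is planted beyond the exclusion distance (uncoupled).
    Coordinates are emitted in micrometres with additive end-point noise.
    """
    if n_fibers < 0:
        raise ValueError("n_fibers must be non-negative")
    rng = np.random.default_rng(seed)
    return [_simulate_fiber(cfg, rng, f"fiber{i:05d}") for i in range(n_fibers)]
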