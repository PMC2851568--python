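"""Classification of pulse-chase-pulse labeled DNA-fiber tracks.

Spread DNA fibres carry tracks of two labels: channel 1 (first pulse, e.g.
biotin-dUTP) and channel 2 (second pulse, e.g. BrdU) separated by an
unlabeled chase.  Around each primary (channel-1) replicon cluster the
channel-2 labelling distinguishes three outcomes:

extending
    only the outgrowing forks of the primary cluster incorporate the second
    label: at most one channel-2 track per flank, offset from the cluster
    edge by roughly fork-rate x chase time.
secondary_activation
    additional origins fire in the genetically adjacent DNA during the
    second pulse, leaving multiple channel-2 tracks in a flank.
uncoupled
    a channel-2-only track farther than the exclusion distance (250 kbp)
    from any channel-1 track: a de-novo initiation genetically uncoupled
    from previously active clusters.

Track lengths in micrometres convert to kbp at 2.59 kbp/um.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberTrack",
    "Fiber",
    "FiberClass",
    "FiberReport",
    "AnalysisParams",
    "ForkRateEstimate",
    "um_to_kbp",
    "kbp_to_um",
    "segment_primary_cluster",
    "classify_fiber",
    "inter_origin_distances",
    "estimate_fork_rate",
    "cohort_report",
]

KBP_PER_UM = 2.59


class FiberClass(str, enum.Enum):
    EXTENDING = "extending"
    SECONDARY = "secondary_activation"
    UNCOUPLED = "uncoupled"


@dataclass
class FiberTrack:
    """One labeled track on a fibre; unit is carried by the parent Fiber."""

    fiber_id: str
    channel: int
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.channel not in (1, 2):
            raise ValueError("channel must be 1 or 2")
        if not self.start < self.end:
            raise ValueError("track must have start < end")

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Fiber:
    """A single spread DNA fibre with its labeled tracks sorted by start.

    ``length`` is the total DNA carried by the fibre (same unit as the
    tracks); when absent the labeled span is used for length filtering.
    ``truth_class`` and ``truth_origins_kbp`` hold generator ground truth.
    """

    fiber_id: str
    tracks: list[FiberTrack]
    unit: str = "um"
    length: float | None = None
    truth_class: str | None = None
    truth_origins_kbp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("um", "kbp"):
            raise ValueError("unit must be 'um' or 'kbp'")
        self.tracks = sorted(self.tracks, key=lambda t: (t.start, t.channel))
        for ch in (1, 2):
            chts = [t for t in self.tracks if t.channel == ch]
            for a, b in zip(chts, chts[1:]):
                if b.start < a.end - 1e-9:
                    raise ValueError(
                        f"fiber {self.fiber_id}: overlapping channel-{ch} tracks"
                    )

    def channel_tracks(self, channel: int) -> list[FiberTrack]:
        return [t for t in self.tracks if t.channel == channel]

    def span(self) -> float:
        if not self.tracks:
            return 0.0
        return max(t.end for t in self.tracks) - min(t.start for t in self.tracks)


@dataclass(frozen=True)
class AnalysisParams:
    """Classification parameters; length scales in kbp.

    ``cluster_gap_kbp`` links successive channel-1 tracks into one primary
    cluster; ``exclusion_kbp`` is the uncoupling distance (a channel-2 track
    beyond it from every channel-1 track counts as uncoupled).  The chase
    window ``[rate_min*chase - tol, rate_max*chase + tol]`` is the plausible
    gap between a cluster edge and the track of its own outgrowing fork.
    """

    kbp_per_um: float = KBP_PER_UM
    cluster_gap_kbp: float = 250.0
    exclusion_kbp: float = 250.0
    min_fiber_mbp: float = 0.8
    pulse1_min: float = 30.0
    pulse2_min: float = 20.0
    chase_min: float = 60.0
    fork_rate_range: tuple[float, float] = (1.0, 2.0)
    chase_tol_kbp: float = 15.0
    plausible_rate: tuple[float, float] = (0.5, 3.0)

    @property
    def chase_gap_window(self) -> tuple[float, float]:
        lo = self.fork_rate_range[0] * self.chase_min - self.chase_tol_kbp
        hi = self.fork_rate_range[1] * self.chase_min + self.chase_tol_kbp
        return (max(lo, 0.0), hi)


def um_to_kbp(length_um: float, factor: float = KBP_PER_UM) -> float:
    """Convert a fibre length from micrometres to kbp (1 um = 2.59 kbp)."""
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    return length_um * factor


def kbp_to_um(length_kbp: float, factor: float = KBP_PER_UM) -> float:
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    return length_kbp / factor


def _intervals_kbp(fiber: Fiber, channel: int, factor: float) -> np.ndarray:
    scale = factor if fiber.unit == "um" else 1.0
    ivs = [(t.start * scale, t.end * scale) for t in fiber.channel_tracks(channel)]
    return np.array(ivs, dtype=float).reshape(-1, 2)


def _interval_gap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Distance between two intervals (0 if they touch or overlap)."""
    return max(a[0] - b[1], b[0] - a[1], 0.0)


@dataclass
class ClusterSegmentation:
    """Primary channel-1 cluster and its flanking windows, in kbp."""

    cluster: tuple[float, float]
    cluster_tracks: np.ndarray  # (k, 2) channel-1 intervals of the cluster
    left_flank: tuple[float, float]
    right_flank: tuple[float, float]


def segment_primary_cluster(
    fiber: Fiber, params: AnalysisParams | None = None
) -> ClusterSegmentation:
    """Identify the primary replicon cluster among channel-1 tracks.

    Successive channel-1 tracks with gaps <= ``cluster_gap_kbp`` form runs;
    the run with the largest DNA span is the primary cluster.  The flanks
    extend ``exclusion_kbp`` beyond each cluster edge.
    """
    params = params or AnalysisParams()
    ch1 = _intervals_kbp(fiber, 1, params.kbp_per_um)
    if ch1.shape[0] == 0:
        raise ValueError("fiber has no channel-1 track; route to uncoupled-only assessment")
    runs: list[list[int]] = [[0]]
    for i in range(1, ch1.shape[0]):
        if ch1[i, 0] - ch1[runs[-1][-1], 1] <= params.cluster_gap_kbp:
            runs[-1].append(i)
        else:
            runs.append([i])
    spans = [ch1[r[-1], 1] - ch1[r[0], 0] for r in runs]
    best = runs[int(np.argmax(spans))]
    lo, hi = float(ch1[best[0], 0]), float(ch1[best[-1], 1])
    return ClusterSegmentation(
        cluster=(lo, hi),
        cluster_tracks=ch1[best[0] : best[-1] + 1],
        left_flank=(lo - params.exclusion_kbp, lo),
        right_flank=(hi, hi + params.exclusion_kbp),
    )


def classify_fiber(fiber: Fiber, params: AnalysisParams | None = None) -> FiberClass:
    """Assign a fibre to one of the three replication classes.

    Channel-2 tracks are called *coupled* when within ``exclusion_kbp`` of a
    channel-1 track and *uncoupled* otherwise.  A flank with >= 2 coupled
    channel-2 tracks indicates secondary activation; otherwise any uncoupled
    track marks the fibre uncoupled; otherwise a single coupled flank track
    sitting at the chase distance of the outgrowing fork marks extension
    (a single flank track off that window is also scored as secondary,
    since it cannot be the primary cluster's own fork).
    """
    params = params or AnalysisParams()
    if not fiber.tracks:
        raise ValueError("fiber has no tracks")
    ch1 = _intervals_kbp(fiber, 1, params.kbp_per_um)
    ch2 = _intervals_kbp(fiber, 2, params.kbp_per_um)
    if ch1.shape[0] == 0:
        return FiberClass.UNCOUPLED

    seg = segment_primary_cluster(fiber, params)
    lo, hi = seg.cluster

    def gap_to_ch1(iv) -> float:
        return min(_interval_gap(tuple(iv), tuple(c)) for c in ch1)

    coupled_left, coupled_right, uncoupled = [], [], []
    for iv in ch2:
        if gap_to_ch1(iv) > params.exclusion_kbp:
            uncoupled.append(iv)
        elif iv[1] <= lo:
            coupled_left.append(iv)
        elif iv[0] >= hi:
            coupled_right.append(iv)
        # tracks inside the cluster interval are internal fork labelling

    if len(coupled_left) >= 2 or len(coupled_right) >= 2:
        return FiberClass.SECONDARY
    if uncoupled:
        return FiberClass.UNCOUPLED

    win_lo, win_hi = params.chase_gap_window
    for side, edge in ((coupled_left, lo), (coupled_right, hi)):
        if len(side) == 1:
            gap = max(edge - side[0][1], side[0][0] - edge, 0.0)
            if not (win_lo <= gap <= win_hi):
                return FiberClass.SECONDARY
    return FiberClass.EXTENDING


def inter_origin_distances(
    fiber: Fiber, params: AnalysisParams | None = None
) -> np.ndarray:
    """Successive midpoint separations of the primary cluster's channel-1
    tracks (kbp).  The track midpoint proxies the origin, which is exact for
    symmetric bidirectional forks.  Fewer than 2 tracks -> empty array.
    """
    params = params or AnalysisParams()
    try:
        seg = segment_primary_cluster(fiber, params)
    except ValueError:
        return np.array([])
    mids = seg.cluster_tracks.mean(axis=1)
    return np.diff(mids) if mids.size >= 2 else np.array([])


@dataclass(frozen=True)
class ForkRateEstimate:
    rate_kbp_per_min: float
    implausible: bool


def estimate_fork_rate(
    track_length_kbp: float,
    pulse_min: float,
    bidirectional: bool = True,
    plausible: tuple[float, float] = (0.5, 3.0),
) -> ForkRateEstimate:
    """Per-fork synthesis rate from a track length and the pulse duration.

    A bidirectional track spans both forks of one origin, so the rate is
    halved.  Rates outside the plausible window (default 0.5-3 kbp/min) are
    flagged rather than rejected.
    """
    if pulse_min <= 0:
        raise ValueError("pulse_min must be positive")
    rate = track_length_kbp / pulse_min
    if bidirectional:
        rate /= 2.0
    return ForkRateEstimate(rate, not plausible[0] <= rate <= plausible[1])


def _track_groups(fiber: Fiber, params: AnalysisParams):
    """Maximal runs of tracks (both channels) linked by gaps <= exclusion."""
    scale = params.kbp_per_um if fiber.unit == "um" else 1.0
    tracks = sorted(fiber.tracks, key=lambda t: t.start)
    groups: list[list[FiberTrack]] = []
    end = None
    for t in tracks:
        if end is None or t.start * scale - end > params.exclusion_kbp:
            groups.append([t])
        else:
            groups[-1].append(t)
        end = max(end if end is not None else -np.inf, t.end * scale)
    return groups


@dataclass
class FiberReport:
    """Cohort summary: class counts, spacings, rates and uncoupling."""

    n_fibers: int
    n_excluded_short: int
    class_counts: dict[str, int]
    class_proportions: dict[str, float]
    inter_origin_kbp: dict[str, dict[str, float]]
    fork_rate: dict[str, float]
    uncoupled_group_fraction: float
    uncoupled_track_fraction: float

    def to_dict(self) -> dict:
        return {
            "n_fibers": self.n_fibers,
            "n_excluded_short": self.n_excluded_short,
            "class_counts": self.class_counts,
            "class_proportions": self.class_proportions,
            "inter_origin_kbp": self.inter_origin_kbp,
            "fork_rate": self.fork_rate,
            "uncoupled_group_fraction": self.uncoupled_group_fraction,
            "uncoupled_track_fraction": self.uncoupled_track_fraction,
        }


def cohort_report(
    fibers: list[Fiber], params: AnalysisParams | None = None
) -> FiberReport:
    """Classify a cohort of fibres and summarise it.

    Fibres without tracks contribute nothing; fibres shorter than
    ``min_fiber_mbp`` (fiber length if known, labeled span otherwise) are
    excluded, mirroring the >=0.8 Mbp imaging-field requirement.  The
    uncoupled fraction is reported both per track group (unique-channel-2
    groups / all groups) and per track (channel-2 tracks in unique groups /
    all labeled tracks).
    """
    params = params or AnalysisParams()
    if not fibers:
        raise ValueError("need at least one fiber")
    min_len_kbp = params.min_fiber_mbp * 1000.0

    counts = {c.value: 0 for c in FiberClass}
    spacings: dict[str, list[float]] = {c.value: [] for c in FiberClass}
    rates: list[float] = []
    n_groups = n_unique_groups = n_tracks = n_unique_ch2_tracks = 0
    n_short = 0
    n_used = 0

    for f in fibers:
        if not f.tracks:
            continue
        scale = params.kbp_per_um if f.unit == "um" else 1.0
        flen = (f.length if f.length is not None else f.span()) * scale
        if flen < min_len_kbp:
            n_short += 1
            continue
        n_used += 1
        cls = classify_fiber(f, params)
        counts[cls.value] += 1
        spacings[cls.value].extend(inter_origin_distances(f, params))
        for t in f.channel_tracks(1):
            rates.append(
                estimate_fork_rate(
                    t.length * scale, params.pulse1_min, bidirectional=True,
                    plausible=params.plausible_rate,
                ).rate_kbp_per_min
            )
        groups = _track_groups(f, params)
        n_groups += len(groups)
        n_tracks += len(f.tracks)
        for g in groups:
            if all(t.channel == 2 for t in g):
                n_unique_groups += 1
                n_unique_ch2_tracks += len(g)

    if n_used == 0:
        raise ValueError("no fiber passed the length filter")

    props = {k: v / n_used for k, v in counts.items()}
    spacing_summary = {}
    for k, vals in spacings.items():
        arr = np.asarray(vals)
        spacing_summary[k] = {
            "mean": float(arr.mean()) if arr.size else None,
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size),
        }
    rate_arr = np.asarray(rates)
    lo, hi = params.plausible_rate
    fork_rate = {
        "mean": float(rate_arr.mean()) if rate_arr.size else None,
        "sd": float(rate_arr.std(ddof=1)) if rate_arr.size > 1 else 0.0,
        "n": int(rate_arr.size),
        "implausible_fraction": float(((rate_arr < lo) | (rate_arr > hi)).mean())
        if rate_arr.size
        else None,
    }
    return FiberReport(
        n_fibers=n_used,
        n_excluded_short=n_short,
        class_counts=counts,
        class_proportions=props,
        inter_origin_kbp=spacing_summary,
        fork_rate=fork_rate,
        uncoupled_group_fraction=n_unique_groups / n_groups if n_groups else float("nan"),
        uncoupled_track_fraction=n_unique_ch2_tracks / n_tracks if n_tracks else float("nan"),
    )
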