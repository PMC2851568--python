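"""Segmentation of replication-timing profiles into timing domains.

A timing profile is a binned genomic signal in which higher values mark
earlier-replicating DNA.  Peaks in the profile correspond to replication
timing domains; the valley (local minimum) between two prominence-filtered
peaks is taken as the domain boundary, which is the closest automatable
reading of calling domains at points of inflection.  Coordinates are
0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .replicon_clusters import DistributionProfile, build_profile

__all__ = [
    "TimingProfile",
    "TimingDomain",
    "SegmentationParams",
    "smooth_profile",
    "call_domains",
    "domain_length_profile",
]


@dataclass
class TimingProfile:
    """Binned timing signal: sorted, non-overlapping genomic bins.

    ``truth_boundaries_bp`` / ``truth_apexes_bp`` carry planted ground truth
    when the profile comes from the synthetic generator; they are ignored by
    the domain caller.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    truth_boundaries_bp: np.ndarray | None = None
    truth_apexes_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.starts.size == self.ends.size == self.values.size):
            raise ValueError("starts, ends and values must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("bins must have positive width")
        if self.starts.size > 1:
            if np.any(np.diff(self.starts) <= 0):
                raise ValueError("bins must be sorted by start")
            if np.any(self.starts[1:] < self.ends[:-1]):
                raise ValueError("bins must not overlap")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def span_bp(self) -> int:
        return 0 if len(self) == 0 else int(self.ends[-1] - self.starts[0])

    @classmethod
    def uniform(cls, chrom, values, bin_size_bp, start_bp=0, **kw) -> "TimingProfile":
        values = np.asarray(values, dtype=float)
        starts = start_bp + bin_size_bp * np.arange(values.size, dtype=np.int64)
        return cls(chrom=chrom, starts=starts, ends=starts + bin_size_bp, values=values, **kw)


@dataclass
class TimingDomain:
    """One peak-delimited timing domain, 0-based half-open in bp."""

    chrom: str
    start_bp: int
    end_bp: int
    apex_bp: int
    apex_value: float

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError("domain must have positive length")
        if not (self.start_bp <= self.apex_bp < self.end_bp):
            raise ValueError("apex must lie inside the domain")

    @property
    def length_kbp(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the domain caller.

    smoothing_window : odd number of bins for the moving average (1 = off).
    min_prominence : peak prominence threshold in signal units; None uses
        0.1 x the interquartile range of the smoothed profile.
    min_domain_length_kbp : domains shorter than this are merged into the
        neighbouring domain with the higher apex.
    """

    smoothing_window: int = 3
    min_prominence: float | None = None
    min_domain_length_kbp: float = 0.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.min_prominence is not None and self.min_prominence < 0:
            raise ValueError("min_prominence must be >= 0")


def smooth_profile(p: TimingProfile, window: int) -> TimingProfile:
    """Centred moving average with edge truncation; window=1 is the identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1 or len(p) == 0:
        smoothed = p.values.copy()
    else:
        kernel = np.ones(window)
        norm = np.convolve(np.ones_like(p.values), kernel, mode="same")
        smoothed = np.convolve(p.values, kernel, mode="same") / norm
    return TimingProfile(chrom=p.chrom, starts=p.starts, ends=p.ends, values=smoothed)


def _boundary_between(values: np.ndarray, left_apex: int, right_apex: int) -> int:
    """Bin index of the valley between two apexes; ties go to the midpoint."""
    seg = values[left_apex + 1 : right_apex]
    lo = seg.min()
    cands = np.flatnonzero(seg <= lo + 1e-12) + left_apex + 1
    mid = (left_apex + right_apex) / 2
    return int(cands[np.argmin(np.abs(cands - mid))])


def call_domains(p: TimingProfile, params: SegmentationParams | None = None) -> list[TimingDomain]:
    """Call timing domains from a binned profile.

    Local maxima with prominence >= the threshold become domain apexes.
    Each domain runs from the preceding to the following valley; the first
    and last domains extend to the profile ends.  Adjacent domains share
    boundaries exactly, so the called domains tile the profile.

    Peaks are detected on the smoothed profile but valleys are refined on
    the original values: a moving average drags the apparent minimum into
    the shallower of two flanking peaks, while the native-resolution
    valley stays within one bin of the true inflection.
    """
    params = params or SegmentationParams()
    if len(p) == 0:
        return []
    sm = smooth_profile(p, params.smoothing_window)
    v = sm.values
    if params.min_prominence is None:
        q1, q3 = np.percentile(v, [25, 75])
        prom = 0.1 * (q3 - q1)
    else:
        prom = params.min_prominence
    # plateau_size picks up flat-topped (even-width triangular) apexes
    peaks, _ = find_peaks(v, prominence=max(prom, 1e-12), plateau_size=1)
    if peaks.size == 0:
        return []

    cuts = [0]
    for i in range(peaks.size - 1):
        cuts.append(_boundary_between(p.values, int(peaks[i]), int(peaks[i + 1])))
    cuts.append(len(p))

    # bin index -> bp (cut k is the start of the k-th bin; len(p) -> profile end)
    def _bp(idx: int) -> int:
        return int(p.ends[-1]) if idx >= len(p) else int(p.starts[idx])

    domains = []
    for i, pk in enumerate(peaks):
        apex_bp = int((p.starts[pk] + p.ends[pk]) // 2)
        domains.append(
            TimingDomain(
                chrom=p.chrom,
                start_bp=_bp(cuts[i]),
                end_bp=_bp(cuts[i + 1]),
                apex_bp=apex_bp,
                apex_value=float(v[pk]),
            )
        )

    # merge undersized domains into the taller-apex neighbour
    min_len = params.min_domain_length_kbp
    while len(domains) > 1:
        lengths = [d.length_kbp for d in domains]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_len:
            break
        left = domains[i - 1] if i > 0 else None
        right = domains[i + 1] if i < len(domains) - 1 else None
        if right is None or (left is not None and left.apex_value >= right.apex_value):
            keep, j = left, i - 1
        else:
            keep, j = right, i + 1
        merged = TimingDomain(
            chrom=keep.chrom,
            start_bp=min(keep.start_bp, domains[i].start_bp),
            end_bp=max(keep.end_bp, domains[i].end_bp),
            apex_bp=keep.apex_bp,
            apex_value=keep.apex_value,
        )
        domains[min(i, j)] = merged
        del domains[max(i, j)]
    return domains


def domain_length_profile(
    domains: list[TimingDomain], bin_width_kbp: float = 50.0
) -> DistributionProfile:
    """Distribution profile of domain lengths (delegates to build_profile)."""
    if not domains:
        raise ValueError("need at least one domain")
    return build_profile([d.length_kbp for d in domains], bin_width_kbp)
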