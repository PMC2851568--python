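"""File formats, run configuration and the pipeline dispatcher.

Native tabular dialect is TSV with a header line plus ``#key=value``
metadata comments.  Genomic intervals follow UCSC conventions exactly:
bedGraph (4 columns) and BED6, 0-based half-open.  Summaries and run logs
are JSON.  Identical config + seed produce byte-identical data outputs;
the run log additionally records a wall-clock timestamp.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fiber_analysis, foci_spatial, replicon_clusters, synthetic_data, timing_domains
from .fiber_analysis import AnalysisParams, Fiber, FiberTrack, cohort_report
from .replicon_clusters import ClusterSizePMF, RepliconLengthModel, build_profile, sample_clusters
from .synthetic_data import (
    ActivationModel,
    FiberConfig,
    FociSet,
    NormalSpec,
    NucleusConfig,
    TimingProfileSpec,
    apply_plasticity,
    apply_segregation,
    gen_fibers,
    gen_nuclear_foci,
    gen_timing_profile,
)
from .timing_domains import SegmentationParams, TimingDomain, TimingProfile, call_domains

__all__ = [
    "ParseError",
    "RunConfig",
    "RunLog",
    "read_foci_tsv",
    "write_foci_tsv",
    "read_fibers_tsv",
    "write_fibers_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "write_domains_bed",
    "run_pipeline",
    "SUBCOMMANDS",
]

FOCI_COLUMNS = ["id", "x_nm", "y_nm", "z_nm", "diameter_nm", "zone", "chain_id", "chain_pos"]
FIBER_COLUMNS = [
    "fiber_id", "channel", "start_um", "end_um",
    "fiber_length_um", "truth_class", "truth_origin_kbp",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _read_meta_and_table(path, required_cols) -> tuple[dict, pd.DataFrame, int]:
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = 0
    with path.open() as fh:
        lines = fh.readlines()
    for header_line, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            break
    else:
        raise ParseError(f"{path}: no header line found")
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("".join(lines[header_line:])), sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: line {header_line + 1}: missing columns {missing}")
    return meta, df, header_line


def write_foci_tsv(fs: FociSet, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#nucleus_diameter_um={fs.nucleus.nucleus_diameter_um}\n")
        fh.write(f"#focus_diameter_nm={fs.nucleus.focus_diameter_nm}\n")
        fh.write(f"#foci_per_zone={fs.nucleus.foci_per_zone}\n")
        fh.write(f"#n_zones={fs.nucleus.n_zones}\n")
        fh.write(f"#zone_duration_h={fs.nucleus.zone_duration_h}\n")
        fh.write(f"#model={fs.model.value}\n")
        fh.write(f"#seed={fs.seed}\n")
        fh.write("\t".join(FOCI_COLUMNS) + "\n")
        for i in range(len(fs)):
            fh.write(
                f"{fs.ids[i]}\t{fs.centers[i,0]:.6f}\t{fs.centers[i,1]:.6f}\t"
                f"{fs.centers[i,2]:.6f}\t{fs.diameters[i]:.6f}\t{fs.zones[i]}\t"
                f"{fs.chain_ids[i]}\t{fs.chain_pos[i]}\n"
            )


def read_foci_tsv(path) -> FociSet:
    """Read a foci TSV, validating geometry; errors name the line."""
    meta, df, header_line = _read_meta_and_table(path, FOCI_COLUMNS)
    if "nucleus_diameter_um" not in meta:
        raise ParseError(f"{path}: missing #nucleus_diameter_um metadata")
    cfg = NucleusConfig(
        nucleus_diameter_um=float(meta["nucleus_diameter_um"]),
        focus_diameter_nm=float(meta.get("focus_diameter_nm", 500.0)),
        foci_per_zone=int(meta.get("foci_per_zone", 0)),
        n_zones=int(meta.get("n_zones", 0)),
        zone_duration_h=float(meta.get("zone_duration_h", 1.0)),
    )
    numeric = df[FOCI_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise ParseError(f"{path}: line {header_line + 2 + row}: malformed row")
    centers = numeric[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
    diam = numeric["diameter_nm"].to_numpy(float)
    outside = np.linalg.norm(centers, axis=1) + diam / 2 > cfg.radius_nm + 1e-6
    if outside.any():
        row = int(np.flatnonzero(outside)[0])
        raise ParseError(
            f"{path}: line {header_line + 2 + row}: focus extends outside the nucleus"
        )
    fs = FociSet(
        nucleus=cfg,
        model=ActivationModel(meta.get("model", "random")),
        seed=int(meta.get("seed", 0)),
        ids=numeric["id"].to_numpy(np.int64),
        centers=centers,
        diameters=diam,
        zones=numeric["zone"].to_numpy(np.int64),
        chain_ids=numeric["chain_id"].to_numpy(np.int64),
        chain_pos=numeric["chain_pos"].to_numpy(np.int64),
    )
    fs.validate()
    return fs


def write_fibers_tsv(fibers: list[Fiber], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#unit=um\n")
        fh.write("\t".join(FIBER_COLUMNS) + "\n")
        for f in fibers:
            cls = f.truth_class or ""
            flen = f"{f.length:.6f}" if f.length is not None else ""
            origins = (
                ";".join(f"{x:.4f}" for x in f.truth_origins_kbp)
                if f.truth_origins_kbp is not None
                else ""
            )
            for t in f.tracks:
                fh.write(
                    f"{f.fiber_id}\t{t.channel}\t{t.start:.6f}\t{t.end:.6f}\t"
                    f"{flen}\t{cls}\t{origins}\n"
                )


def read_fibers_tsv(path) -> list[Fiber]:
    meta, df, header_line = _read_meta_and_table(path, FIBER_COLUMNS[:4])
    fibers = []
    for fid, grp in df.groupby("fiber_id", sort=False):
        tracks = [
            FiberTrack(str(fid), int(r.channel), float(r.start_um), float(r.end_um))
            for r in grp.itertuples()
        ]
        cls = None
        origins = None
        length = None
        if "fiber_length_um" in grp.columns:
            val = grp["fiber_length_um"].iloc[0]
            if pd.notna(val) and val != "":
                length = float(val)
        if "truth_class" in grp.columns:
            val = grp["truth_class"].iloc[0]
            if isinstance(val, str) and val:
                cls = val
        if "truth_origin_kbp" in grp.columns:
            val = grp["truth_origin_kbp"].iloc[0]
            if isinstance(val, str) and val:
                origins = np.array([float(x) for x in val.split(";")])
        fibers.append(
            Fiber(fiber_id=str(fid), tracks=tracks, unit=meta.get("unit", "um"),
                  length=length, truth_class=cls, truth_origins_kbp=origins)
        )
    return fibers


def write_bedgraph(p: TimingProfile, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s, e, v in zip(p.starts, p.ends, p.values):
            fh.write(f"{p.chrom}\t{s}\t{e}\t{v:.6f}\n")


def read_bedgraph(path) -> TimingProfile:
    """Parse a 4-column bedGraph into a TimingProfile (single chromosome).

    Unsorted input is sorted with a warning; overlapping intervals are an
    error.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    if df.empty:
        raise ParseError(f"{path}: empty bedGraph")
    if df["chrom"].nunique() > 1:
        raise ParseError(f"{path}: expected a single chromosome")
    if not df["start"].is_monotonic_increasing:
        warnings.warn(f"{path}: unsorted bedGraph, sorting", stacklevel=2)
        df = df.sort_values("start", kind="stable").reset_index(drop=True)
    starts = df["start"].to_numpy(np.int64)
    ends = df["end"].to_numpy(np.int64)
    if np.any(starts[1:] < ends[:-1]):
        row = int(np.flatnonzero(starts[1:] < ends[:-1])[0]) + 2
        raise ParseError(f"{path}: line {row}: overlapping intervals")
    return TimingProfile(
        chrom=str(df["chrom"].iloc[0]), starts=starts, ends=ends,
        values=df["value"].to_numpy(float),
    )


def write_domains_bed(domains: list[TimingDomain], path) -> None:
    """BED6 of timing domains: name = apex value, score = length in kbp."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for d in sorted(domains, key=lambda d: (d.chrom, d.start_bp)):
            fh.write(
                f"{d.chrom}\t{d.start_bp}\t{d.end_bp}\t{d.apex_value:.6g}\t"
                f"{d.length_kbp:.6g}\t.\n"
            )


def write_profile_tsv(profile: replicon_clusters.DistributionProfile, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#mean={profile.mean:.6f}\n#sd={profile.sd:.6f}\n")
        fh.write(f"#central90={profile.central90[0]:.6f},{profile.central90[1]:.6f}\n")
        fh.write(f"#n={profile.n}\n")
        fh.write("bin_start\tbin_end\tfrequency\n")
        for i, f in enumerate(profile.frequencies):
            fh.write(f"{profile.bin_edges[i]:.6g}\t{profile.bin_edges[i+1]:.6g}\t{f:.8f}\n")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One pipeline invocation: a subcommand, its parameters and a seed."""

    subcommand: str
    params: dict
    seed: int
    outdir: Path
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.subcommand not in SUBCOMMANDS:
            raise ValueError(
                f"unknown subcommand {self.subcommand!r}; expected one of {sorted(SUBCOMMANDS)}"
            )
        unknown = set(self.params) - set(SUBCOMMANDS[self.subcommand].accepted)
        if unknown:
            raise ValueError(f"unknown parameters for {self.subcommand}: {sorted(unknown)}")


@dataclass
class RunLog:
    timestamp: str
    subcommand: str
    params: dict
    seed: int
    versions: dict
    record_counts: dict
    outputs: list

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"sphasetools": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


def _nucleus_from_params(p: dict) -> NucleusConfig:
    return NucleusConfig(
        nucleus_diameter_um=float(p.get("nucleus_diameter_um", 10.0)),
        focus_diameter_nm=float(p.get("focus_diameter_nm", 500.0)),
        foci_per_zone=int(p.get("foci_per_zone", 350)),
        n_zones=int(p.get("n_zones", 10)),
        zone_duration_h=float(p.get("zone_duration_h", 1.0)),
    )


def _cmd_simulate_foci(p: dict, seed: int, outdir: Path):
    fs = gen_nuclear_foci(
        _nucleus_from_params(p),
        p.get("model", "genetic"),
        seed,
        n_chains=int(p.get("n_chains", 46)),
    )
    if "keep_chains" in p and p["keep_chains"] is not None:
        fs = apply_segregation(fs, int(p["keep_chains"]), seed + 1)
    sd = float(p.get("plasticity_sd_nm", 0.0))
    if sd > 0:
        fs = apply_plasticity(fs, sd, seed + 2)
    out = outdir / "foci.tsv"
    write_foci_tsv(fs, out)
    return {"foci": len(fs)}, [out]


def _cmd_nn(p: dict, seed: int, outdir: Path):
    fs = read_foci_tsv(p["foci"])
    a = fs.zone(int(p.get("a_zone", 1)))
    b = fs.zone(int(p.get("b_zone", 2)))
    thr = float(p.get("threshold_nm", 500.0))
    d = foci_spatial.nn_cross_channel(a, b)
    s = foci_spatial.summarize(d)
    summary = {
        "mean_nm": s.mean, "sd_nm": s.sd, "n": s.n,
        "coassociation_fraction": foci_spatial.coassociation_fraction(a, b, thr),
        "threshold_nm": thr,
    }
    if len(a) >= 2:
        w = foci_spatial.summarize(foci_spatial.nn_within_channel(a))
        summary["within_channel_a"] = {"mean_nm": w.mean, "sd_nm": w.sd, "n": w.n}
    if "voxel_nm" in p and p["voxel_nm"]:
        summary["colocalization_fraction"] = foci_spatial.colocalization_fraction(
            a, b, float(p["voxel_nm"])
        )
    dist_out = outdir / "nn_distances.tsv"
    with dist_out.open("w") as fh:
        fh.write("distance_nm\n")
        for v in d.values:
            fh.write(f"{v:.6f}\n")
    json_out = outdir / "nn_summary.json"
    json_out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"distances": d.n}, [dist_out, json_out]


def _cmd_simulate_clusters(p: dict, seed: int, outdir: Path):
    model = RepliconLengthModel(
        mu=float(p.get("mu", 140.6238)), sigma=float(p.get("sigma", 58.8192)),
        truncation=p.get("truncation", "clip"),
    )
    pmf = (
        ClusterSizePMF.from_string(p["pmf"]) if p.get("pmf") else ClusterSizePMF()
    )
    n = int(p.get("n", 112))
    sample = sample_clusters(n, pmf, model, seed)
    profile = build_profile(sample.dna_content, float(p.get("bin_width_kbp", 50.0)))
    out_tsv = outdir / "cluster_profile.tsv"
    write_profile_tsv(profile, out_tsv)
    summary = {
        "n_clusters": n, "mean_kbp": profile.mean, "sd_kbp": profile.sd,
        "central90_kbp": list(profile.central90),
        "pmf_mean": pmf.mean(),
    }
    out_json = outdir / "cluster_summary.json"
    out_json.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"clusters": n}, [out_tsv, out_json]


def _cmd_simulate_profile(p: dict, seed: int, outdir: Path):
    if p.get("lengths_kbp"):
        lengths = tuple(float(x) for x in str(p["lengths_kbp"]).split(","))
    else:
        rng = np.random.default_rng(seed)
        n = int(p.get("n_domains", 6))
        lengths = tuple(rng.uniform(275.0, 935.0, size=n))
    if p.get("heights"):
        heights = tuple(float(x) for x in str(p["heights"]).split(","))
    else:
        rng2 = np.random.default_rng(seed + 1)
        heights = tuple(rng2.uniform(0.5, 1.5, size=len(lengths)))
    spec = TimingProfileSpec(
        domain_lengths_kbp=lengths,
        peak_heights=heights,
        bin_size_bp=int(p.get("bin_size_bp", 10_000)),
        noise_sd=float(p.get("noise_sd", 0.0)),
        seed=seed,
    )
    profile = gen_timing_profile(spec)
    out_bg = outdir / "timing_profile.bedgraph"
    write_bedgraph(profile, out_bg)
    truth = {
        "boundaries_bp": [int(x) for x in profile.truth_boundaries_bp],
        "apexes_bp": [int(x) for x in profile.truth_apexes_bp],
        "lengths_kbp": list(lengths),
    }
    out_truth = outdir / "timing_truth.json"
    out_truth.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {"bins": len(profile), "domains": len(lengths)}, [out_bg, out_truth]


def _cmd_segment_domains(p: dict, seed: int, outdir: Path):
    profile = read_bedgraph(p["bedgraph"])
    params = SegmentationParams(
        smoothing_window=int(p.get("window", 3)),
        min_prominence=(
            float(p["prominence"]) if p.get("prominence") is not None else None
        ),
        min_domain_length_kbp=float(p.get("min_length_kbp", 0.0)),
    )
    domains = call_domains(profile, params)
    out_bed = outdir / "domains.bed"
    write_domains_bed(domains, out_bed)
    out_len = outdir / "domain_lengths.tsv"
    with out_len.open("w") as fh:
        fh.write("length_kbp\n")
        for d in domains:
            fh.write(f"{d.length_kbp:.6f}\n")
    return {"domains": len(domains)}, [out_bed, out_len]


def _fiber_config_from_params(p: dict) -> FiberConfig:
    kwargs = {}
    for key in ("pulse1_min", "chase_min", "pulse2_min", "noise_sd_kbp", "kbp_per_um",
                "exclusion_kbp"):
        if p.get(key) is not None:
            kwargs[key] = float(p[key])
    if p.get("fork_rate") is not None:
        lo, _, hi = str(p["fork_rate"]).partition(",")
        kwargs["fork_rate_kbp_per_min"] = (float(lo), float(hi or lo))
    if p.get("class_mix") is not None:
        kwargs["class_mix"] = tuple(float(x) for x in str(p["class_mix"]).split(","))
    if p.get("pmf"):
        kwargs["replicons_per_cluster"] = ClusterSizePMF.from_string(p["pmf"])
    return FiberConfig(**kwargs)


def _cmd_simulate_fibers(p: dict, seed: int, outdir: Path):
    cfg = _fiber_config_from_params(p)
    fibers = gen_fibers(cfg, int(p.get("n", 100)), seed)
    out = outdir / "fibers.tsv"
    write_fibers_tsv(fibers, out)
    return {"fibers": len(fibers), "tracks": sum(len(f.tracks) for f in fibers)}, [out]


def _cmd_classify_fibers(p: dict, seed: int, outdir: Path):
    fibers = read_fibers_tsv(p["fibers"])
    params = AnalysisParams(
        kbp_per_um=float(p.get("factor", 2.59)),
        cluster_gap_kbp=float(p.get("gap_kbp", 250.0)),
        exclusion_kbp=float(p.get("exclusion_kbp", 250.0)),
        min_fiber_mbp=float(p.get("min_fiber_mbp", 0.8)),
    )
    report = cohort_report(fibers, params)
    out_json = outdir / "fiber_report.json"
    out_json.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    out_tsv = outdir / "fiber_classes.tsv"
    with out_tsv.open("w") as fh:
        fh.write("fiber_id\tclass\ttruth_class\n")
        for f in fibers:
            if not f.tracks:
                continue
            cls = fiber_analysis.classify_fiber(f, params).value
            fh.write(f"{f.fiber_id}\t{cls}\t{f.truth_class or ''}\n")
    return {"fibers": report.n_fibers}, [out_json, out_tsv]


@dataclass(frozen=True)
class _Sub:
    run: object
    accepted: tuple


SUBCOMMANDS: dict[str, _Sub] = {
    "simulate-foci": _Sub(_cmd_simulate_foci, (
        "model", "nucleus_diameter_um", "focus_diameter_nm", "foci_per_zone",
        "n_zones", "zone_duration_h", "n_chains", "keep_chains", "plasticity_sd_nm",
    )),
    "nn": _Sub(_cmd_nn, ("foci", "a_zone", "b_zone", "threshold_nm", "voxel_nm")),
    "simulate-clusters": _Sub(_cmd_simulate_clusters, (
        "n", "mu", "sigma", "truncation", "pmf", "bin_width_kbp",
    )),
    "simulate-profile": _Sub(_cmd_simulate_profile, (
        "n_domains", "lengths_kbp", "heights", "bin_size_bp", "noise_sd",
    )),
    "segment-domains": _Sub(_cmd_segment_domains, (
        "bedgraph", "window", "prominence", "min_length_kbp",
    )),
    "simulate-fibers": _Sub(_cmd_simulate_fibers, (
        "n", "pulse1_min", "chase_min", "pulse2_min", "fork_rate", "class_mix",
        "pmf", "noise_sd_kbp", "kbp_per_um", "exclusion_kbp",
    )),
    "classify-fibers": _Sub(_cmd_classify_fibers, (
        "fibers", "gap_kbp", "exclusion_kbp", "min_fiber_mbp", "factor",
    )),
}


def run_pipeline(config: RunConfig) -> RunLog:
    """Execute one subcommand, write its outputs and a JSON run log."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    counts, outputs = SUBCOMMANDS[config.subcommand].run(
        config.params, config.seed, config.outdir
    )
    log = RunLog(
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        subcommand=config.subcommand,
        params={k: str(v) for k, v in config.params.items()},
        seed=config.seed,
        versions=_versions(),
        record_counts=counts,
        outputs=[str(o) for o in outputs],
    )
    (config.outdir / "run_log.json").write_text(
        json.dumps(log.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return log
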