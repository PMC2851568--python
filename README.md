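# sphasetools

During S phase, mammalian genomes replicate as ~0.5–1 Mbp units — DNA foci,
each a cluster of 3–5 replicons served by one replication factory — and
different foci replicate at characteristic times. A central question is
whether the order of activation is dictated by *spatial* proximity of foci in
the nucleus, by their *genetic* continuity along the chromosome fibre
(a "next-in-line" mechanism), or is random. `sphasetools` is a tested
re-implementation of the computational side of that question, for people who
analyse replication-timing and single-molecule replication data:

* **Monte-Carlo nuclei** of labeled foci under the three activation models
  (350 spherical foci of 500 nm per 1-h time zone, 10 zones, in a 10 µm
  nucleus), with mitotic segregation and chromosome-territory plasticity;
* **3D nearest-neighbour statistics** — the discrimination statistic is the
  co-association fraction: the proportion of foci labeled in time zone *z*
  whose nearest zone-*z+1* focus lies within 500 nm;
* **replicon-cluster simulation** — cluster DNA content as a compound sum
  `S = Σᵢ₌₁ᵏ Lᵢ` with `k ~ pmf(replicons/cluster)` and
  `L ~ N(µ = 140.6238, σ = 58.8192) kbp` (clipped positive), compared to
  timing-domain length distributions by Pearson correlation of binned
  profiles;
* **timing-domain segmentation** — peaks in a binned timing profile
  (bedGraph) delimited by the valleys between prominence-filtered maxima;
* **DNA-fibre classification** — pulse–chase–pulse labeled tracks
  (30 min / 1 h / 20 min, 1 µm = 2.59 kbp) classified as *extending
  replicons*, *secondary activation*, or *uncoupled* initiations
  (channel-2-only tracks > 250 kbp from any channel-1 track), with
  inter-origin distances and fork-rate estimates.

Every input is produced by the package's own generators with ground truth
attached, so all statistics are testable end to end.

## Worked example

Simulate a genetic-continuity nucleus, segregate to 3 labeled territories,
apply 300 nm plasticity, then measure zone-1 → zone-2 nearest neighbours:

```sh
sphase simulate-foci --model genetic --keep-chains 3 \
    --plasticity-sd-nm 300 --seed 11 --out run1
sphase nn --foci run1/foci.tsv --a-zone 1 --b-zone 2 \
    --threshold-nm 500 --seed 11 --out run1
cat run1/nn_summary.json
```

```json
{
  "coassociation_fraction": 1.0,
  "mean_nm": 333.95730538206413,
  "n": 24,
  "sd_nm": 62.13801472778716,
  "threshold_nm": 500.0,
  "within_channel_a": {
    "mean_nm": 864.218907702629,
    "n": 24,
    "sd_nm": 474.0023272210886
  }
}
```

Consecutively labeled foci sit ~330 ± 60 nm apart — closer than the 500 nm
focus diameter, i.e. touching neighbours — and every zone-1 focus has a
zone-2 focus within 500 nm (`coassociation_fraction: 1.0`). Foci of the
*same* channel are much farther apart (~860 nm), which is the signature that
consecutive-zone adjacency is structural, not density. Re-running with
`--model random` leaves the co-association far below 1.

Simulating 10 000 replicon clusters with the default length model and a
uniform {3,4,5} replicons/cluster table:

```sh
sphase simulate-clusters --n 10000 --seed 11 --out run2
cat run2/cluster_summary.json
```

```json
{
  "central90_kbp": [306.51202389214484, 845.7882534213616],
  "mean_kbp": 560.1465784402146,
  "n_clusters": 10000,
  "pmf_mean": 3.9999999999999996,
  "sd_kbp": 164.3198436324056
}
```

The mean cluster content (~560 kbp here) is several times the single-replicon
mean, in the range observed for replication-timing domains. Other
subcommands: `simulate-profile`, `segment-domains`, `simulate-fibers`,
`classify-fibers` (see `sphase <cmd> --help`); everything is also available
as library functions (`import sphasetools`).

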