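# Methods

This note documents the models behind `sphasetools`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic
generators do and do not capture about real data.

## Nuclear foci model

A nucleus is a sphere of diameter 10 µm containing `foci_per_zone × n_zones`
spherical foci (defaults 350 × 10, diameter 500 nm). Focus centres are
restricted to the ball of radius `R − r` so spheres lie fully inside.
Overlap between foci is permitted: the quoted 44% occupancy of the default
configuration is the naive volume-sum ratio `3500 · (250/5000)³ = 0.4375`,
which ignores overlap, and a hard-sphere packing would not reproduce that
number. Uniform placement uses rejection sampling from the bounding cube; a
bounded attempt count turns pathological geometries into an explicit
`CapacityError`.

Three activation models assign time-zone labels (1-based, one per hour of
S phase):

* **random** — uniform centres; zone labels are a random permutation with
  exact per-zone counts, independent of position; each focus is its own
  "chain", since random activation implies no useful territory structure.
* **genetic** — foci lie on 46 chains (one per chromosome of a diploid
  human karyotype; configurable), built as fixed-step random walks with
  radial reflection at the nuclear wall. Zone labels follow a *cyclic
  wave*: along each chain the zone advances by one per focus, wrapping
  after the last zone. One wrap is one replication wave of `n_zones`
  consecutive foci, so a chain of ~76 foci carries ~7–8 interleaved waves —
  a caricature of the alternating early/late (R/G-band) structure of real
  chromosomes. The construction guarantees the property the model exists
  for: every focus of zone z (z < n_zones) is chain-adjacent to a zone-z+1
  focus, except possibly the single terminal focus of a chain. A
  block-structured assignment (several same-zone foci in a row) was
  rejected because block-interior foci are many walk steps from the next
  zone and the model would no longer predict 1:1 co-association — the
  prediction it is meant to embody.
* **spatial** — same chain geometry as the genetic model (so territories
  exist and segregation behaves identically), but zone labels come from
  proximity to one uniformly placed seed point per zone, rebalanced to
  exact counts by reassigning the farthest surplus foci.

The default chain step is 0.75 × focus diameter (375 nm). Measured
centre-to-centre separations of consecutively labeled foci are 350–390 nm —
*below* the ~500 nm focus diameter (adjacent foci interpenetrate) — so a
step equal to the diameter would place every adjacent pair exactly on the
500 nm co-association threshold and make the statistic numerically
degenerate. Both step and threshold are parameters.

**Segregation** keeps the foci of `n_keep_chains` uniformly sampled chains,
emulating the dilution of labeled chromosomes to ~3 territories per cell
over days of growth. **Plasticity** models territory dynamics: for the
genetic model each chain moves rigidly (uniform random rotation about its
centroid plus an isotropic Gaussian translation, sd `step_sd_nm` per axis),
which reproduces the observed 0.2–0.6 µm positional shifts while preserving
intra-chain distances — the experimentally observed behaviour that
neighbour relations survive territory deformation. Optional per-focus
jitter (`local_jitter_nm`, default 0) is repaired sequentially along each
chain so adjacent separations never exceed 1.5 × their original value;
foci are finally re-projected radially into the nucleus (a contraction, so
it cannot break the 1.5× bound). For random/spatial sets every focus is
displaced independently (mean displacement magnitude `σ√(8/π)`, the
3-d.o.f. chi mean).

## Spatial statistics

Distances are Euclidean centre-to-centre in nm, computed with a KD tree and
tested for exact agreement against an O(n²) scan. Cross-channel queries
never exclude a focus from being its own neighbour (the channels are
distinct labels); within-channel queries do. Equidistant neighbours are
genuinely tied, so reported distances do not depend on the tie-break. The
model-discrimination statistic pools, over all z, the fraction of zone-z
foci whose nearest zone-z+1 focus lies within 500 nm. Summary statistics
are mean ± sample sd (n−1); the sd of a singleton is defined as 0 with a
warning. Two-condition comparisons use Welch's unequal-variance t test
(sample sizes and variances differ between conditions throughout); two
zero-variance samples with equal means give p = 1 by convention. Voxel
co-localization rasterises each sphere as the voxels whose centres fall
inside it (default voxel 50 nm, the imaging voxel size being unknown) and
reports `|voxels(a) ∩ voxels(b)| / |voxels(a)|`.

## Replicon-cluster simulation

Cluster DNA content is the gap-free sum of k replicon lengths with k drawn
from a replicons-per-cluster PMF and lengths from N(140.6238, 58.8192²) kbp.
The published frequency table behind the original simulations is in a cited
reference and not reproduced here; the default PMF is uniform on {3, 4, 5}
(mean 4, consistent with "3–5 replicons per ~1 Mbp") and fully
user-overridable, so simulated means (~560 kbp at the default PMF) are
conditional on that choice. The distribution-free property — mean content
equals E[k]·E[L] (Wald's identity) — is what the tests assert.

Non-positive normal draws (0.84% of the mass) are **clipped** to a 0.1 kbp
floor by default. Clipping preserves the published moments (mean +0.12%,
sd −0.76%, exact values 140.789 / 58.371 by quadrature); resampling the
negative tail — also available (`truncation="resample"`), as is reflection —
yields the lower-truncated normal whose mean is +0.97% and sd −2.83% off
the published values, distorting the calibration the model is defined by.

Profiles are normalised histograms from 0 to the rounded-up maximum
(default bin 50 kbp); the central 90% interval uses empirical 5th/95th
percentiles with linear interpolation between order statistics. Profile
similarity is the Pearson correlation of per-bin frequencies on a common
grid (shorter profiles are padded with empty bins; differing bin widths are
an error, as rebinning frequencies across incommensurate grids is not
well-defined).

## Timing-domain segmentation

Timing profiles are uniform genomic bins (0-based half-open; bedGraph I/O).
The caller smooths with a centred moving average (default window 3 bins,
edge-truncated), finds local maxima with prominence ≥ 0.1 × the profile IQR
by default (plateau-aware, since symmetric even-width peaks have two-bin
tops), and places each boundary at the minimum of the *original* values
between adjacent apexes — smoothing biases valley positions toward the
shallower peak by up to ⌊window/2⌋ bins, while the native-resolution valley
stays within one bin of the true inflection on noise-free input. Ties
resolve toward the midpoint between apexes. Profile ends count as minima,
so called domains tile the profile exactly; domains shorter than
`min_domain_length_kbp` (default 0) merge into the neighbour with the
higher apex. Increasing the prominence threshold can only remove peaks, so
the domain count is monotone non-increasing in it.

The synthetic profile generator concatenates one triangular peak per
planted domain (apex height = timing value, valleys at boundaries) plus
optional white noise, and records the planted boundaries and apexes as
ground truth. Real timing profiles have autocorrelated noise, asymmetric
peaks and plateaux; recovery results on triangular peaks therefore bound
the caller's geometric accuracy, not its robustness on experimental data.
The published domain statistics (mean 529.5 ± 208.0 kbp over 112 domains,
and profile correlations 0.9193/0.9100 against cluster simulations) derive
from an external ES-cell timing dataset browsed interactively and are
treated as external validation, not recomputed here.

## Fibre simulation and classification

Each simulated fibre carries one primary replicon cluster: k origins
(replicons-per-cluster PMF) fire at the start of the first pulse; forks run
bidirectionally at a per-fibre rate drawn uniformly from 1–2 kbp/min;
converging forks fuse at gap midpoints; DNA synthesised during pulse 1
(30 min) and pulse 2 (20 min, after a 60 min chase) becomes channel-1 and
channel-2 tracks. Ground-truth classes are drawn at 55% extending / 40%
secondary activation / 5% uncoupled (the printed uncoupled rate; the
double-labeled split is not printed and both classes are described as
common — the mix is configurable). Primary inter-origin spacings use the
published class-specific models (181.2 ± 87.5 kbp extending,
119.6 ± 47.0 kbp secondary), clipped so one cluster stays one cluster at
the 250 kbp linkage gap.

For secondary fibres, neighbouring origins fire at the start of pulse 2 on
one or both flanks. Their positions are drawn from the spacing model but
clipped to lie beyond the primary cluster's outgoing fork front (origins
the fork has already passed would be passively replicated, not fire) and
close enough to remain within the 250 kbp coupling distance of labeled
DNA, with consecutive tracks kept resolvable (≥ 5 kbp apart). Uncoupled
fibres add one isolated pulse-2-only origin > 250 kbp beyond any channel-1
track. Track endpoints receive Gaussian noise (default sd 5 kbp, ~2 px at
the stated conversion; tests of exact recovery use 0) and coordinates are
emitted in µm at 2.59 kbp/µm. Fibres are padded with unlabeled DNA to
≥ 850 kbp so the 0.8 Mbp analysis filter keeps them.

Classification works in kbp. Channel-1 tracks within 250 kbp gaps form
runs; the run with the largest span is the primary cluster. A channel-2
track is *coupled* if within the exclusion distance (250 kbp) of any
channel-1 track. Decision order: ≥ 2 coupled channel-2 tracks in one flank
→ secondary activation; otherwise any uncoupled channel-2 track (or no
channel-1 track at all) → uncoupled; otherwise a single coupled flank track
is extension only if its gap to the cluster edge falls in the chase window
`[rate_min·chase − tol, rate_max·chase + tol]` (default [45, 135] kbp,
tol 15 kbp) — the distance the cluster's own outgrowing fork travels
unlabeled — and is otherwise scored as secondary. The order matters:
coupled evidence of secondary firing outranks a distant extra track, while
an otherwise-extending fibre with an isolated distant track is an
uncoupled event, which is exactly how the generator composes those classes.

Origins are proxied by channel-1 track midpoints (exact for symmetric
bidirectional forks; biased when forks fused during the pulse, which is
why recovery tests use wide spacings). Fork rates divide track length by
pulse duration, halved for bidirectional tracks, flagged outside
0.5–3 kbp/min. The uncoupled rate is reported three ways: the fibre-class
proportion, per track group (maximal runs of tracks linked by ≤ 250 kbp
gaps; groups with no channel-1 member are "uniquely second-pulse"), and
per track — the printed 5% does not state its denominator.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (numpy `default_rng`) and
is bit-reproducible; pipeline runs log seed, parameters and versions. Test
and acceptance problem sizes are chosen so the whole suite runs in seconds
on one core while keeping Monte-Carlo error well inside the asserted
tolerances: 10⁶ draws for length-model moments (se of the mean ≈ 0.06 kbp),
20-seed sweeps for model discrimination and domain recovery, 10³ fibres for
classification, 10⁵ clusters for the Wald identity.

## Known limitations

No voxel-level image formation (foci are ideal spheres; localisation error
only as optional jitter), no non-spherical nuclei, no cell-cycle kinetics
beyond discrete zones, no origin licensing or firing-time stochasticity
within a cluster (all primary origins fire at pulse start), no fibre
breakage, stretching variability or bundling, and no stalled-fork or
asymmetry analysis. In-cell distance measurements (e.g. 390 ± 148 nm) are
properties of the microscopy data; the package reproduces their
computation, not their values.
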