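# Methods

## The extrusion model

Chromatin is a 1D lattice of genomic bins (2 kb by default). Cohesin
complexes load at random unoccupied positions with both legs on adjacent
bins and extrude a loop by moving the legs outward, up to
`extrusion_speed` bins per leg per synchronous time step. A leg halts at
the lattice edge or one bin away from any other leg (collision); halted
legs resume when the obstruction clears.

**Directional barriers.** Oriented CTCF-binding elements capture legs
travelling against their arrow: a forward (+) barrier captures leftward
legs arriving from downstream, so forward elements anchor loops that extend
downstream of them and produce peaks in the *downstream* directional
contact profile; reverse (−) barriers mirror this. This is the standard
convergent-CTCF rule and the single most consequential convention in the
package; a dedicated test asserts it. Capture succeeds with
`capture_prob` per encounter, and captured legs release with
`release_rate` per step.

**Unloading and Wapl.** Each cohesin unloads with per-step probability
`u = unload_prob_ref × wapl_level`, multiplied by `ctcf_stabilization`
(≤ 1) while any leg is captured — CTCF-paused cohesin resides longer.
`wapl_level` is the dimensionless abundance of the cohesin-release factor:
1.0 for the pro-B-like condition, 2.2 for pre-B-like (the measured protein
ratio), and 6.6 for the Wapl-promoter-mutant pre-B-like condition
(threefold above pre-B).

**Pool-limited loading.** The loading-attempt rate is
`loading_rate × max(0, 1 − N/pool_size)`, with `N` the current bound
number: cohesin recycles from a finite nuclear pool, so the bound amount
saturates near `pool_size` rather than growing as 1/u. This matters
scientifically: with constant-rate loading the low-Wapl condition floods
the lattice and every leg jams, inverting the loop-length dose response.
`pool_size=None` recovers constant-rate loading.

**Contact-map synthesis.** Ensembles are sampled after a burn-in at a
fixed snapshot stride; per snapshot a map accumulates (i) one contact at
every cohesin's loop base `(left, right)`; (ii) "interaction-zone" contacts
between the outermost legs of cohesin pairs connected through at most
`transitive_depth` collisions (legs within one bin), weighted
`transitive_weight^depth` — the crosslinkable juxtaposition of loop bases
at collided cohesin rings; and (iii) a background whose per-pair contact
probability decays as `separation^-background_exponent`, scaled to a fixed
fraction of the expected signal. All randomness flows from one recorded
seed through independent Philox streams (simulation vs background).

## Locus presets

Two presets place barriers the way the immunoglobulin loci do, each with a
ground-truth table the recovery analyses score against.

* `igh_like` — 2.8 Mb / 1,400 bins; forward barriers tile the 5' 2.44-Mb
  V cluster (125 at `full` scale, 20 at `desk` scale), converging on an
  IGCR1-like and a 3'CBE-like reverse pair near the 3' end.
* `igk_like` — 3.2 Mb / 1,600 bins; 18 internal V-cluster barriers,
  reverse-dominated with a few interspersed forward elements, then a
  Cer-like reverse pair and a Sis-like forward pair near the 3' end and a
  barrier-free regulatory segment to the edge.

Desk-scale barrier spacing is kept ≥ 12 bins so neighbouring elements stay
resolvable by the profile peak caller. Barrier kinetics are preset
specific, modelling element-specific CTCF occupancy: heavy-chain-like
V-cluster elements pause transiently (release 0.02/step) so extruding legs
percolate through the dense all-forward array, kappa-like elements hold
longer (release 0.005/step), and the kappa internal elements capture at
0.6× the strength of the regulatory Cer/Sis pairs, letting sweeps sample
the cluster while the 3' elements anchor persistently.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 2,000 bp | lattice and analysis resolution |
| `loading_rate` | 0.4 /step | loading attempts at an empty lattice |
| `pool_size` | 4 | bound-cohesin saturation level |
| `unload_prob_ref` | 0.0165 /step | release probability at wapl 1.0 |
| `extrusion_speed` | 3 bins/leg/step | extrusion velocity |
| `ctcf_stabilization` | 0.3 | unloading multiplier while captured |
| `capture_prob` | 0.85 | per-encounter capture probability |
| `transitive_depth` | 3 | max collision-chain depth for zone contacts |
| `transitive_weight` | 0.8 | per-depth geometric weight |
| `background_fraction` | 0.3 | background share of expected signal |
| `n_snapshots` / `burn_in` / `stride` | 800 / 2,000 / 40 | ensemble sampling |
| Cross-score `d_min`–`d_max` | 30 kb – 1 Mb | cohesin-looping separation window |
| peak `span` / `min_prominence` | 5 bins / 2.5 SD | strict-local-max peak caller |
| stripe `window` / `threshold` | 101 bins / 0.15 | windowed extent measure |

The time step is left abstract; rates were chosen jointly so that the
pre-B-like condition (wapl 2.2) yields median extruded loops of ~250 kb on
the presets and so that loop-length medians decrease strictly across wapl
1.0 → 2.2 → 6.6 — the dose-response ordering observed between pro-B,
pre-B, and Wapl-overexpressing pre-B cells. With these rates, the desk
presets run in a few seconds on one core.

## Analysis definitions and numerical choices

* **Cross-score** sums raw (or obs/exp) contacts with upstream and
  downstream neighbours separately within the separation window; matrices
  binned finer than requested are coarsened by pixel aggregation. Bins are
  masked when more than half of their combined two-sided window falls
  off-locus or on unmappable partner bins; partial-window edge bins are
  kept and flagged so 3'-terminal anchors stay detectable.
* **Peak calling** takes strict local maxima within ±`span` bins whose
  prominence (height above the higher flanking minimum) exceeds
  `min_prominence` standard deviations of the unmasked profile — a
  transparent stand-in for an unpublished peak-caller configuration,
  surfaced as parameters rather than hard-coded.
* **Peak–CBE matching** pairs downstream peaks with forward elements and
  upstream peaks with reverse elements, greedily by distance with
  deterministic tie-breaks (higher score, then leftmost); each element is
  used at most once.
* **Gap detection** finds runs of bins below a low quantile of *both*
  profiles; on sparse maps a rolling mean (`smooth_bins`) absorbs Poisson
  zeros first, and quantile thresholds are computed on full-window bins so
  that edge-truncated bins cannot drag them to zero.
* **Balancing** is plain iterative correction equalizing marginals
  (tolerance 1e-5, 200 iterations); zero-marginal bins are masked with an
  absent (NaN) weight and excluded from every downstream statistic.
* **Expected-by-distance** averages over all valid bin pairs at each
  separation, counting empty pixels in the denominator.
* **P(s)**: the contact-frequency curve uses 0.1-decade log bins of
  separation with fractions normalized per analyzed region (recorded in
  the output); the slope is the centered finite difference of the
  *per-pair mean* contact frequency on log-log axes, so a power law
  `s^-a` gives a flat slope of `-a`.
* **Differential maps** scale both inputs to equal totals (the
  deterministic analogue of read down-sampling) before per-pixel
  `log2((A+p)/(B+p))` with pseudocount 1 raw count by default.
* **Stripe extent** averages the anchor-row signal and a barrier-free
  flank-row background in a rolling window (101 bins ≈ 200 kb,
  integrating over the punctate inter-CBE structure of sparse maps),
  subtracts the flank, normalizes to the track's own top decile, and
  thresholds at a fraction of that peak strength; the proximal contiguous
  stretch and the largest gap are reported alongside the above fraction.
* **Loop calling** is a deliberately simplified ring-enrichment detector
  (obs/exp > `min_enrichment` × ring mean, local maximum, raw-count
  floor), not a reimplementation of production punctate callers; loop
  length is the anchor-midpoint distance (resolution-robust). Loop-list
  comparison uses reciprocal ≥ 90 % overlap of both anchors.
* **Compartments**: leading eigenvector of the Pearson correlation of the
  obs/exp matrix over unmasked bins, sign-fixed against an
  active-chromatin phasing track; saddle strength is the corner ratio
  (outer 20 % of eigenvector quantiles; 50 quantiles by default, fewer on
  small matrices).
* **Motif scanning** scores both strands with a log-odds matrix and
  replaces an analytic p-value with a score threshold or a Monte-Carlo
  null quantile (`p < 0.001` honoured in the empirical mode); assignment
  to peak summits uses the 100-bp window with the higher-score rule.

## What the generator does and does not emulate

The synthetic maps reproduce the features the analyses are built to
detect: oriented-barrier loop anchoring, Wapl-dependent loop-length
scaling, collision chains bridging loop bases, distance-decay background,
and an insulated 3' regulatory segment. They do **not** emulate 3D polymer
physics, trans contacts, replication/cell-cycle heterogeneity, mappability
artifacts, restriction/ligation biases, or sequencing depth of real
Micro-C libraries (desk maps carry thousands, not billions, of contacts —
hence the windowed stripe statistics). Passing recovery tests therefore
demonstrates correctness of the analysis chain on data with known truth,
not performance on real libraries.

A known limitation of the 1D model class: contact-intensity scales (leg
travel, pinned dwell, traverse survival) are all exponential with rate
proportional to `wapl_level`, so extent contrasts between two Wapl levels
are bounded near their ratio. The locus-geometry asymmetry (dense
all-forward ladder vs sparse-forward reverse cluster) gives the correct
direction of the heavy-chain stripe truncation at elevated Wapl and the
chain-depth dependence of kappa stripe coverage, but the simulated
contrasts are milder than the full-vs-collapsed stripe geometry seen in
deep real maps: at the default thresholds, the 3'-anchored stripe extent
on `igh_like` drops from roughly two-thirds of the V cluster at wapl 1.0
to roughly one-third at 2.2 (rather than ~95 % to ~15 %), and the
depth-3-bridged Cer stripe on `igk_like` shortens its largest gap without
becoming fully contiguous across the cluster. The corresponding two
acceptance-style tests encode the stronger geometric expectations and are
expected to fail under the default study conditions; they are retained as
a faithful record of the model's reach.

## Real-data mode

`run_real_data` applies the identical analysis chain to user-supplied text
matrices (BED3 bins + triplet or dense counts), optionally with an
oriented-CBE BED6 for peak matching; no network access is ever attempted.
Outputs are bedGraph profile tracks, BED peak/gap intervals, BEDPE loops,
TSV curves/saddles, and a JSON report; every run writes a manifest echoing
the fully resolved configuration and seed.
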