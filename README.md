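# locifold

Chromatin-folding analysis of immunoglobulin loci: a 1D loop-extrusion
simulator with directional CTCF barriers, and the contact-map statistics used
to characterize V(D)J-recombination architecture — the **Cross-score**
directional loop-anchor statistic, P(s) contact-frequency curves and slopes,
differential and stripe quantification, A/B-compartment eigenvectors and
saddle strength, simplified punctate loop calling, loop-overlap comparison,
and oriented CTCF-binding-element (CBE) annotation.

## The scientific problem

The murine *Igh* (2.8 Mb) and *Igk* (3.2 Mb) loci must contract so that
distant V genes reach the proximal (D)J elements before RAG recombination.
Cohesin-mediated loop extrusion drives this folding, and the cohesin-release
factor **Wapl** sets cohesin's residence time: more Wapl, shorter loops.  The
two loci solve the contraction problem differently. The *Igh* V cluster
carries ~125 CBEs all in forward orientation, convergent with reverse CBEs at
the 3' IGCR1/3'CBE elements, supporting extended extrusion across the whole
locus when Wapl is low (pro-B cells). The *Igk* V cluster carries mostly
reverse CBEs matching the reverse pair at the 3' Cer element, folding into
many internal loops whose collided cohesins juxtapose distant sequences at a
transient "interaction zone" even when Wapl is high (pre-B cells).

This package makes every step of that analysis testable without any
sequencing data: the simulator generates contact maps from locus presets with
known ground-truth barrier positions and orientations, and the analysis stack
is scored against that ground truth.

## The core statistic

For each genomic bin *i* at resolution *b* (default 2 kb), with contact
counts *C(i, j)* and a separation window *d*<sub>min</sub>–*d*<sub>max</sub>
(default 30 kb – 1 Mb, the cohesin-looping range):

```
up(i)   = Σ_{j < i,  d_min ≤ (i−j)·b ≤ d_max}  C(j, i)
down(i) = Σ_{j > i,  d_min ≤ (j−i)·b ≤ d_max}  C(i, j)
```

Peaks of `down` mark anchors whose loops extend downstream — forward CBEs
under the convergent-CTCF rule — and peaks of `up` mark reverse CBEs.
An obs/exp mode divides each count by the distance-decay expectation before
summation. Runs where both profiles are low flag insulated segments (the 3'
"regulatory loop").

## Worked example

```sh
python examples/cross_score_anchors.py
```

prints, for a simulated kappa-like locus at the pre-B Wapl level (seed 11):

```
22 profile peaks (17 upstream / 5 downstream)
anchor recovery: precision 1.00, recall 1.00, orientation mismatches 0
insulation gap: bins 1453-1468 (2.91-2.93 Mb)
```

Every called peak lies within ±2 bins (±4 kb) of a ground-truth barrier of
the matching orientation — upstream peaks at reverse elements, downstream
peaks at forward elements — and the detected low-signal gap is the insulated
boundary between the V cluster and the Cer/Sis-bounded regulatory segment.

`examples/wapl_dosage_loops.py` shows the Wapl dose response:

```
wapl 1.0: median loop   398 kb, mean P(s) slope -0.58
wapl 2.2: median loop   250 kb, mean P(s) slope -1.01
wapl 6.6: median loop   108 kb, mean P(s) slope -1.22
```

Median extruded loop length falls monotonically as Wapl rises, mirroring the
pro-B > pre-B > Wapl-overexpressing pre-B ordering seen experimentally.
The other examples cover map simulation (`simulate_locus_maps.py`),
compartments and loop calling (`compartments_and_loops.py`), and CBE
annotation (`annotate_cbes.py`).

A thin CLI mirrors the library:

```sh
locifold simulate --kind igk_like --wapl-level 2.2 --seed 11 --out-prefix /tmp/igk
locifold cross-score --matrix /tmp/igk.pixels.tsv --bins /tmp/igk.bins.bed \
    --cbes /tmp/igk.truth.bed --out-prefix /tmp/igk_cs
locifold benchmark --seed 1 --out-dir /tmp/bench
```

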