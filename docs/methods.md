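# Methods

## The model

Priming is modelled as a two-leg translocation process on a circular plasmid
of length L, anchored at a primed protospacer (PPS) whose PAM is a
non-consensus variant (default TG). The strand carrying the PPS is the
*target strand* (TS, the strand base-paired by the crRNA); its complement is
the *non-target strand* (NTS).

**Leg 1 (NTS).** R-loop formation at the PPS displaces the NTS as ssDNA. One
adaptation complex loads there and translocates 3'→5' along the NTS. Travel
distance is geometric: a memoryless per-bp fall-off with mean `proc_mean`
(the package's processivity parameter). Every GG dinucleotide the complex
reads on the NTS within its travelled span is excised with probability
`p_capture`; the protospacer is the 32 nt (see length model) immediately 5'
of the GG on that strand. Because 3'→5' on the NTS runs toward lower +
coordinates when the PPS is on the − strand, leg-1 products lie 5' of the PPS
on their own strand — the model's strongest asymmetry.

**Leg 2 (TS).** Unwinding exposes the TS 3' of the PPS as ssDNA over a span
equal to the leg-1 travel. A Poisson(`lambda_ts`) number of complexes load at
uniform positions within that span and translocate 3'→5' along the TS with
the same fall-off and capture rules. They may run past the PPS, which yields
TS hits on both sides of it with a 5' excess — a more diffuse distribution
than leg 1, as observed.

**Background.** With probability `p_bg` per cell, one capture occurs at a GG
PAM drawn uniformly from the whole plasmid, either strand.

**Slippage.** At excision, with probability `p_slip` the register shifts by
±1 nt (sign equiprobable), moving the protospacer interval and the PAM
together. Downstream, such hits show GG at +1/−1 (`slip_plus1`) or −2/−3
(`slip_minus1`) instead of −1/−2. Note that the combination "GG at both
+1/−1 and −2/−3 while −1/−2 is not GG" is logically impossible (it would
force G at −1 and −2); the classifier keeps a `both` branch defensively.

**Destination arrays.** Each capture is routed to CRISPR1/2/3 with weights
`array_weights` and inserted leader-proximally (newest spacer closest to the
leader), duplicating the first repeat.

**Event counts per cell.** Each clone draws a target event count from a
geometric distribution truncated to 1..9 (`event_geom_p`, reflecting that
screened clones carry 1–9 new spacers, mode 1, typically ~2); priming rounds
(leg 1 + leg 2) run until the pooled captures reach the target, and the
retained events are drawn *uniformly* from a pool covering at least three
rounds. Retaining a prefix of the first round instead would over-select the
lower-variance NTS leg (the TS machine count is Poisson-dispersed) and skew
the strand split by several points. Mechanics dominate the target: with
`p_capture = 0` or no GG PAM on the plasmid, cells acquire nothing.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| plasmid length | 6735 | bp | size class of a small mobilizable plasmid; ~800 GG PAMs at GC 0.5 |
| `proc_mean` | 500 | bp | decay scale of the observed distance histogram; geometric chosen for memorylessness |
| `p_capture` | 0.05 | per GG read | gives ~1.5 captures per leg, so a clone reaches 1–9 spacers in a few rounds |
| `lambda_ts` | 1.0 | machines/round | one TS loading per NTS walk in expectation; balances the strand split at ~50:50 |
| `p_bg` | 0.05 | per cell | rare non-primed acquisition; ~2 % of events |
| `p_slip` | 0.08 | per capture | slipped PAMs are a small minority (<10 %) of acquisitions |
| `p_len33` | 0.12 | — | 33-nt spacers are ~12 % of acquisitions |
| `p_len_other` | 0.01 | — | 31/34-nt spacers are rare (<1 %), split evenly |
| `array_weights` | 0.65/0.32/0.03 | — | relative acquisition activity of CRISPR1/2/3 |
| `event_geom_p` | 0.4 | — | truncated geometric on 1..9; mode 1, ~2.3 events per clone |

All randomness flows from a single master seed; per-cell streams are derived
from (seed, cell index) so cells are independent of iteration order and
results are bit-reproducible.

## Conventions

* Coordinates are 0-based half-open on the + strand; an origin-spanning
  interval is encoded with `end > L` and reduced modulo L. Reports and BED
  output reduce coordinates (BED splits wrapped intervals into two arcs).
* PAM positions are counted **away from the protospacer into the 3' flank**:
  −1 is adjacent to the protospacer, +1 is the protospacer's last base. This
  is the reverse of some community conventions and is the most error-prone
  convention in this analysis; `flank3[0]` is always the −1 base.
* Signed distance is midpoint-to-midpoint, reduced to (−L/2, L/2], positive
  toward increasing + coordinate. The distance anchor is a package choice —
  midpoints keep the measure symmetric in protospacer length.
* 5'/3' direction labels are evaluated **on the hit's own strand**:
  `5prime` iff (hit on + and d < 0) or (hit on − and d > 0). TS/NTS labels
  compare the hit strand with the PPS strand.
* On a circle, "all leg-1 hits are 5' of the PPS" holds until a walk passes
  the antipode (|d| > L/2 folds the sign). At the default decay scale this
  affects ~0.1 % of events; it is circle geometry, not mechanism.

## Analysis stages

**Repeat/spacer parsing.** Repeats are found by a greedy left-to-right scan
at Hamming distance ≤ 3 from the per-array consensus (Sanger amplicons are
near-exact; edit-distance alignment would complicate interval bookkeeping).
Spacers are the inter-repeat gaps; gaps outside 20–50 bp are flagged
anomalous but retained. If no repeats are found the reverse complement is
tried once (amplicons are expected leader→trailer).

**New-spacer identification** takes the shortest leader-proximal prefix whose
removal leaves a non-empty exact match to a prefix of the wild-type spacer
list. Matching is exact by design: a mutated wild-type spacer raises an
array-mismatch error rather than being silently absorbed.

**Independence lower bound.** An acquisition is identified by the triple
(array, spacer sequence, ordered spacer context below it at insertion time).
Identical triples across clones may be ancestors or siblings and count once;
the number of distinct triples is therefore a lower bound on independent
acquisition events.

**Mapping** is exact by default (`max_mismatch = 0`; new spacers derive from
the plasmid verbatim), with a Hamming tolerance option for degraded reads.
Multiple placements at the minimal distance are flagged ambiguous; ambiguous
hits are excluded from distance statistics (they lack a unique locus) but
retained in PAM and length tables.

**Shifting windows.** Window size defaults to 5 % of L and the step to 1 %
(the step is a package choice, exposed in the config). Ratios are
protospacer-midpoint counts over GG-PAM counts per window; windows with zero
PAMs report an undefined (NaN) ratio, never zero.

**Clustering test.** The statistic is the mean |d| of unambiguous hits. The
null draws the same number of positions per strand uniformly without
replacement from the GG PAM landscape, so the test asks whether hits sit
closer to the PPS than the PAM supply allows; p = (1 + #{null ≤ obs}) /
(n_perm + 1). A permutation null was chosen because the claim is spatial and
the landscape is irregular; no analytic null is attempted. The
without-replacement null requires more PAMs than records per strand, so on
large simulated datasets the test is run on a study-scale subsample
(~100 records).

**Logos** use per-position base frequencies over the 8-nt 5' and 3' flanks
and information content 2 − H bits with a uniform background and no
small-sample correction; a plasmid-composition background is available as an
option. Logos are also computed per spacer-length group for consensus-PAM
hits.

**Processivity recovery.** Under the geometric travel model, capture
distances are geometric; the ML mean is the sample mean, reported with a
percentile bootstrap interval (200 resamples). Fits from fewer than 30
distances carry a small-sample flag. Two honest biases are documented: the
protospacer-midpoint anchor adds ~32 bp relative to the walk origin, and the
per-cell event cap down-weights long-travel cells; together with the
discreteness of the local PAM landscape this keeps recovered means within
roughly ±15 % of `proc_mean` at n ≈ 5000 — the package's tests require 20 %.

## What the generator does and does not emulate

It emulates: ~100 clones with 1–9 new spacers routed to three arrays with
unequal weights; 32-nt-dominant spacer lengths; GG PAMs with rare ±1
slippage; strand-balanced acquisition with a strong NTS-5' bias and a more
diffuse TS distribution; distance decay from the primed site on a ~6.7-kb
circular replicon; leader-proximal insertion with repeat duplication.

It does **not** emulate sequencing error (amplicons are error-free),
replication or conjugation biology, interference and plasmid-loss kinetics,
real leader/repeat sequence context (wild-type spacers are random 32-mers),
PAM-landscape heterogeneity beyond what a random sequence provides, or any
dependence between acquisition and plasmid copy number. Whether excision uses
ssDNA or dsDNA is unknown; the simulator captures on the ridden strand as a
modelling choice. Passing tests therefore validate the pipeline's logic and
the model's qualitative distribution shapes, not base-level properties of any
real dataset.

## Problem sizes

The test suite simulates 1000 clones (~2400 events) for distribution-shape
properties, 4500 clones (~5500 NTS-leg events) for processivity recovery, 100
random plasmids (0.3–1.5 kb) for the exhaustive mapping/PAM oracles, and 200
null datasets × 199 permutations for test calibration. The acceptance script
uses 1000 clones for the headline statistics and 4500 for the recovery check.
These sizes make every stochastic property statement stable across seeds.

## Known limitations

* The clustering test conditions on the observed number of hits per strand;
  it does not model per-clone correlation (several hits from one clone share
  a priming round), which makes the test anti-conservative if clones are
  treated as independent loci. The independence lower bound partially guards
  against this in the screening summaries.
* Repeat finding assumes indel-free amplicons; an indel inside a repeat
  shifts all downstream intervals and will surface as an array-mismatch.
* `both`-class slippage is unreachable (see above) and exists only as a
  defensive branch.
* The geometric travel law is an interpretability choice, not a measured
  kinetic; only its decay scale is identifiable from distance data.
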