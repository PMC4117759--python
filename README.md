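# crisprprime

Analysis of **primed spacer acquisition** in Type I-F CRISPR-Cas systems.

When a bacterium already carries a spacer matching a plasmid protospacer whose
PAM is degenerate (e.g. 5'-protospacer-**TG**-3' instead of the GG consensus),
interference is weak but adaptation is strongly stimulated: clones rapidly pick
up new spacers targeting the same plasmid ("priming"). Given Sanger amplicons
of the CRISPR arrays from such plasmid-cured clones, `crisprprime`:

1. parses each amplicon into ordered repeats and spacers and identifies the
   newly acquired leader-proximal spacers against wild-type array models;
2. maps every new spacer to the circular plasmid (both strands, across the
   origin) and records its 8-nt flanks;
3. calls the PAM at flank positions -1/-2 (consensus 5'-protospacer-GG-3')
   and classifies ±1-nt register **slippage** (GG at +1/-1 or -2/-3);
4. computes strand- and distance-resolved protospacer statistics relative to
   the primed protospacer: signed circular distances, target-strand (TS) vs
   non-target-strand (NTS) and 5'/3' splits, PAM-landscape-normalized
   shifting-window densities, flank sequence logos, a permutation test of
   clustering, and a lower bound on independent acquisition events.

A stochastic simulator of the **bi-directional translocation model** of
priming is part of the package: an adaptation complex (Cas1:Cas2-3) loads on
the displaced non-target strand at the primed site, translocates 3'→5' with a
memoryless per-bp fall-off, and excises protospacers at GG PAMs it reads; the
exposed target strand recruits further complexes that translocate 3'→5' on
that strand. The simulator produces clone amplicons plus a ground-truth event
table, so the whole pipeline is testable end to end without any external data.

## Model in brief

For a primed protospacer on the − strand, the signed circular distance of a
hit midpoint from the primed-site midpoint is

    d = ((m_hit − m_site + L/2) mod L) − L/2   ∈ (−L/2, L/2]

with d > 0 toward increasing + strand coordinate. Travel distances are
geometric with mean `proc_mean`; each GG read on the ridden strand within a
walk is captured with probability `p_capture`; a Poisson(`lambda_ts`) number
of target-strand machines load uniformly on the exposed span. Per-position
logo information content is `2 − H` bits (Shannon entropy, uniform
background). The clustering statistic is the mean |d| over hits, tested
against positions drawn uniformly without replacement from the strand-matched
GG PAM landscape.

## Worked example

Simulate a 6735-bp plasmid with a TG-PAM primed protospacer on the − strand,
60 clones, and run the full analysis:

```bash
crisprprime simulate --seed 42 --n-cells 60 --out-dir demo
crisprprime all \
    --plasmid demo/plasmid.fasta --amplicons demo/amplicons.fasta \
    --array-models demo/arrays.yaml --primed-site demo/primed_site.yaml \
    --n-perm 199 --seed 42 --out-dir demo/out
cat demo/out/summary.yaml
```

which prints:

```yaml
n_genotypes: 60
n_new_spacers: 126
n_unmapped: 0
independent_events_lower_bound: 114
clustering:
  mean_abs_distance_bp: 408.7738095238095
  p_value: 0.005
processivity_bp: 460.6159420289855
seed: 42
```

The 60 clones acquired 126 new spacers, all of which map back to the plasmid;
at least 114 are independent acquisition events (identical
array/spacer/context triples across clones are counted once). New protospacers
cluster near the primed site: their mean |d| of ~409 bp is far smaller than
expected from the GG PAM landscape (permutation p = 0.005 at 199 permutations),
and the fitted geometric decay scale of NTS-side distances is ~461 bp.
`demo/out/` also contains the per-hit table and BED intervals, length and
PAM-class tables, the TS/NTS × 5'/3' summary, shifting-window densities
(5 % window, 1 % step) and flank logos as TSV.

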