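# vlrbkit

Long-read immune-repertoire analysis for the variable lymphocyte
receptor B (VLRB) antibodies of jawless vertebrates, plus a synthetic
repertoire/read simulator with full ground truth.

Lamprey B-like lymphocytes assemble their antigen receptor, VLRB, from
leucine-rich-repeat (LRR) cassettes instead of immunoglobulin V(D)J
segments. A mature VLRB coding sequence is

```
SP — LRR-NT — LRR1 — LRRv × (k−1) — LRRve — CP — LRR-CT — stalk
```

with a 21-aa signal peptide (SP), a 31-aa capping N-terminal LRR, an
18-aa conserved LRR1, one to nine variable 24-aa LRRv units (the last
one, LRRve, immediately precedes the connecting peptide), an 11-aa CP,
a variable-length capping C-terminal LRR carrying the antigen-binding
loop, and an invariant 87-aa stalk. Because repertoire diversity comes
from the *number* of incorporated LRRv cassettes as well as their
sequence, amplicons vary by hundreds of bases and are best read with
long-read (HiFi) amplicon sequencing. `vlrbkit` is for researchers who
have such multiplexed, UMI-tagged VLRB amplicon reads (or want to
simulate them) and need the complete path to a filtered, annotated,
clustered repertoire.

## What the pipeline does

1. **Demultiplex/trim** — exact matching of the constant primer
   segments on both strands; reads lacking perfect primers or carrying
   disagreeing/unknown 6-nt barcodes are discarded.
2. **UMI correction** — reads sharing a 12-nt UMI are collapsed to a
   consensus molecule when they form a single ≥ 99%-identity cluster;
   divergent bins are discarded; molecules with identical sequence
   whose UMIs differ by ≤ 1 nt are merged to the best-supported member.
3. **ORF filters** — frame-0 translation; premature-stop sequences
   removed; proteins whose best stalk-motif window
   (`DCGKPACTTLLNCANFLSCLCSTCALCRKR`) has ≥ 3 mismatches removed;
   identical proteins collapsed per animal.
4. **Subunit annotation** — LRR1 by its 5 conserved residues
   (`xLxLxxNxxxxLxxxxFx`), LRRv units by 24-aa tiling on the conserved
   leucines of `xLxxLxxLxLx`, CP/LRR-CT split, and the loop bounded by
   the conserved W and C anchors (`Wxxx-loop-xxC`): core loop
   `[W+4, C−3]`, extended loop `W..C` (always core + 7).
5. **Consensus filter** — sequential length checks (LRRv 24, LRR1 18,
   LRR-NT 31, stalk 87, SP 21, CP 11) with per-step accounting.
6. **Analytics** — CD-HIT-style greedy identity clustering with
   threshold sweeps and cluster-size CDFs, cross-animal sharing at
   100% identity, Kyte–Doolittle hydropathy (GRAVY) and Grantham
   polarity statistics per LRRv position, loop hydropathy split at
   0.35, position frequency matrices, length distributions.

The simulator builds cassette libraries at the published genomic locus
counts (SP 1, LRR-NT 79, LRR1 66, LRRv 601, CP 29, LRR-CT 91, stalk 1),
assembles per-animal transcripts with a truncated-geometric LRRv count
(mean 2.2), and emits barcoded, UMI-tagged amplicon reads with PCR
duplicates, substitution errors and strand randomization — with a truth
table linking every read to its molecule, so every stage can be
verified end to end.

## Worked example

```
$ vlrbkit simulate --seed 5 --out-dir sim --animals 3 --molecules-per-animal 200
wrote 856 reads for 600 molecules to sim
$ vlrbkit run-all --reads sim/reads.fastq --out-dir out
retained 368 consensus VLRB sequences; reports in out
```

`out/run_report.json` shows the stepwise accounting (counts telescope —
each stage's output is the next stage's input):

```
"input_reads": 856,
"demux_rejections": {"no_fwd_primer": 16, "no_rev_primer": 28,
                     "barcode_mismatch": 11},
"demuxed_reads": 801,
"molecules": 581,
"premature_stop_8a": 195,
"no_stalk_8b": 0,
"unique_proteins": 385,
"no_lrr1_10a": 9, "no_lrrv_10b": 6, "no_loop_11": 1,
"retained": 368
```

At the default 10⁻³ per-base error rate, 55 of 856 reads carry an error
in a primer/barcode segment and are rejected; 195 molecules are the
simulated nonfunctional transcripts caught as premature stops; a
handful of error-carrying molecules lose a conserved motif residue and
fall out at annotation. `out/analytics.json` then reports, for the 368
retained records: mean protein length 255.4 ± 39.4 aa, mean core loop
16.8 ± 5.3 aa, 4 of 364 unique proteins (1.1%) shared between ≥ 2
animals, and 338/368 extended loops in the low-hydropathy class at the
0.35 GRAVY split.

Clustering any annotated subunit set, e.g. a threshold sweep of stalk
sequences against their single genomic locus:

```
$ vlrbkit cluster --annotations out/annotations.tsv --subunit protein \
    --threshold 0.95 --out clusters.tsv
```

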