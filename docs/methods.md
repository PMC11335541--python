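# Methods

## Amplicon model and coordinate conventions

The pipeline assumes the two-primer, UMI-tagged VLRB amplicon design:
reverse transcription primes inside the invariant stalk region with an
oligo carrying a 12-nt UMI (`TATTTCCAGCACACTGGATCAG` + N×12 +
`TCAACGTTTCCTGCAGAGGGCG`), and PCR uses a forward primer annealing in
the SP coding region (`TAT` + 6-nt barcode + `gtggatcaagtggatcgc`) and
a reverse primer annealing on the RT oligo (`TAT` + 6-nt barcode +
`CCAGCACACTGGATCAG`). The sense strand of the resulting amplicon is

```
TAT + barcode + [SP-anneal…CDS…stop] + stalk-anneal + rc(UMI)
    + rc(rev constant) + rc(barcode) + ATA
```

The SP-annealing segment encodes the first six SP residues (VDQVDR) and
is retained in the insert, which anchors the reading frame at insert
position 0. All coordinates are 0-based half-open; spans are in protein
coordinates unless a record is explicitly nucleotide-level. Every
constant of the design and of the analysis lives in `PipelineConfig`
(YAML-serializable; all defaults overridable).

## Demultiplexing

Primer and barcode matching is exact (no mismatches, no indels):
demultiplexing requires perfect copies of every constant segment, and
the 6-nt barcodes read from both ends must agree and be present in the
barcode table — the conservative reconciliation when the two ends
disagree. Matching is case-insensitive for nucleotides. Both strands
are tried; rejection reasons are `no_fwd_primer`, `no_rev_primer`,
`barcode_mismatch`.

## UMI correction

Within one animal, reads are binned by exact UMI. A bin collapses to
one consensus molecule iff its reads form a single single-linkage
cluster at ≥ 99% identity (identical columns of a global alignment /
alignment length; Hamming shortcut for equal lengths; edlib
minimum-edit-distance alignments otherwise). Divergent bins — UMI
collisions or heavily mutated duplicates — are discarded whole. The
consensus is the position-wise majority over the modal-length members;
column ties resolve to the residue of the most frequent full-length
member, then lexicographically, making the consensus deterministic.
This replaces the centroid behavior of external clustering tools with a
reproducible equivalent.

Molecules with identical consensus whose UMIs are within Hamming
distance 1 (a single PCR error in the UMI) form connected components;
each component keeps only its best-supported member (highest read
count; ties keep the lexicographically smallest UMI). Keeping one
member rather than dropping both is a design choice recorded in the
run report.

## ORF and stalk filters

Translation is standard-code, frame 0, trailing partial codon ignored.
Because the RT-anneal site sits immediately downstream of the stop
codon, the insert of an intact transcript is exactly CDS + stop; a stop
codon is therefore premature iff it occurs before the final codon.

The 30-aa stalk motif `DCGKPACTTLLNCANFLSCLCSTCALCRKR` is slid over the
protein without gaps; the best window is kept iff it has ≤ 2
mismatches (removal at ≥ 3 residue differences), ties resolving to the
most C-terminal window. Indel-containing stalks are not rescued by a
gapped matcher: they fail the 87-aa stalk-length filter downstream
regardless. The stalk subunit span starts a fixed offset upstream of
the motif (`stalk_motif_offset`, default 50) and runs to the
C-terminus; the offset is a config parameter because the motif's
placement within the 87-aa stalk is a property of the germline stalk
cassette, and an anatomical start is required for the stalk-length
filter to be meaningful. Identical proteins are collapsed per animal,
abundance counting collapsed molecules.

## Subunit annotation

* **LRR1** — first 18-residue window, scanning window starts from the
  SP end (21) through the expected LRR-NT plus a 20-residue margin,
  whose five conserved residues of `xLxLxxNxxxxLxxxxFx` match exactly.
  Ungapped matching is the primary mode: any record that would need
  gaps fails the later exact-length filters anyway, so the modes agree
  on the final dataset.
* **LRR-NT** — residual span between SP and LRR1; no direct detector
  exists for it, and the 31-aa consensus filter constrains it.
* **LRRv** — 24-aa units tiled from the LRR1 end; a unit is accepted
  iff the four conserved leucines of `xLxxLxxLxLx` match exactly at
  some offset within it. Tiling stops at the first failing unit, which
  marks the CP start; the last accepted unit is the LRRve.
* **CP** — the 11 residues after the LRRve, defined positionally
  (deterministic, unlike template alignment against a random reference
  set); the CP-length filter enforces the consensus.
* **Loop** — within the LRR-CT (CP end to stalk start), the anchors are
  the first tryptophan and the first cysteine ≥ 7 residues downstream:
  core loop `[W+4, C−3]` inclusive, extended loop `W..C` inclusive, so
  extended − core = 7 always. A 15-aa core loop yields a 22-aa extended
  loop.

Annotation failures are statuses (`no_lrr1`, `no_lrrv`, `no_loop`),
never exceptions, and feed the stepwise report.

## Consensus filter and analytics

Length checks run sequentially — LRRv 24 (and ≥ 1 unit), LRR1 18,
LRR-NT 31, stalk 87, SP 21, CP 11 — each record charged to the first
failing step, because per-step counts are only meaningful under a fixed
order.

Clustering is greedy incremental (CD-HIT convention): sequences sorted
longest-first (ties lexicographic), each joining the first cluster
whose representative it matches at identity ≥ threshold (identical
aligned residues / shorter length), else founding a cluster. No k-mer
pre-screen is used; at desk scale the exact computation is affordable
and avoids a heuristic divergence source. Identical strings reuse the
first decision, which provably cannot change the outcome. Cluster-size
CDFs (largest first) serve as the diversity surrogate; the threshold
sweep reports total clusters and the percentage of sequences inside the
N largest clusters for a subunit with N genomic loci.

Sharing counts proteins present at 100% identity in ≥ k animals,
k = 2..n, fractions relative to the union of unique proteins.

Hydropathy is the Kyte–Doolittle GRAVY (mean per-residue value) and
polarity the Grantham scale; both ship as TSV data files and can be
overridden. Positional statistics group LRRv units by ordinal position
with the final (LRRve) unit as its own group — a single-unit molecule
contributes only to LRRve. Loop hydropathy is split high/low at GRAVY
0.35 computed on the extended loop; core-loop scores are also emitted.
Mean ± SD uses the sample SD (n−1). Length distributions include a
lattice statistic: the histogram mass on the modal protein-length class
modulo 24 aa (one LRRv cassette).

## Synthetic data generator

The simulator emulates the study conditions: 6 animals by default, a
truncated-geometric LRRv-count distribution on 1..9 whose parameter is
solved numerically so the truncated mean equals 2.2, per-base
substitution error 10⁻³ (HiFi-grade), PCR duplicates per molecule
1 + Poisson(0.4), a nonfunctional fraction of 0.35 (the order observed
for premature-stop/stalk-less transcripts in circulating lymphocyte
libraries), and 1.7% of transcripts copied verbatim into a second
(occasionally third) animal to create cross-animal sharing.

Cassette libraries are drawn uniformly over residues at the published
locus counts, with the motif residues pinned: LRR1 cassettes carry the
five conserved residues, LRRv cassettes the four conserved leucines at
a fixed construction offset (2), stalk cassettes embed the diagnostic
motif at offset 50, and LRR-CT cassettes contain exactly one W…C
anchor pair with core-loop lengths uniform on 10–25 aa (covering the
reported mean 16.6 ± 2.3 and mode 15; no generative loop model is
established). Reverse translation uses one fixed codon per amino acid —
no codon-usage model — which preserves all protein-level behavior while
substitution errors still exercise the nucleotide-level identity logic.
Nonfunctional transcripts receive either a random in-frame stop or a
1-nt deletion (frameshift).

What the generator does **not** emulate: partial-cassette templates and
alternative priming sites (so true biological LRRv diversity is
underrepresented), PCR chimeras, quality-score structure, codon usage,
and realistic amino-acid composition (draws are uniform). Passing tests
therefore demonstrate the correctness of the pipeline's logic against a
known truth, not its performance on real base-calling error profiles.
Chance motif occurrences in random cassettes (a spurious LRR1 window
upstream of the true one, or an LRRv-motif match just after the LRRve)
can legitimately shift annotation off the construction truth;
`has_spurious_motifs` flags such records (≲ 0.5% at the default
composition) and truth-recovery checks count them separately.

## Numerical and scale choices

Tolerances: UMI collapse identity 0.99; clustering thresholds
{0.65, 0.70, 0.75, 0.85, 0.95, 1.00}; loop split 0.35. Degenerate
inputs: empty read streams produce all-zero reports; empty cluster
input produces an empty cluster set; sharing requires ≥ 2 animals.
Verification suites run at deliberately modest scale — ground-truth
recovery on ~10,000 molecules across 6 animals, clustering oracle
equivalence on 50 random sets of ≤ 100 sequences — chosen as the size
at which every code path (UMI collisions, shared transcripts,
nonfunctional injection, spurious motifs) is exercised while remaining
cheap to rerun.

## Known limitations

Dataset-scale published counts (3.2M HiFi reads, 413,962 retained
sequences, Table-style cluster censuses) require the deposited SRA
data and are out of scope; the pipeline's operations are instead
validated against synthetic ground truth and brute-force oracles.
Non-consensus architectures (e.g. 23-aa LRRv variants) are annotated
where possible and removed by the consensus filter, mirroring the
published stringent approach. Statistical significance tests annotated
on published figures (t-tests, ANOVA) are not produced — only the
underlying summary statistics.
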