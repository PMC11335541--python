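"""Read orientation, primer/barcode demultiplexing and UMI correction.

The amplicon is fully determined by the primer design, so trimming is
anchor-based and exact: a read is kept only if it carries perfect copies
of every constant primer segment (forward SP-annealing segment at the 5'
end; stalk-anneal segment, reverse-primer constant and TAT pad at the 3'
end) and the two 6-nt barcodes agree and are listed in the barcode
table.  Reads are searched on both strands.

UMI correction happens in two stages, per animal:

1. reads sharing a UMI are collapsed to one consensus molecule when they
   form a single >= 99%-identity cluster; divergent bins (PCR chimeras or
   UMI collisions) are discarded whole;
2. molecules with identical consensus sequence whose UMIs differ by at
   most one nt are merged down to the best-supported member (a single
   PCR substitution in the UMI creates such neighbors).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import alignment_identity, hamming
from .config import PipelineConfig
from .simulate import revcomp

REJECT_NO_FWD = "no_fwd_primer"
REJECT_NO_REV = "no_rev_primer"
REJECT_BARCODE = "barcode_mismatch"


@dataclass
class DemuxRecord:
    read_id: str
    sample_id: str
    umi: str
    insert: str


@dataclass
class Molecule:
    sample_id: str
    umi: str
    consensus_nt: str
    read_count: int


def _try_parse(read: str, cfg: PipelineConfig) -> tuple | str:
    """Parse one orientation; returns (bc1, bc2, umi, insert) or a reason."""
    fwd = cfg.fwd_constant
    head = 3 + 6  # TAT pad + barcode
    stalk_anchor = revcomp(cfg.rt_stalk_segment)
    rev_anchor = revcomp(cfg.rev_constant)
    tail = len(stalk_anchor) + cfg.umi_length + len(rev_anchor) + 6 + 3
    if len(read) < head + len(fwd) + tail:
        return REJECT_NO_FWD
    if read[head:head + len(fwd)] != fwd or read[:3] != "TAT":
        return REJECT_NO_FWD
    if (read[-3:] != "ATA"
            or read[-(3 + 6 + len(rev_anchor)):-(3 + 6)] != rev_anchor
            or read[-tail:-(tail - len(stalk_anchor))] != stalk_anchor):
        return REJECT_NO_REV
    bc1 = read[3:head]
    bc2 = revcomp(read[-(3 + 6):-3])
    umi = revcomp(read[-(3 + 6 + len(rev_anchor) + cfg.umi_length):
                       -(3 + 6 + len(rev_anchor))])
    insert = read[head:-tail]
    return bc1, bc2, umi, insert


def orient_and_trim(read_id: str, read: str,
                    cfg: PipelineConfig) -> DemuxRecord | str:
    """Demultiplex one read; returns a :class:`DemuxRecord` or a reason.

    Rejection reasons: ``no_fwd_primer``, ``no_rev_primer``,
    ``barcode_mismatch`` (also when the two barcodes disagree).
    """
    read = read.upper()
    result = _try_parse(read, cfg)
    if isinstance(result, str):
        flipped = _try_parse(revcomp(read), cfg)
        if isinstance(flipped, str):
            # report the forward-strand reason unless the reverse got further
            return (flipped if (result == REJECT_NO_FWD
                                and flipped != REJECT_NO_FWD) else result)
        result = flipped
    bc1, bc2, umi, insert = result
    if bc1 != bc2:
        return REJECT_BARCODE
    sample = next((s for s, b in cfg.barcode_table.items()
                   if b.upper() == bc1), None)
    if sample is None:
        return REJECT_BARCODE
    return DemuxRecord(read_id=read_id, sample_id=sample, umi=umi,
                       insert=insert)


def demultiplex(reads: Iterable[tuple[str, str]], cfg: PipelineConfig
                ) -> tuple[list[DemuxRecord], Counter]:
    """Demultiplex a read stream; returns records and rejection counts."""
    records: list[DemuxRecord] = []
    rejects: Counter = Counter()
    for rid, seq in reads:
        out = orient_and_trim(rid, seq, cfg)
        if isinstance(out, str):
            rejects[out] += 1
        else:
            records.append(out)
    return records, rejects


# ----------------------------------------------------------------------
# UMI collapse
# ----------------------------------------------------------------------

def _single_linkage_one_cluster(seqs: Sequence[str], min_identity: float
                                ) -> bool:
    """True iff all sequences fall in one single-linkage identity cluster."""
    n = len(seqs)
    if n <= 1:
        return True
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = find(i), find(j)
            if ri != rj and alignment_identity(seqs[i], seqs[j]) >= min_identity:
                parent[ri] = rj
    return len({find(i) for i in range(n)}) == 1


def _majority_consensus(seqs: Sequence[str]) -> str:
    """Position-wise majority over the modal-length sequences.

    Column ties resolve to the residue used by the most frequent
    full-length member, then lexicographically.
    """
    length_counts = Counter(len(s) for s in seqs)
    modal_len = sorted(length_counts,
                       key=lambda L: (-length_counts[L], L))[0]
    full = [s for s in seqs if len(s) == modal_len]
    seq_counts = Counter(full)
    # most frequent member, ties broken lexicographically
    top_member = sorted(seq_counts, key=lambda s: (-seq_counts[s], s))[0]
    cols = []
    for i in range(modal_len):
        cc = Counter(s[i] for s in full)
        best = max(cc.values())
        tied = sorted(b for b, c in cc.items() if c == best)
        cols.append(top_member[i] if top_member[i] in tied else tied[0])
    return "".join(cols)


def collapse_umi_bins(records: Sequence[DemuxRecord], cfg: PipelineConfig
                      ) -> tuple[list[Molecule], int]:
    """Collapse same-UMI reads of one sample into consensus molecules.

    Returns the molecules plus the number of reads discarded in bins
    whose members exceeded 1% mutual divergence.
    """
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError("collapse_umi_bins expects records of one sample")
    bins: dict[str, list[DemuxRecord]] = defaultdict(list)
    for r in records:
        bins[r.umi].append(r)
    molecules: list[Molecule] = []
    discarded_reads = 0
    for umi in sorted(bins):
        seqs = [r.insert for r in bins[umi]]
        if _single_linkage_one_cluster(seqs, cfg.umi_collapse_identity):
            molecules.append(Molecule(
                sample_id=bins[umi][0].sample_id, umi=umi,
                consensus_nt=_majority_consensus(seqs),
                read_count=len(seqs)))
        else:
            discarded_reads += len(seqs)
    return molecules, discarded_reads


def remove_umi_neighbors(molecules: Sequence[Molecule],
                         cfg: PipelineConfig
                         ) -> tuple[list[Molecule], int]:
    """Drop 1-nt-UMI neighbors that carry identical consensus sequences.

    Molecules with identical consensus whose UMIs are within
    ``umi_neighbor_distance`` form connected components; each component
    keeps its single best-supported member (highest read count, ties to
    the lexicographically smallest UMI).
    """
    by_seq: dict[str, list[Molecule]] = defaultdict(list)
    for m in molecules:
        by_seq[m.consensus_nt].append(m)
    kept: list[Molecule] = []
    removed = 0
    for seq in by_seq:
        group = by_seq[seq]
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (len(group[i].umi) == len(group[j].umi)
                        and hamming(group[i].umi, group[j].umi)
                        <= cfg.umi_neighbor_distance):
                    parent[find(i)] = find(j)
        comps: dict[int, list[Molecule]] = defaultdict(list)
        for i, m in enumerate(group):
            comps[find(i)].append(m)
        for comp in comps.values():
            best = sorted(comp, key=lambda m: (-m.read_count, m.umi))[0]
            kept.append(best)
            removed += len(comp) - 1
    order = {(m.sample_id, m.umi): i for i, m in enumerate(molecules)}
    kept.sort(key=lambda m: order[(m.sample_id, m.umi)])
    return kept, removed
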