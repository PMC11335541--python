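"""Translation, premature-stop filter, stalk-motif filter, protein dedup.

The amplicon design anchors the reading frame: the retained insert
begins at the first codon of the SP and, for an intact transcript, ends
with the stop codon immediately upstream of the RT-primer anneal site.
A stop codon is therefore premature exactly when it occurs before the
final codon of the insert.

The stalk filter slides the 30-aa diagnostic motif over the protein
without gaps; proteins whose best window differs from the motif by
three or more residues are removed, following the published rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .align import hamming
from .config import PipelineConfig, Span
from .preprocess import Molecule

STATUS_OK = "ok"
STATUS_PREMATURE_STOP = "premature_stop"
STATUS_NO_STALK = "no_stalk"


@dataclass
class ProteinRecord:
    sample_id: str
    protein: str
    abundance: int
    stalk_span: Span | None
    status: str


def match_stalk(protein: str, cfg: PipelineConfig) -> Span | None:
    """Best ungapped placement of the stalk motif, if within 2 mismatches.

    Ties between equally good windows resolve to the most C-terminal
    one.  Returns the motif span, or None when every window carries
    ``stalk_max_mismatch + 1`` or more differences.
    """
    motif = cfg.stalk_motif
    m = len(motif)
    if len(protein) < m:
        return None
    best_start, best_mm = None, cfg.stalk_max_mismatch + 1
    for s in range(len(protein) - m + 1):
        mm = hamming(protein[s:s + m], motif)
        if mm <= best_mm:  # <= : most C-terminal wins ties
            best_start, best_mm = s, mm
    if best_mm > cfg.stalk_max_mismatch:
        return None
    return Span(best_start, best_start + m)


def stalk_subunit_span(protein: str, motif_span: Span,
                       cfg: PipelineConfig) -> Span | None:
    """Stalk span: starts a fixed offset upstream of the motif, runs to
    the C-terminus."""
    start = motif_span.start - cfg.stalk_motif_offset
    if start < 0:
        return None
    return Span(start, len(protein))


def translate_from_start(molecule: Molecule,
                         cfg: PipelineConfig) -> ProteinRecord:
    """Frame-0 translation plus the premature-stop and stalk filters."""
    insert = molecule.consensus_nt
    n_codons = len(insert) // 3
    if n_codons == 0:
        raise ValueError("insert shorter than one codon")
    aa = str(Seq(insert[: 3 * n_codons]).translate())
    first_stop = aa.find("*")
    if 0 <= first_stop < len(aa) - 1:
        return ProteinRecord(molecule.sample_id, aa[:first_stop], 1,
                             None, STATUS_PREMATURE_STOP)
    protein = aa[:-1] if aa.endswith("*") else aa
    motif_span = match_stalk(protein, cfg)
    stalk = (stalk_subunit_span(protein, motif_span, cfg)
             if motif_span else None)
    if stalk is None:
        return ProteinRecord(molecule.sample_id, protein, 1, None,
                             STATUS_NO_STALK)
    return ProteinRecord(molecule.sample_id, protein, 1, stalk, STATUS_OK)


def dedup_proteins(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Collapse identical proteins of one sample, summing abundances.

    Output sorted by descending abundance, then lexicographically.
    """
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError("dedup_proteins expects records of one sample")
    if any(r.status != STATUS_OK for r in records):
        raise ValueError("dedup_proteins expects status-ok records")
    counts: Counter = Counter()
    spans: dict[str, Span] = {}
    for r in records:
        counts[r.protein] += r.abundance
        spans[r.protein] = r.stalk_span
    sample = next(iter(samples)) if samples else ""
    return [
        ProteinRecord(sample, p, counts[p], spans[p], STATUS_OK)
        for p in sorted(counts, key=lambda p: (-counts[p], p))
    ]
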