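"""Structural subunit annotation of VLRB proteins.

Annotation walks the protein N- to C-terminus: the 21-aa SP is fixed
(single germline locus); LRR1 is the first 18-residue window after the
SP whose five conserved residues (xLxLxxNxxxxLxxxxFx) match exactly;
LRR-NT is the residual region between SP and LRR1; LRRv units are tiled
in 24-aa steps from the end of LRR1 while each unit carries the four
conserved leucines of xLxxLxxLxLx at some offset, the last accepted
unit being the LRRve; the 11-aa CP follows the LRRve; the LRR-CT runs
from the CP to the stalk and contains the antigen-binding loop, bounded
by a conserved tryptophan (4 residues upstream of the core loop) and
cysteine (3 residues downstream): the core loop is [W+4, C-3] inclusive
and the extended loop W..C inclusive, seven residues longer.

Motif matching is ungapped; every sequence surviving the downstream
exact-length filters (18/24 aa units) is gap-free, so a gapped aligner
would accept the same final set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig, Span
from .orf import ProteinRecord

STATUS_ANNOTATED = "annotated"
STATUS_NO_LRR1 = "no_lrr1"
STATUS_NO_LRRV = "no_lrrv"
STATUS_NO_LOOP = "no_loop"


@dataclass
class VLRBAnnotation:
    protein: str
    sample_id: str = ""
    abundance: int = 1
    spans: dict = field(default_factory=dict)
    lrrv_count: int = 0
    status: str = STATUS_ANNOTATED

    def span(self, name: str) -> Span | None:
        return self.spans.get(name)

    @property
    def core_loop_seq(self) -> str | None:
        s = self.spans.get("core_loop")
        return self.protein[s.start:s.end] if s else None

    @property
    def extended_loop_seq(self) -> str | None:
        s = self.spans.get("extended_loop")
        return self.protein[s.start:s.end] if s else None


def detect_lrr1(protein: str, sp_end: int, cfg: PipelineConfig,
                search_end: int | None = None) -> Span | None:
    """First 18-residue window after the SP matching all 5 conserved
    residues of the LRR1 motif.  The search covers window starts from
    the SP end through the expected LRR-NT plus a safety margin."""
    w = len(cfg.lrr1_motif)
    if search_end is None:
        search_end = (sp_end + cfg.subunit_length_spec["LRR-NT"]
                      + cfg.lrr1_search_margin)
    conserved = cfg.lrr1_conserved
    for s in range(sp_end, min(search_end, len(protein) - w) + 1):
        win = protein[s:s + w]
        if all(win[i] == aa for i, aa in conserved):
            return Span(s, s + w)
    return None


def _lrrv_unit_matches(unit: str, cfg: PipelineConfig) -> bool:
    conserved = cfg.lrrv_conserved
    m = len(cfg.lrrv_motif)
    for off in range(len(unit) - m + 1):
        if all(unit[off + i] == aa for i, aa in conserved):
            return True
    return False


def detect_lrrv_units(protein: str, lrr1_end: int, stalk_start: int,
                      cfg: PipelineConfig) -> list[Span]:
    """Tile 24-aa LRRv candidates from the end of LRR1 toward the stalk.

    Tiling stops at the first unit missing the conserved leucines (or
    running into the stalk); the final accepted unit is the LRRve.
    """
    unit_len = cfg.subunit_length_spec["LRRv"]
    spans: list[Span] = []
    pos = lrr1_end
    while pos + unit_len <= stalk_start:
        unit = protein[pos:pos + unit_len]
        if not _lrrv_unit_matches(unit, cfg):
            break
        spans.append(Span(pos, pos + unit_len))
        pos += unit_len
    return spans


def detect_cp_ct_loop(protein: str, lrrve_end: int, stalk_start: int,
                      cfg: PipelineConfig
                      ) -> tuple[Span, Span, Span, Span] | None:
    """Split [lrrve_end, stalk_start) into CP + LRR-CT and find the loop.

    The anchor pair is the first tryptophan of the LRR-CT and the first
    cysteine at least 7 residues downstream of it (Wxxx-loop-xxC): the
    core loop spans [W+4, C-3] inclusive, the extended loop W..C
    inclusive.  Returns (CP, LRR-CT, core_loop, extended_loop) spans or
    None when no valid anchor pair exists.
    """
    cp_len = cfg.subunit_length_spec["CP"]
    if stalk_start - lrrve_end < cp_len + 2:
        return None
    cp = Span(lrrve_end, lrrve_end + cp_len)
    ct = Span(cp.end, stalk_start)
    region = protein[ct.start:ct.end]
    w_off = region.find("W")
    if w_off < 0:
        return None
    c_off = region.find("C", w_off + cfg.extended_loop_flank_total)
    if c_off < 0:
        return None
    w = ct.start + w_off
    c = ct.start + c_off
    core = Span(w + cfg.loop_upstream_offset,
                c - cfg.loop_downstream_offset + 1)
    extended = Span(w, c + 1)
    return cp, ct, core, extended


def annotate_protein(record: ProteinRecord | str,
                     cfg: PipelineConfig) -> VLRBAnnotation:
    """Compose the subunit detectors into a full annotation.

    Accepts a stalk-bearing :class:`ProteinRecord` (or a bare protein
    string, in which case the stalk is located first).  Annotation
    failures are statuses, never exceptions.
    """
    if isinstance(record, str):
        from .orf import match_stalk, stalk_subunit_span
        protein, sample, abundance = record, "", 1
        motif = match_stalk(protein, cfg)
        stalk = stalk_subunit_span(protein, motif, cfg) if motif else None
        if stalk is None:
            raise ValueError("protein lacks a stalk; run the stalk filter first")
    else:
        protein, sample, abundance = (record.protein, record.sample_id,
                                      record.abundance)
        stalk = record.stalk_span
        if stalk is None:
            raise ValueError("record lacks a stalk span")

    ann = VLRBAnnotation(protein=protein, sample_id=sample,
                         abundance=abundance)
    sp_len = cfg.subunit_length_spec["SP"]
    ann.spans["SP"] = Span(0, min(sp_len, len(protein)))
    ann.spans["stalk"] = stalk

    lrr1 = detect_lrr1(protein, sp_len, cfg)
    if lrr1 is None or lrr1.end > stalk.start:
        ann.status = STATUS_NO_LRR1
        return ann
    ann.spans["LRR-NT"] = Span(sp_len, lrr1.start)
    ann.spans["LRR1"] = lrr1

    lrrv = detect_lrrv_units(protein, lrr1.end, stalk.start, cfg)
    if not lrrv:
        ann.status = STATUS_NO_LRRV
        return ann
    ann.spans["LRRv"] = lrrv
    ann.lrrv_count = len(lrrv)

    loop = detect_cp_ct_loop(protein, lrrv[-1].end, stalk.start, cfg)
    if loop is None:
        ann.status = STATUS_NO_LOOP
        return ann
    cp, ct, core, extended = loop
    ann.spans["CP"] = cp
    ann.spans["LRR-CT"] = ct
    ann.spans["core_loop"] = core
    ann.spans["extended_loop"] = extended
    ann.status = STATUS_ANNOTATED
    return ann
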