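"""End-to-end orchestration with per-stage count accounting.

``run_pipeline`` chains demultiplexing, UMI collapse and neighbor
removal, translation and stalk filtering, per-sample protein dedup,
subunit annotation, the consensus length filter and the sharing
analysis, and returns the retained annotations together with a
:class:`RunReport` whose counts telescope: each stage's output count is
the next stage's input count.  Everything downstream of read input is
deterministic.
"""

from __future__ import annotations

import gzip
import json
import time
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

from . import annotate as _annotate
from . import orf as _orf
from . import preprocess as _pre
from . import repertoire as _rep
from .config import PipelineConfig
from .repertoire import FilterReport, SharingSummary


def read_sequences(path: str) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTQ/FASTA, plain or gzipped."""
    opener = gzip.open if str(path).endswith(".gz") else open
    name = str(path)[:-3] if str(path).endswith(".gz") else str(path)
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


@dataclass
class RunReport:
    """Fig-2-style stepwise accounting of the run."""

    input_reads: int = 0
    demux_rejections: dict[str, int] = field(default_factory=dict)
    demuxed_reads: int = 0
    umi_bin_discarded_reads: int = 0
    molecules_after_collapse: int = 0
    umi_neighbors_removed: int = 0
    molecules: int = 0
    premature_stop: int = 0          # step 8a
    no_stalk: int = 0                # step 8b
    ok_molecules: int = 0
    unique_proteins: int = 0
    no_lrr1: int = 0                 # step 10a
    no_lrrv: int = 0                 # step 10b
    no_loop: int = 0                 # step 11
    annotated: int = 0
    filter_report: FilterReport | None = None   # steps 12a-f
    retained: int = 0
    stage_seconds: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def check_telescoping(self) -> None:
        """Raise if any stage's output does not equal the next input."""
        assert self.demuxed_reads == (
            self.input_reads - sum(self.demux_rejections.values()))
        assert self.molecules == (
            self.molecules_after_collapse - self.umi_neighbors_removed)
        assert self.ok_molecules == (
            self.molecules - self.premature_stop - self.no_stalk)
        assert self.annotated == (
            self.unique_proteins - self.no_lrr1 - self.no_lrrv - self.no_loop)
        if self.filter_report is not None:
            assert self.filter_report.input_count == self.annotated
            assert self.retained == self.filter_report.retained

    def to_dict(self) -> dict:
        d = {
            "input_reads": self.input_reads,
            "demux_rejections": dict(self.demux_rejections),
            "demuxed_reads": self.demuxed_reads,
            "umi_bin_discarded_reads": self.umi_bin_discarded_reads,
            "molecules_after_collapse": self.molecules_after_collapse,
            "umi_neighbors_removed": self.umi_neighbors_removed,
            "molecules": self.molecules,
            "premature_stop_8a": self.premature_stop,
            "no_stalk_8b": self.no_stalk,
            "ok_molecules": self.ok_molecules,
            "unique_proteins": self.unique_proteins,
            "no_lrr1_10a": self.no_lrr1,
            "no_lrrv_10b": self.no_lrrv,
            "no_loop_11": self.no_loop,
            "annotated": self.annotated,
            "retained": self.retained,
            "stage_seconds": self.stage_seconds,
        }
        if self.filter_report is not None:
            d["consensus_filter_12"] = dict(self.filter_report.rejections)
        return d

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_pipeline(reads: Iterable[tuple[str, str]], cfg: PipelineConfig
                 ) -> tuple[list, RunReport]:
    """Run every stage on a read stream; returns (annotations, report).

    The returned annotations are the consensus-filtered records; the
    report carries the full Fig-2-style stepwise accounting.
    """
    cfg.validate()
    report = RunReport(config=cfg.to_dict())

    t0 = time.perf_counter()
    reads = list(reads)
    report.input_reads = len(reads)
    records, rejects = _pre.demultiplex(reads, cfg)
    report.demux_rejections = dict(rejects)
    report.demuxed_reads = len(records)
    report.stage_seconds["demux"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    by_sample: dict[str, list] = defaultdict(list)
    for r in records:
        by_sample[r.sample_id].append(r)
    molecules: dict[str, list] = {}
    for sample in sorted(by_sample):
        mols, discarded = _pre.collapse_umi_bins(by_sample[sample], cfg)
        report.umi_bin_discarded_reads += discarded
        report.molecules_after_collapse += len(mols)
        kept, removed = _pre.remove_umi_neighbors(mols, cfg)
        report.umi_neighbors_removed += removed
        molecules[sample] = kept
    report.molecules = sum(len(v) for v in molecules.values())
    report.stage_seconds["umi"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    unique_by_sample: dict[str, list] = {}
    for sample, mols in molecules.items():
        ok = []
        for m in mols:
            rec = _orf.translate_from_start(m, cfg)
            if rec.status == _orf.STATUS_PREMATURE_STOP:
                report.premature_stop += 1
            elif rec.status == _orf.STATUS_NO_STALK:
                report.no_stalk += 1
            else:
                ok.append(rec)
        report.ok_molecules += len(ok)
        unique_by_sample[sample] = _orf.dedup_proteins(ok) if ok else []
    report.unique_proteins = sum(len(v) for v in unique_by_sample.values())
    report.stage_seconds["orf"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    annotated = []
    for sample in sorted(unique_by_sample):
        for rec in unique_by_sample[sample]:
            ann = _annotate.annotate_protein(rec, cfg)
            if ann.status == _annotate.STATUS_NO_LRR1:
                report.no_lrr1 += 1
            elif ann.status == _annotate.STATUS_NO_LRRV:
                report.no_lrrv += 1
            elif ann.status == _annotate.STATUS_NO_LOOP:
                report.no_loop += 1
            else:
                annotated.append(ann)
    report.annotated = len(annotated)
    report.stage_seconds["annotate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    retained, freport = _rep.apply_consensus_filter(annotated, cfg)
    report.filter_report = freport
    report.retained = len(retained)
    report.stage_seconds["filter"] = time.perf_counter() - t0

    report.check_telescoping()
    return retained, report


def sharing_from_annotations(annotations: Iterable) -> SharingSummary:
    """Cross-animal sharing of retained proteins (needs >= 2 samples)."""
    per_animal: dict[str, list[str]] = defaultdict(list)
    for ann in annotations:
        per_animal[ann.sample_id].append(ann.protein)
    return _rep.shared_sequences(per_animal)
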