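"""Consensus filtering, greedy identity clustering and sharing analysis.

The consensus filter enforces the canonical subunit lengths of a mature
VLRB molecule — every LRRv 24 aa, LRR1 18 aa, LRR-NT 31 aa, stalk 87 aa,
SP 21 aa, CP 11 aa — applied sequentially in that order, so each
rejected record is charged to the first failing step.  The per-step
counts therefore depend on the order, which is preserved here.

Clustering is CD-HIT-style greedy incremental clustering: sequences are
sorted longest-first and each either joins the first existing cluster
whose representative it matches at or above the identity threshold or
founds a new cluster.  Identity is identical aligned residues divided by
the length of the shorter sequence (the CD-HIT convention).  No k-mer
pre-screen is used; at desk scale exact greedy clustering is affordable
and avoids a heuristic divergence source.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align import shorter_identity
from .annotate import STATUS_ANNOTATED, VLRBAnnotation
from .config import PipelineConfig

FILTER_STEPS = (
    "lrrv_length",    # 12a
    "lrr1_length",    # 12b
    "lrrnt_length",   # 12c
    "stalk_length",   # 12d
    "sp_length",      # 12e
    "cp_length",      # 12f
)


@dataclass
class FilterReport:
    rejections: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in FILTER_STEPS})
    retained: int = 0

    @property
    def input_count(self) -> int:
        return self.retained + sum(self.rejections.values())


def _first_failing_step(ann: VLRBAnnotation,
                        cfg: PipelineConfig) -> str | None:
    lens = cfg.subunit_length_spec
    lrrv = ann.spans.get("LRRv") or []
    if len(lrrv) < 1 or any(len(s) != lens["LRRv"] for s in lrrv):
        return "lrrv_length"
    if len(ann.spans["LRR1"]) != lens["LRR1"]:
        return "lrr1_length"
    if len(ann.spans["LRR-NT"]) != lens["LRR-NT"]:
        return "lrrnt_length"
    if len(ann.spans["stalk"]) != lens["stalk"]:
        return "stalk_length"
    if len(ann.spans["SP"]) != lens["SP"]:
        return "sp_length"
    if len(ann.spans["CP"]) != lens["CP"]:
        return "cp_length"
    return None


def apply_consensus_filter(annotations: Sequence[VLRBAnnotation],
                           cfg: PipelineConfig
                           ) -> tuple[list[VLRBAnnotation], FilterReport]:
    """Keep annotations whose subunits all have consensus lengths."""
    report = FilterReport()
    retained: list[VLRBAnnotation] = []
    for ann in annotations:
        if ann.status != STATUS_ANNOTATED:
            raise ValueError("consensus filter expects annotated records")
        step = _first_failing_step(ann, cfg)
        if step is None:
            retained.append(ann)
            report.retained += 1
        else:
            report.rejections[step] += 1
    return retained, report


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

@dataclass
class Cluster:
    representative: str
    member_ids: list[int]


@dataclass
class ClusterSet:
    threshold: float
    clusters: list[Cluster]
    n_sequences: int

    def sizes(self) -> list[int]:
        return [len(c.member_ids) for c in self.clusters]


def greedy_cluster(sequences: Sequence[str], threshold: float) -> ClusterSet:
    """CD-HIT-style greedy incremental clustering.

    Sequences are processed longest-first (ties lexicographic); each
    joins the first cluster whose representative it matches at
    ``identity >= threshold``, else founds a new cluster.  Member ids
    are indices into ``sequences``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold outside (0, 1]")
    order = sorted(range(len(sequences)),
                   key=lambda i: (-len(sequences[i]), sequences[i], i))
    clusters: list[Cluster] = []
    # identical strings always make the same join decision, so compute
    # it once per distinct string
    decision: dict[str, Cluster] = {}
    for idx in order:
        seq = sequences[idx]
        target = decision.get(seq)
        if target is None:
            for cl in clusters:
                if shorter_identity(seq, cl.representative) >= threshold:
                    target = cl
                    break
            if target is None:
                target = Cluster(representative=seq, member_ids=[])
                clusters.append(target)
            decision[seq] = target
        target.member_ids.append(idx)
    return ClusterSet(threshold=threshold, clusters=clusters,
                      n_sequences=len(sequences))


def cluster_size_cdf(cs: ClusterSet) -> list[tuple[int, float]]:
    """(rank, cumulative sequence fraction), largest clusters first."""
    if cs.n_sequences == 0:
        return []
    sizes = sorted(cs.sizes(), reverse=True)
    out = []
    cum = 0
    for rank, size in enumerate(sizes, start=1):
        cum += size
        out.append((rank, cum / cs.n_sequences))
    return out


def threshold_sweep(sequences: Sequence[str], thresholds: Sequence[float],
                    loci_count: int) -> pd.DataFrame:
    """Cluster at each threshold; report total clusters and the percent
    of sequences contained in the ``loci_count`` largest clusters."""
    rows = []
    for t in thresholds:
        cs = greedy_cluster(sequences, t)
        sizes = sorted(cs.sizes(), reverse=True)
        top = sum(sizes[:loci_count])
        pct = 100.0 * top / cs.n_sequences if cs.n_sequences else 0.0
        rows.append({"threshold": t, "n_clusters": len(sizes),
                     "pct_in_top_loci": pct})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# cross-animal sharing
# ----------------------------------------------------------------------

@dataclass
class SharingSummary:
    n_animals: int
    total_unique: int
    counts: dict[int, int]     # k -> proteins present in >= k animals
    fractions: dict[int, float]


def shared_sequences(per_animal: dict[str, Sequence[str]]
                     ) -> SharingSummary:
    """Count proteins present (100% identity) in at least k animals."""
    if len(per_animal) < 2:
        raise ValueError("sharing analysis needs at least 2 animals")
    presence: Counter = Counter()
    for proteins in per_animal.values():
        for p in set(proteins):
            presence[p] += 1
    total = len(presence)
    n = len(per_animal)
    counts = {k: sum(1 for v in presence.values() if v >= k)
              for k in range(2, n + 1)}
    fractions = {k: (counts[k] / total if total else 0.0) for k in counts}
    return SharingSummary(n_animals=n, total_unique=total,
                          counts=counts, fractions=fractions)
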