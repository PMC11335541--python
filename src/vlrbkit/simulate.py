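"""Synthetic VLRB repertoire and amplicon-read simulator.

The mature VLRB coding sequence is assembled from cassette libraries in
the fixed architecture SP - LRR-NT - LRR1 - LRRv x (k-1) - LRRve - CP -
LRR-CT - stalk, with k between 1 and 9 variable units (a single-unit
molecule carries only the LRRve).  Cassette library sizes default to the
published counts of genomic loci (SP 1, LRR-NT 79, LRR1 66, LRRv 601,
CP 29, LRR-CT 91, stalk 1).

Reads emulate the amplicon produced by a stalk-annealing RT primer
carrying a 12-nt UMI followed by PCR with barcoded forward/reverse
primers:

    TAT + barcode + [CDS + stop] + stalk-anneal + rc(UMI)
        + rc(rev-primer constant) + rc(barcode) + ATA

PCR duplicates share a UMI and carry independent substitution errors;
roughly half of the reads are emitted reverse-complemented.  A truth
table links every read to its animal, UMI and source transcript so that
each downstream stage can be verified against ground truth.

Reverse translation uses one fixed codon per amino acid (no codon-usage
model); the codons for V, D, Q and R are chosen so that the start of the
SP coding sequence reproduces the forward-primer annealing segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import AA_ALPHABET, PipelineConfig, Span

# one deterministic codon per residue; VDQVDR -> GTGGATCAAGTGGATCGC,
# the forward-primer annealing segment at the start of the SP
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGC",
    "S": "AGC", "T": "ACT", "V": "GTG", "W": "TGG", "Y": "TAT",
}
STOP_CODON = "TAA"

_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_LIBRARY_SIZES = {
    "SP": 1, "LRR-NT": 79, "LRR1": 66, "LRRv": 601,
    "CP": 29, "LRR-CT": 91, "stalk": 1,
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def reverse_translate(protein: str) -> str:
    return "".join(CODON[aa] for aa in protein)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters of the simulated experiment.

    Defaults emulate the sequenced cohort: 6 larvae, a truncated-
    geometric LRRv-count distribution on 1..9 with mean 2.2, HiFi-grade
    per-base substitution errors (1e-3), a substantial nonfunctional
    fraction (premature stops / frameshifts, as observed in circulating
    lymphocyte libraries), and a small fraction of transcripts shared
    verbatim between animals.
    """

    n_animals: int = 6
    molecules_per_animal: int = 1000
    lrrv_mean: float = 2.2
    lrrv_max: int = 9
    pcr_duplicate_lambda: float = 0.4  # reads per molecule = 1 + Poisson
    error_rate: float = 1e-3
    nonfunctional_fraction: float = 0.35
    shared_sequence_fraction: float = 0.017
    library_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIBRARY_SIZES)
    )
    core_loop_min: int = 10
    core_loop_max: int = 25

    def validate(self) -> "SimConfig":
        for name in ("error_rate", "nonfunctional_fraction",
                     "shared_sequence_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        if not (1.0 <= self.lrrv_mean <= self.lrrv_max):
            raise ValueError("lrrv_mean outside [1, lrrv_max]")
        return self


def truncated_geometric_p(mean: float, kmax: int = 9) -> float:
    """Solve for the geometric parameter giving the requested truncated mean.

    P(k) is proportional to (1-p)^(k-1) on k = 1..kmax.
    """
    ks = np.arange(1, kmax + 1)

    def trunc_mean(p: float) -> float:
        w = (1.0 - p) ** (ks - 1)
        return float((ks * w).sum() / w.sum())

    if mean <= 1.0:
        return 1.0 - 1e-12
    return brentq(lambda p: trunc_mean(p) - mean, 1e-9, 1.0 - 1e-9)


def lrrv_count_pmf(mean: float, kmax: int = 9) -> np.ndarray:
    p = truncated_geometric_p(mean, kmax)
    w = (1.0 - p) ** np.arange(kmax)
    return w / w.sum()


# ----------------------------------------------------------------------
# cassette library
# ----------------------------------------------------------------------

@dataclass
class CassetteLibrary:
    sp: list[str]
    lrrnt: list[str]
    lrr1: list[str]
    lrrv: list[str]
    cp: list[str]
    lrrct: list[str]
    stalk: list[str]

    def by_subunit(self) -> dict[str, list[str]]:
        return {
            "SP": self.sp, "LRR-NT": self.lrrnt, "LRR1": self.lrr1,
            "LRRv": self.lrrv, "CP": self.cp, "LRR-CT": self.lrrct,
            "stalk": self.stalk,
        }


def _random_peptide(rng: np.random.Generator, n: int,
                    alphabet: str = AA_ALPHABET) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _unique_peptides(rng, count, maker) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < count:
        s = maker(rng)
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


#: construction offset of the LRRv motif within each 24-aa cassette
LRRV_MOTIF_OFFSET = 2


def build_cassette_library(cfg: SimConfig, seed: int,
                           pipeline_cfg: PipelineConfig | None = None
                           ) -> CassetteLibrary:
    """Draw a cassette library satisfying all structural invariants."""
    pcfg = pipeline_cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    sizes = cfg.library_sizes
    lens = pcfg.subunit_length_spec

    def make_sp(r):
        # SP starts with the residues encoded by the primer anneal segment
        return "VDQVDR" + _random_peptide(r, lens["SP"] - 6)

    def make_lrrnt(r):
        return _random_peptide(r, lens["LRR-NT"])

    lrr1_cons = dict(pcfg.lrr1_conserved)

    def make_lrr1(r):
        s = list(_random_peptide(r, lens["LRR1"]))
        for i, aa in lrr1_cons.items():
            s[i] = aa
        return "".join(s)

    lrrv_cons = dict(pcfg.lrrv_conserved)

    def make_lrrv(r):
        s = list(_random_peptide(r, lens["LRRv"]))
        for i, aa in lrrv_cons.items():
            s[LRRV_MOTIF_OFFSET + i] = aa
        return "".join(s)

    def make_cp(r):
        return _random_peptide(r, lens["CP"])

    no_w = AA_ALPHABET.replace("W", "")
    no_wc = no_w.replace("C", "")

    def make_lrrct(r):
        # exactly one W...C anchor pair: W-free prefix, C/W-free stretch
        # between W and the anchoring C, unconstrained suffix
        prefix = _random_peptide(r, int(r.integers(2, 7)), no_w)
        core_len = int(r.integers(cfg.core_loop_min, cfg.core_loop_max + 1))
        middle = _random_peptide(r, 3 + core_len + 2, no_wc)
        suffix = _random_peptide(r, int(r.integers(3, 9)))
        return prefix + "W" + middle + "C" + suffix

    def make_stalk(r):
        off = pcfg.stalk_motif_offset
        tail = lens["stalk"] - off - len(pcfg.stalk_motif)
        return (_random_peptide(r, off) + pcfg.stalk_motif
                + _random_peptide(r, tail))

    return CassetteLibrary(
        sp=_unique_peptides(rng, sizes["SP"], make_sp),
        lrrnt=_unique_peptides(rng, sizes["LRR-NT"], make_lrrnt),
        lrr1=_unique_peptides(rng, sizes["LRR1"], make_lrr1),
        lrrv=_unique_peptides(rng, sizes["LRRv"], make_lrrv),
        cp=_unique_peptides(rng, sizes["CP"], make_cp),
        lrrct=_unique_peptides(rng, sizes["LRR-CT"], make_lrrct),
        stalk=_unique_peptides(rng, sizes["stalk"], make_stalk),
    )


# ----------------------------------------------------------------------
# transcripts
# ----------------------------------------------------------------------

@dataclass
class GroundTruthTranscript:
    transcript_id: str
    sample_id: str
    cassette_ids: dict
    lrrv_count: int
    protein: str      # intended (functional) amino-acid sequence
    nt: str           # coding sequence actually placed in the amplicon
    is_functional: bool

    def true_spans(self, cfg: PipelineConfig) -> dict:
        """Ground-truth subunit spans in protein coordinates."""
        lens = cfg.subunit_length_spec
        pos = 0
        spans: dict = {}
        for name, n in (("SP", lens["SP"]), ("LRR-NT", lens["LRR-NT"]),
                        ("LRR1", lens["LRR1"])):
            spans[name] = Span(pos, pos + n)
            pos += n
        spans["LRRv"] = []
        for _ in range(self.lrrv_count):
            spans["LRRv"].append(Span(pos, pos + lens["LRRv"]))
            pos += lens["LRRv"]
        spans["CP"] = Span(pos, pos + lens["CP"])
        pos += lens["CP"]
        ct_len = (len(self.protein) - pos - lens["stalk"])
        spans["LRR-CT"] = Span(pos, pos + ct_len)
        pos += ct_len
        spans["stalk"] = Span(pos, len(self.protein))
        return spans


def _assemble(lib: CassetteLibrary, rng: np.random.Generator,
              k: int) -> tuple[dict, str]:
    ids = {
        "SP": int(rng.integers(len(lib.sp))),
        "LRR-NT": int(rng.integers(len(lib.lrrnt))),
        "LRR1": int(rng.integers(len(lib.lrr1))),
        "LRRv": [int(i) for i in rng.integers(len(lib.lrrv), size=k)],
        "CP": int(rng.integers(len(lib.cp))),
        "LRR-CT": int(rng.integers(len(lib.lrrct))),
        "stalk": int(rng.integers(len(lib.stalk))),
    }
    protein = (
        lib.sp[ids["SP"]] + lib.lrrnt[ids["LRR-NT"]] + lib.lrr1[ids["LRR1"]]
        + "".join(lib.lrrv[i] for i in ids["LRRv"])
        + lib.cp[ids["CP"]] + lib.lrrct[ids["LRR-CT"]]
        + lib.stalk[ids["stalk"]]
    )
    return ids, protein


def _inject_nonfunctional(nt: str, rng: np.random.Generator) -> str:
    """Premature in-frame stop or a 1-nt deletion (frameshift)."""
    n_codons = len(nt) // 3
    if rng.random() < 0.5:
        c = int(rng.integers(10, max(11, n_codons - 95)))
        return nt[: 3 * c] + STOP_CODON + nt[3 * (c + 1):]
    p = int(rng.integers(30, max(31, len(nt) - 300)))
    return nt[:p] + nt[p + 1:]


def simulate_repertoire(lib: CassetteLibrary, cfg: SimConfig,
                        seed: int) -> list[GroundTruthTranscript]:
    """Assemble per-animal ground-truth transcripts (Fig-1A architecture)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    pmf = lrrv_count_pmf(cfg.lrrv_mean, cfg.lrrv_max)
    animals = [f"larva{i + 1}" for i in range(cfg.n_animals)]

    n_total = cfg.n_animals * cfg.molecules_per_animal
    n_shared = int(round(cfg.shared_sequence_fraction * n_total))

    transcripts: list[GroundTruthTranscript] = []
    serial = 0

    def new_transcript(sample: str, ids: dict, protein: str, k: int,
                       functional: bool) -> GroundTruthTranscript:
        nonlocal serial
        nt = reverse_translate(protein)
        if not functional:
            nt = _inject_nonfunctional(nt, rng)
        t = GroundTruthTranscript(
            transcript_id=f"tx{serial:07d}", sample_id=sample,
            cassette_ids=ids, lrrv_count=k, protein=protein, nt=nt,
            is_functional=functional,
        )
        serial += 1
        return t

    # shared transcripts: one assembly copied verbatim into >= 2 animals
    remaining = {a: cfg.molecules_per_animal for a in animals}
    if cfg.n_animals >= 2:
        for _ in range(n_shared):
            k = int(rng.choice(np.arange(1, cfg.lrrv_max + 1), p=pmf))
            ids, protein = _assemble(lib, rng, k)
            n_carriers = 2 + int(rng.random() < 0.2)  # mostly pairs
            n_carriers = min(n_carriers, cfg.n_animals)
            carriers = rng.choice(animals, size=n_carriers, replace=False)
            for a in carriers:
                if remaining[a] > 0:
                    transcripts.append(new_transcript(str(a), ids, protein, k, True))
                    remaining[str(a)] -= 1

    for a in animals:
        for _ in range(remaining[a]):
            k = int(rng.choice(np.arange(1, cfg.lrrv_max + 1), p=pmf))
            ids, protein = _assemble(lib, rng, k)
            functional = rng.random() >= cfg.nonfunctional_fraction
            transcripts.append(new_transcript(a, ids, protein, k, functional))

    return transcripts


# ----------------------------------------------------------------------
# reads
# ----------------------------------------------------------------------

def _add_substitutions(seq: str, rate: float,
                       rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def amplicon_sequence(transcript: GroundTruthTranscript, umi: str,
                      cfg: PipelineConfig) -> str:
    """Error-free sense-strand amplicon for one cDNA molecule."""
    bc = cfg.barcode_table[transcript.sample_id]
    body = transcript.nt + STOP_CODON
    return (
        "TAT" + bc + body
        + revcomp(cfg.rt_stalk_segment)
        + revcomp(umi)
        + revcomp(cfg.rev_constant)
        + revcomp(bc) + "ATA"
    )


def simulate_reads(transcripts: Sequence[GroundTruthTranscript],
                   cfg: SimConfig, seed: int,
                   pipeline_cfg: PipelineConfig | None = None
                   ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit (read_id, sequence) pairs plus the per-read truth table.

    Every molecule draws a random 12-nt UMI; PCR duplicates share the
    UMI and accumulate independent substitution errors; about half the
    reads are reverse-complemented.
    """
    cfg.validate()
    pcfg = pipeline_cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    bases = list("ACGT")

    reads: list[tuple[str, str]] = []
    rows = []
    for t in transcripts:
        umi = "".join(rng.choice(bases, size=pcfg.umi_length))
        template = amplicon_sequence(t, umi, pcfg)
        n_reads = 1 + int(rng.poisson(cfg.pcr_duplicate_lambda))
        for _ in range(n_reads):
            seq = _add_substitutions(template, cfg.error_rate, rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rid = f"read{len(reads):08d}"
            reads.append((rid, seq))
            rows.append((rid, t.sample_id, umi, t.transcript_id,
                         t.lrrv_count, t.is_functional))
    truth = pd.DataFrame(
        rows, columns=["read_id", "animal", "umi", "transcript_id",
                       "lrrv_count", "functional"],
    )
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path: str,
                quality: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality * len(seq)}\n")


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# ground-truth oracles for downstream verification
# ----------------------------------------------------------------------

def _lrr1_window_matches(window: str, conserved) -> bool:
    return all(window[i] == aa for i, aa in conserved)

def has_spurious_motifs(t: GroundTruthTranscript,
                        cfg: PipelineConfig) -> bool:
    """True if chance motif occurrences can shift annotation off truth.

    Checks for an LRR1 conserved-residue match upstream of the true
    LRR1, and for an LRRv-motif match in the 24-residue window
    immediately after the true LRRve (which would over-extend tiling).
    """
    lens = cfg.subunit_length_spec
    prot = t.protein
    true_lrr1 = lens["SP"] + lens["LRR-NT"]
    w = lens["LRR1"]
    cons1 = cfg.lrr1_conserved
    for s in range(lens["SP"], true_lrr1):
        if s + w <= len(prot) and _lrr1_window_matches(prot[s:s + w], cons1):
            return True
    lrrv_end = true_lrr1 + w + lens["LRRv"] * t.lrrv_count
    unit = prot[lrrv_end:lrrv_end + lens["LRRv"]]
    consv = cfg.lrrv_conserved
    if len(unit) == lens["LRRv"]:
        for off in range(lens["LRRv"] - len(cfg.lrrv_motif) + 1):
            if all(unit[off + i] == aa for i, aa in consv):
                return True
    return False


def expected_unique_proteins(transcripts: Sequence[GroundTruthTranscript],
                             truth: pd.DataFrame,
                             cfg: PipelineConfig) -> dict[str, set[str]]:
    """Truth-side recount of what the pipeline should retain.

    Replays, from the truth table alone, the UMI-bin collisions (two
    different molecules drawing the same UMI in one animal discard the
    bin) and classifies each surviving functional transcript as cleanly
    annotatable or carrying spurious motif occurrences.  Returns sets of
    protein strings keyed by 'expected' (functional, non-spurious,
    surviving preprocessing) and 'spurious' (functional but flagged).
    """
    by_id = {t.transcript_id: t for t in transcripts}
    mols = truth[["animal", "umi", "transcript_id"]].drop_duplicates()
    lost: set[tuple[str, str]] = set()
    for (animal, umi), grp in mols.groupby(["animal", "umi"]):
        txs = grp["transcript_id"].unique()
        nts = {by_id[x].nt for x in txs}
        if len(nts) > 1:  # colliding UMIs with divergent molecules
            lost.update((animal, x) for x in txs)
    expected: set[str] = set()
    spurious: set[str] = set()
    for _, row in mols.iterrows():
        t = by_id[row.transcript_id]
        if not t.is_functional:
            continue
        if (row.animal, row.transcript_id) in lost:
            continue
        if has_spurious_motifs(t, cfg):
            spurious.add(t.protein)
        else:
            expected.add(t.protein)
    return {"expected": expected - spurious, "spurious": spurious}
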