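"""Pipeline configuration and shared coordinate conventions.

All constants of the wet-lab design and of the analysis live in one
:class:`PipelineConfig`: the RT/PCR primer sequences with their embedded
6-nt sample barcodes and 12-nt UMI, the diagnostic stalk motif, the LRR1
and LRRv recognition motifs, the consensus subunit lengths, identity
thresholds, and the hydropathy split used for loop analyses.

Coordinates are 0-based half-open throughout the package; spans refer to
protein coordinates unless a record is explicitly nucleotide-level.
Motif wildcards are written ``x``; amino-acid letters are matched
case-sensitively in uppercase, nucleotides case-insensitively.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterator

import yaml

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# 5'->3' RT oligo: PCR-anneal segment, 12-nt UMI (N run), stalk-anneal segment
DEFAULT_RT_OLIGO = "TATTTCCAGCACACTGGATCAG" + "N" * 12 + "TCAACGTTTCCTGCAGAGGGCG"
DEFAULT_FWD_PRIMER = "TAT" + "N" * 6 + "gtggatcaagtggatcgc"
DEFAULT_REV_PRIMER = "TAT" + "N" * 6 + "CCAGCACACTGGATCAG"
DEFAULT_STALK_MOTIF = "DCGKPACTTLLNCANFLSCLCSTCALCRKR"
DEFAULT_LRR1_MOTIF = "xLxLxxNxxxxLxxxxFx"
DEFAULT_LRRV_MOTIF = "xLxxLxxLxLx"

#: consensus subunit lengths (aa) enforced by the erroneous-sequence filter
DEFAULT_SUBUNIT_LENGTHS = {
    "SP": 21,
    "LRR-NT": 31,
    "LRR1": 18,
    "LRRv": 24,
    "CP": 11,
    "stalk": 87,
}

DEFAULT_BARCODES = {
    "larva1": "AACCTG",
    "larva2": "CCTAGA",
    "larva3": "GGATCC",
    "larva4": "TTGACA",
    "larva5": "ACGTAC",
    "larva6": "CAGTGT",
}


class ConfigError(ValueError):
    """Raised when a :class:`PipelineConfig` violates an invariant."""


@dataclass(frozen=True, order=True)
class Span:
    """0-based half-open interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __iter__(self) -> Iterator[int]:
        return iter((self.start, self.end))


def conserved_positions(motif: str) -> list[tuple[int, str]]:
    """Return ``(index, residue)`` for every non-wildcard motif position.

    The LRR1 motif ``xLxLxxNxxxxLxxxxFx`` has five conserved residues,
    the LRRv motif ``xLxxLxxLxLx`` four conserved leucines.
    """
    out = []
    for i, ch in enumerate(motif):
        if ch == "x":
            continue
        if ch not in AA_ALPHABET:
            raise ValueError(f"illegal motif character {ch!r} at position {i}")
        out.append((i, ch))
    return out


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with the published defaults."""

    rt_oligo: str = DEFAULT_RT_OLIGO
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER
    barcode_table: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BARCODES)
    )
    umi_length: int = 12
    umi_collapse_identity: float = 0.99
    umi_neighbor_distance: int = 1
    stalk_motif: str = DEFAULT_STALK_MOTIF
    stalk_max_mismatch: int = 2
    #: offset of the diagnostic motif within the 87-aa stalk subunit
    stalk_motif_offset: int = 50
    lrr1_motif: str = DEFAULT_LRR1_MOTIF
    lrrv_motif: str = DEFAULT_LRRV_MOTIF
    lrrv_min_segment: int = 15
    lrr1_search_margin: int = 20
    subunit_length_spec: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBUNIT_LENGTHS)
    )
    loop_upstream_offset: int = 4
    loop_downstream_offset: int = 3
    extended_loop_flank_total: int = 7
    hydropathy_split: float = 0.35
    clustering_thresholds: list[float] = field(
        default_factory=lambda: [0.65, 0.70, 0.75, 0.85, 0.95, 1.00]
    )

    # ------------------------------------------------------------------
    # derived fields, cached by validate()
    # ------------------------------------------------------------------

    @property
    def umi_span(self) -> Span:
        """Position of the N-run (UMI) inside the RT oligo."""
        m = re.search(r"N+", self.rt_oligo)
        if m is None:
            raise ConfigError("rt_oligo contains no UMI (N run)")
        return Span(m.start(), m.end())

    @property
    def rt_pcr_segment(self) -> str:
        """5' part of the RT oligo: annealing site of the reverse PCR primer."""
        return self.rt_oligo[: self.umi_span.start].upper()

    @property
    def rt_stalk_segment(self) -> str:
        """3' part of the RT oligo: anneals inside the invariant stalk region."""
        return self.rt_oligo[self.umi_span.end :].upper()

    @property
    def fwd_constant(self) -> str:
        """Transcript-annealing segment of the forward primer (SP coding)."""
        return self.fwd_primer[3 + 6 :].upper()

    @property
    def rev_constant(self) -> str:
        """RT-oligo-annealing segment of the reverse primer."""
        return self.rev_primer[3 + 6 :].upper()

    @property
    def lrr1_conserved(self) -> list[tuple[int, str]]:
        return conserved_positions(self.lrr1_motif)

    @property
    def lrrv_conserved(self) -> list[tuple[int, str]]:
        return conserved_positions(self.lrrv_motif)

    # ------------------------------------------------------------------

    def validate(self) -> "PipelineConfig":
        """Check every invariant; return self if all hold.

        Raises :class:`ConfigError` naming the first violated invariant.
        """
        umi = self.umi_span  # raises if no N run
        if len(umi) != self.umi_length:
            raise ConfigError(
                f"umi_length != N-run length ({self.umi_length} vs {len(umi)})"
            )
        seen: dict[str, str] = {}
        for sample, bc in self.barcode_table.items():
            if len(bc) != 6:
                raise ConfigError("barcode length != 6")
            if bc in seen:
                raise ConfigError(f"duplicate barcode {bc} ({seen[bc]}, {sample})")
            seen[bc] = sample
        for ch in self.stalk_motif:
            if ch not in AA_ALPHABET:
                raise ConfigError(f"stalk_motif has non-canonical residue {ch!r}")
        conserved_positions(self.lrr1_motif)
        conserved_positions(self.lrrv_motif)
        if (
            self.extended_loop_flank_total
            != self.loop_upstream_offset + self.loop_downstream_offset
        ):
            raise ConfigError(
                "extended_loop_flank_total != loop_upstream_offset + loop_downstream_offset"
            )
        for name, val in [
            ("umi_collapse_identity", self.umi_collapse_identity),
            ("hydropathy thresholds", 1.0),
        ]:
            if not (0.0 < val <= 1.0):
                raise ConfigError(f"{name} outside (0, 1]")
        for t in self.clustering_thresholds:
            if not (0.0 < t <= 1.0):
                raise ConfigError(f"clustering threshold {t} outside (0, 1]")
        for name, length in self.subunit_length_spec.items():
            if length <= 0:
                raise ConfigError(f"subunit length {name} not positive")
        if self.umi_length <= 0:
            raise ConfigError("umi_length not positive")
        if not (
            0
            <= self.stalk_motif_offset
            <= self.subunit_length_spec["stalk"] - len(self.stalk_motif)
        ):
            raise ConfigError("stalk_motif_offset places motif outside the stalk")
        return self

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(cfg: PipelineConfig) -> PipelineConfig:
    """Functional alias for :meth:`PipelineConfig.validate`."""
    return cfg.validate()
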