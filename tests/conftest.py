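"""Shared fixtures: default config and hand-built canonical proteins.

The hand-built protein uses alanine-rich cassettes whose only motif
occurrences are the intended ones, so expected subunit boundaries are
known exactly by construction.
"""

from __future__ import annotations

import pytest

from vlrbkit.config import PipelineConfig

# canonical hand-built cassettes (lengths 21/31/18/24/11/var/87)
SP = "VDQVDR" + "A" * 15
LRRNT = "A" * 31                       # no L/N/F: no spurious LRR1 window
LRR1 = "ALALAANAAAALAAAAFA"            # the LRR1 motif with x = A
LRRV = "AA" + "ALAALAALALA" + "A" * 11   # motif at offset 2, 24 aa


def make_lrrct(core_len: int = 15, prefix: str = "GG",
               suffix: str = "GGGG") -> str:
    """LRR-CT with one W...C anchor: W xxx core xx C (no L: never tiles)."""
    return prefix + "W" + "AAA" + "S" * core_len + "GG" + "C" + suffix


def make_protein(cfg: PipelineConfig, k: int = 2, core_len: int = 15,
                 lrrnt: str = LRRNT, cp: str = "A" * 11,
                 lrrct: str | None = None) -> str:
    stalk = "A" * cfg.stalk_motif_offset + cfg.stalk_motif + "A" * (
        cfg.subunit_length_spec["stalk"] - cfg.stalk_motif_offset
        - len(cfg.stalk_motif))
    ct = lrrct if lrrct is not None else make_lrrct(core_len)
    return SP + lrrnt + LRR1 + LRRV * k + cp + ct + stalk


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig().validate()
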