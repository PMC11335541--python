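"""Pairwise identity primitives shared by UMI collapse and clustering.

Two identity conventions are used downstream and both are defined here:

``alignment_identity``
    identical columns / alignment length, from a global (Needleman-
    Wunsch) alignment.  Used for the >= 99% within-UMI collapse.
``shorter_identity``
    identical columns / length of the shorter sequence — the CD-HIT
    convention.  Used for greedy repertoire clustering.

Alignments come from edlib's minimum-edit-distance global mode; for
equal-length pairs a Hamming computation is equivalent in practice and
much faster, so it is used as a shortcut.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def _cigar_stats(a: str, b: str) -> tuple[int, int]:
    """(matches, alignment_length) of a global min-edit alignment."""
    res = edlib.align(a, b, mode="NW", task="path")
    matches = 0
    length = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        length += n
        if op == "=":
            matches += n
    return matches, length


def alignment_identity(a: str, b: str) -> float:
    """Identical columns / alignment length (global alignment)."""
    if not a or not b:
        return 0.0
    if len(a) == len(b):
        m = len(a) - hamming(a, b)
        return m / len(a)
    matches, length = _cigar_stats(a, b)
    return matches / length


def shorter_identity(a: str, b: str) -> float:
    """Identical columns / shorter sequence length (CD-HIT convention)."""
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    if len(a) == len(b):
        matches = len(a) - hamming(a, b)
    else:
        matches, _ = _cigar_stats(a, b)
    return matches / min(len(a), len(b))
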