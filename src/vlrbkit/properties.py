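"""Amino-acid property analytics over annotated repertoires.

Hydropathy uses the Kyte-Doolittle scale (GRAVY = mean per-residue
value) and polarity the Grantham scale; both ship as TSV data files and
can be overridden.  Loop hydropathy is bimodal in real repertoires and
is split into high/low groups at a fixed threshold (default 0.35),
computed on the extended loop.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import VLRBAnnotation


def _load_scale(filename: str) -> dict[str, float]:
    ref = resources.files("vlrbkit").joinpath("data", filename)
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["residue"], df["value"].astype(float)))


KYTE_DOOLITTLE: dict[str, float] = _load_scale("hydropathy_kyte_doolittle.tsv")
GRANTHAM_POLARITY: dict[str, float] = _load_scale("polarity_grantham.tsv")


def _mean_score(peptide: str, scale: dict[str, float]) -> float:
    if not peptide:
        raise ValueError("empty peptide")
    try:
        return sum(scale[aa] for aa in peptide) / len(peptide)
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def gravy(peptide: str, scale: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy (Kyte-Doolittle mean)."""
    return _mean_score(peptide, scale or KYTE_DOOLITTLE)


def polarity(peptide: str, scale: dict[str, float] | None = None) -> float:
    """Mean Grantham polarity."""
    return _mean_score(peptide, scale or GRANTHAM_POLARITY)


# ----------------------------------------------------------------------
# positional statistics
# ----------------------------------------------------------------------

def positional_subunit_stats(annotations: Sequence[VLRBAnnotation]
                             ) -> pd.DataFrame:
    """Mean +/- SD of hydropathy and polarity per LRRv ordinal position.

    Units are grouped by position (1st, 2nd, ...); the final unit of
    every molecule is the LRRve and is reported as its own group, so a
    single-unit molecule contributes only to the LRRve group.  SD is the
    sample standard deviation (n-1 denominator).
    """
    groups: dict[str, list[str]] = {}
    for ann in annotations:
        units = ann.spans.get("LRRv") or []
        for i, sp in enumerate(units):
            label = "LRRve" if i == len(units) - 1 else f"LRRv{i + 1}"
            groups.setdefault(label, []).append(ann.protein[sp.start:sp.end])
    rows = []
    for label in sorted(groups, key=lambda x: (x == "LRRve", x)):
        seqs = groups[label]
        h = np.array([gravy(s) for s in seqs])
        p = np.array([polarity(s) for s in seqs])
        rows.append({
            "group": label, "n": len(seqs),
            "hydropathy_mean": h.mean(),
            "hydropathy_sd": h.std(ddof=1) if len(h) > 1 else 0.0,
            "polarity_mean": p.mean(),
            "polarity_sd": p.std(ddof=1) if len(p) > 1 else 0.0,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# loop hydropathy split
# ----------------------------------------------------------------------

@dataclass
class LoopGroup:
    label: str                # "high" or "low"
    loops: list[str]
    threshold: float


def split_loops_by_hydropathy(loops: Iterable[str],
                              threshold: float = 0.35
                              ) -> tuple[LoopGroup, LoopGroup]:
    """Partition loop sequences at gravy >= threshold (high) / < (low)."""
    high, low = [], []
    for s in loops:
        (high if gravy(s) >= threshold else low).append(s)
    return (LoopGroup("high", high, threshold),
            LoopGroup("low", low, threshold))


# ----------------------------------------------------------------------
# frequency matrices and length distributions
# ----------------------------------------------------------------------

def frequency_matrix(sequences: Sequence[str]) -> pd.DataFrame:
    """Column-stochastic position x residue frequency matrix.

    All sequences must share one length (e.g. 24-aa LRRv units); each
    row (position) sums to 1.
    """
    if not sequences:
        raise ValueError("no sequences")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences differ in length")
    residues = sorted({aa for s in sequences for aa in s})
    mat = np.zeros((L, len(residues)))
    col = {aa: j for j, aa in enumerate(residues)}
    for s in sequences:
        for i, aa in enumerate(s):
            mat[i, col[aa]] += 1
    mat /= len(sequences)
    return pd.DataFrame(mat, columns=residues,
                        index=pd.RangeIndex(L, name="position"))


def majority_residues(freq: pd.DataFrame) -> list[str]:
    """Per-position majority residue of a frequency matrix."""
    return list(freq.idxmax(axis=1))


@dataclass
class LengthDistributions:
    protein_length: Counter
    lrrv_count: Counter
    core_loop_length: Counter
    protein_length_mean: float
    protein_length_sd: float
    core_loop_mean: float
    core_loop_sd: float
    lattice_spacing: int
    lattice_fraction: float   # mass on the modal length class mod spacing


def length_distributions(annotations: Sequence[VLRBAnnotation],
                         lattice_spacing: int = 24) -> LengthDistributions:
    """Histograms of protein length, LRRv count and core-loop length.

    Mature VLRB lengths fall on a lattice of ~24-aa spacing (one LRRv
    cassette); the reported lattice fraction is the histogram mass on
    the modal residue class modulo the spacing.
    """
    plens = [len(a.protein) for a in annotations]
    kcounts = [a.lrrv_count for a in annotations]
    clens = [len(a.span("core_loop")) for a in annotations
             if a.span("core_loop") is not None]

    def _stats(xs):
        if not xs:
            return 0.0, 0.0
        arr = np.asarray(xs, dtype=float)
        return float(arr.mean()), (float(arr.std(ddof=1))
                                   if len(arr) > 1 else 0.0)

    pmean, psd = _stats(plens)
    cmean, csd = _stats(clens)
    if plens:
        classes = Counter(x % lattice_spacing for x in plens)
        lattice_fraction = max(classes.values()) / len(plens)
    else:
        lattice_fraction = 0.0
    return LengthDistributions(
        protein_length=Counter(plens), lrrv_count=Counter(kcounts),
        core_loop_length=Counter(clens),
        protein_length_mean=pmean, protein_length_sd=psd,
        core_loop_mean=cmean, core_loop_sd=csd,
        lattice_spacing=lattice_spacing, lattice_fraction=lattice_fraction,
    )
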