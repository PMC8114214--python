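"""Consensus binding motifs and residue-usage statistics.

Position frequency matrices (PFMs) over unique peptides of a fixed
length, consensus classification of per-position residue preferences
(dominant > 30%, strong 20-30%, moderate 10-20%), single-position
residue frequencies (e.g. leucine at p3), and small-versus-bulky
amino-acid usage by peptide length.

Positions are numbered p1..pL from the N terminus; p-omega denotes the
C-terminal position of each peptide regardless of its length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, PeptideRecord

#: Small residues (Figure-style usage analysis): Ala, Asp, Gly, Asn, Pro, Ser.
SMALL_RESIDUES = frozenset("ADGNPS")
#: Bulky residues: Phe, His, Lys, Arg, Tyr.
BULKY_RESIDUES = frozenset("FHKRY")

#: Consensus class boundaries on per-position frequency. Dominant is
#: strictly > 0.30; strong is (0.20, 0.30]; moderate is (0.10, 0.20];
#: anything at or below 0.10 is omitted from the consensus.
DOMINANT_THRESHOLD = 0.30
STRONG_THRESHOLD = 0.20
MODERATE_THRESHOLD = 0.10


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position amino-acid frequencies for peptides of one length.

    ``freqs`` is an L x 20 DataFrame (index ``p1``..``pL``, columns the 20
    standard residues); rows sum to 1. Built only from unique sequences of
    exactly the stated length.
    """

    length: int
    freqs: pd.DataFrame
    n_peptides: int
    cell_line: str = ""

    def frequency(self, position: int, residue: str) -> float:
        return float(self.freqs.at[f"p{position}", residue])


def _unique_of_length(
    records: Iterable[PeptideRecord], length: int, cell_line: str | None
) -> list[str]:
    return sorted(
        {
            r.sequence
            for r in records
            if r.length == length and (cell_line is None or r.cell_line == cell_line)
        }
    )


def build_pfm(
    records: Iterable[PeptideRecord],
    length: int,
    cell_line: str | None = None,
) -> PositionFrequencyMatrix:
    """Position frequency matrix from unique sequences of one length.

    Frequencies are simple counts over unique peptides (pooled across
    replicates), count / n_peptides at each position. Raises when no
    peptide of the requested length exists.
    """
    seqs = _unique_of_length(records, length, cell_line)
    if not seqs:
        raise ValueError(
            f"no unique peptides of length {length}"
            + (f" in cell line {cell_line!r}" if cell_line else "")
        )
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((length, 20), dtype=float)
    for s in seqs:
        for pos, res in enumerate(s):
            counts[pos, aa_index[res]] += 1
    freqs = pd.DataFrame(
        counts / len(seqs),
        index=[f"p{i}" for i in range(1, length + 1)],
        columns=list(AMINO_ACIDS),
    )
    return PositionFrequencyMatrix(length, freqs, len(seqs), cell_line or "")


def classify_frequency(f: float) -> str | None:
    """Consensus class for one per-position residue frequency.

    Returns ``"dominant"`` (> 0.30), ``"strong"`` ((0.20, 0.30]),
    ``"moderate"`` ((0.10, 0.20]) or ``None`` (omitted, <= 0.10).
    """
    if f > DOMINANT_THRESHOLD:
        return "dominant"
    if f > STRONG_THRESHOLD:
        return "strong"
    if f > MODERATE_THRESHOLD:
        return "moderate"
    return None


@dataclass(frozen=True)
class ConsensusMotif:
    """Per-position classified residue preferences.

    ``positions`` maps ``p1``..``pL`` to lists of (residue, frequency,
    class) tuples, ordered by descending frequency with alphabetical
    tie-break; residues at or below the moderate threshold are omitted.
    """

    length: int
    cell_line: str
    positions: Mapping[str, tuple[tuple[str, float, str], ...]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": pos, "residue": res, "frequency": f, "class": cls}
            for pos, entries in self.positions.items()
            for res, f, cls in entries
        ]
        return pd.DataFrame(rows, columns=["position", "residue", "frequency", "class"])


def classify_consensus(pfm: PositionFrequencyMatrix) -> ConsensusMotif:
    """Classify a PFM into its consensus motif (dominant/strong/moderate)."""
    positions: dict[str, tuple[tuple[str, float, str], ...]] = {}
    for pos in pfm.freqs.index:
        entries = []
        for res in AMINO_ACIDS:
            f = float(pfm.freqs.at[pos, res])
            cls = classify_frequency(f)
            if cls is not None:
                entries.append((res, f, cls))
        entries.sort(key=lambda e: (-e[1], e[0]))
        positions[pos] = tuple(entries)
    return ConsensusMotif(pfm.length, pfm.cell_line, positions)


def position_residue_frequency(
    records: Iterable[PeptideRecord],
    length: int,
    position: int,
    residue: str,
    cell_line: str | None = None,
) -> float:
    """Fraction of unique length-L peptides carrying ``residue`` at
    1-based ``position`` (e.g. leucine at p3 of 9mers)."""
    if not (1 <= position <= length):
        raise ValueError(f"position {position} out of range for length {length}")
    seqs = _unique_of_length(records, length, cell_line)
    if not seqs:
        raise ValueError(f"no unique peptides of length {length}")
    return sum(1 for s in seqs if s[position - 1] == residue) / len(seqs)


def small_bulky_usage(
    records: Iterable[PeptideRecord],
    min_len: int = 7,
    max_len: int = 15,
    per_replicate: bool = True,
) -> pd.DataFrame:
    """Small and bulky amino-acid usage fractions per peptide length.

    For each length, the fraction of residue occurrences (pooled over the
    unique peptides of that length) belonging to the small set
    {A, D, G, N, P, S} and the bulky set {F, H, K, R, Y}; the remaining
    nine residues contribute to neither fraction. With ``per_replicate``,
    fractions are computed within each replicate's unique set and the mean
    and SEM across replicates are added.
    """
    records = list(records)
    rows = []
    cell_lines = sorted({r.cell_line for r in records})
    for line in cell_lines:
        line_recs = [r for r in records if r.cell_line == line]
        reps = sorted({r.replicate for r in line_recs})
        for L in range(min_len, max_len + 1):
            uniq = {r.sequence for r in line_recs if r.length == L}
            pooled = "".join(sorted(uniq))
            n_res = len(pooled)
            row = {
                "cell_line": line,
                "length": L,
                "n_unique": len(uniq),
                "small_fraction": (
                    sum(1 for c in pooled if c in SMALL_RESIDUES) / n_res
                    if n_res
                    else np.nan
                ),
                "bulky_fraction": (
                    sum(1 for c in pooled if c in BULKY_RESIDUES) / n_res
                    if n_res
                    else np.nan
                ),
            }
            if per_replicate:
                small_by_rep, bulky_by_rep = [], []
                for rep in reps:
                    rep_pool = "".join(
                        sorted(
                            {
                                r.sequence
                                for r in line_recs
                                if r.length == L and r.replicate == rep
                            }
                        )
                    )
                    if rep_pool:
                        small_by_rep.append(
                            sum(1 for c in rep_pool if c in SMALL_RESIDUES)
                            / len(rep_pool)
                        )
                        bulky_by_rep.append(
                            sum(1 for c in rep_pool if c in BULKY_RESIDUES)
                            / len(rep_pool)
                        )
                for label, vals in (
                    ("small", small_by_rep),
                    ("bulky", bulky_by_rep),
                ):
                    arr = np.asarray(vals)
                    row[f"{label}_mean"] = arr.mean() if arr.size else np.nan
                    row[f"{label}_sem"] = (
                        arr.std(ddof=1) / math.sqrt(arr.size)
                        if arr.size > 1
                        else np.nan
                    )
            rows.append(row)
    return pd.DataFrame(rows)
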