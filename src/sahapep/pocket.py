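"""Pocket-level MHC-I homology scoring and motif transfer.

The peptide-binding groove of an MHC class I molecule anchors the
peptide's p2 residue in its B pocket and the C-terminal (p-omega)
residue in its F pocket. When no binding data exist for an allele, its
pocket preferences can be inferred by comparing the residues lining each
pocket with those of well-characterised alleles: a query allele is
scored against a database of aligned MHC-I sequences using a 20x20
amino-acid similarity matrix, summed over the pocket positions and
weighted by each position's probability of contacting the peptide
binding region. Hits scoring at least a fixed fraction (default 0.93) of
the query's self-score are considered homologous, and the known binding
motifs of the top matches are transferred to the query.

Pocket positions are given in the 1-based ungapped numbering of a
designated reference allele (classically HLA-A*02:01) and located in any
sequence through a multiple alignment containing that reference. The B
pocket uses positions 7, 9, 24, 34, 45, 63, 66, 67, 70, 99; the F pocket
uses 77, 80, 81, 84, 94, 115, 122, 142, 145, 146 plus the residues
adjacent to them (+/- 1 in reference numbering).
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import (
    AlleleSequence,
    ConfigurationError,
    ContactWeights,
    SimilarityMatrix,
)

GAP = "-"

#: Reference-numbered residue positions lining the B pocket (binds p2).
B_POCKET_POSITIONS: tuple[int, ...] = (7, 9, 24, 34, 45, 63, 66, 67, 70, 99)
#: Reference-numbered residue positions lining the F pocket (binds p-omega).
F_POCKET_POSITIONS: tuple[int, ...] = (77, 80, 81, 84, 94, 115, 122, 142, 145, 146)

DEFAULT_CUTOFF = 0.93


@dataclass(frozen=True)
class PocketModel:
    """A named binding pocket with its scoring configuration.

    ``include_adjacent`` expands the position set by ``adjacent_radius``
    in reference numbering (the F pocket default), accommodating minor
    shifts of pocket sites between alleles. ``weights`` are per-position
    contact probabilities; a uniform default is used when none is given.
    """

    name: str
    positions: tuple[int, ...]
    matrix: SimilarityMatrix
    include_adjacent: bool = False
    adjacent_radius: int = 1
    weights: ContactWeights | None = None

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.positions):
            raise ConfigurationError("pocket positions must be >= 1")
        if list(self.positions) != sorted(set(self.positions)):
            raise ConfigurationError("pocket positions must be strictly increasing")

    def expanded_positions(self, max_position: int | None = None) -> tuple[int, ...]:
        """Position set after adjacency expansion, clipped to bounds."""
        if not self.include_adjacent:
            pos = set(self.positions)
        else:
            pos = set()
            for p in self.positions:
                for q in range(p - self.adjacent_radius, p + self.adjacent_radius + 1):
                    if q >= 1:
                        pos.add(q)
        if max_position is not None:
            pos = {p for p in pos if p <= max_position}
        return tuple(sorted(pos))

    def weight(self, position: int) -> float:
        if self.weights is None:
            return 1.0
        return self.weights[position]

    @classmethod
    def b_pocket(
        cls, matrix: SimilarityMatrix, weights: ContactWeights | None = None
    ) -> "PocketModel":
        return cls("B", B_POCKET_POSITIONS, matrix, include_adjacent=False, weights=weights)

    @classmethod
    def f_pocket(
        cls,
        matrix: SimilarityMatrix,
        weights: ContactWeights | None = None,
        adjacent_radius: int = 1,
    ) -> "PocketModel":
        return cls(
            "F",
            F_POCKET_POSITIONS,
            matrix,
            include_adjacent=True,
            adjacent_radius=adjacent_radius,
            weights=weights,
        )


@dataclass(frozen=True)
class PocketMatch:
    """One query-versus-subject pocket comparison."""

    query: str
    subject: str
    pocket: str
    score: float
    max_score: float
    cutoff_fraction: float = DEFAULT_CUTOFF

    @property
    def relative_score(self) -> float:
        return self.score / self.max_score

    @property
    def passes(self) -> bool:
        # >= rule, with a relative tolerance so a score sitting exactly on
        # the cutoff is not rejected by binary rounding of the product
        threshold = self.cutoff_fraction * self.max_score
        return self.score >= threshold - 1e-9 * max(1.0, abs(threshold))


@dataclass(frozen=True)
class PocketMotifReport:
    """Ranked passing matches for one query pocket, with transferred motifs.

    ``matches`` holds all subjects passing the cutoff, ranked by
    descending relative score (ties broken by subject name);
    ``transferred_motifs`` pairs the top-k annotated subjects with their
    known pocket motifs. ``no_prediction`` is True when no subject passes.
    """

    query: str
    pocket: str
    matches: tuple[PocketMatch, ...]
    transferred_motifs: tuple[tuple[str, str], ...] = ()

    @property
    def no_prediction(self) -> bool:
        return not self.matches


# ---------------------------------------------------------------------------
# Reference-coordinate mapping
# ---------------------------------------------------------------------------

def map_reference_positions(
    alignment: Mapping[str, str],
    reference: str,
    positions: Sequence[int],
) -> dict[str, list[str]]:
    """Locate reference-numbered positions in every aligned sequence.

    ``alignment`` maps sequence names to equal-length aligned strings
    (gaps as ``-``) and must contain ``reference``. Each 1-based position
    into the ungapped reference is mapped to its alignment column via the
    reference row; the residue (or ``-``) of every sequence in that
    column is returned, keyed by name, in the order of ``positions``.
    """
    if reference not in alignment:
        raise ConfigurationError(f"reference {reference!r} absent from alignment")
    ref_row = alignment[reference]
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ConfigurationError("aligned sequences have unequal lengths")
    # ungapped reference coordinate -> alignment column
    col_of: dict[int, int] = {}
    res_i = 0
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            res_i += 1
            col_of[res_i] = col
    columns = []
    for p in positions:
        if p not in col_of:
            raise ConfigurationError(
                f"position {p} beyond the reference's ungapped length ({res_i})"
            )
        columns.append(col_of[p])
    return {name: [row[c] for c in columns] for name, row in alignment.items()}


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def pocket_score(
    query_residues: Sequence[str],
    subject_residues: Sequence[str],
    model: PocketModel,
    positions: Sequence[int] | None = None,
    *,
    query: str = "query",
    subject: str = "subject",
    cutoff_fraction: float = DEFAULT_CUTOFF,
) -> PocketMatch:
    """Contact-weighted similarity score of a subject against a query pocket.

    score = sum over pocket positions p of w(p) * M[query(p)][subject(p)],
    where M is the similarity matrix and w the contact weight. The
    maximum score is the query's self-score, sum of w(p) * M[q][q]. A gap
    at a position contributes the matrix's global minimum (weighted), so
    missing pocket residues penalise rather than inflate the relative
    score. ``passes`` applies ``score >= cutoff_fraction * max_score``.
    """
    if positions is None:
        positions = model.expanded_positions()
    if len(query_residues) != len(positions) or len(subject_residues) != len(positions):
        raise ValueError("residue vectors must align with the position list")
    m = model.matrix
    gap_value = m.min_value
    score = 0.0
    max_score = 0.0
    for p, q_res, s_res in zip(positions, query_residues, subject_residues):
        w = model.weight(p)
        if q_res == GAP or s_res == GAP:
            score += w * gap_value
        else:
            score += w * m[q_res, s_res]
        max_score += w * (gap_value if q_res == GAP else m[q_res, q_res])
    if max_score <= 0:
        raise ValueError(
            f"degenerate query self-score {max_score}; the similarity matrix "
            "must score identities positively at these positions"
        )
    return PocketMatch(query, subject, model.name, score, max_score, cutoff_fraction)


def scan_database(
    query: AlleleSequence,
    db: Sequence[AlleleSequence],
    model: PocketModel,
    reference: AlleleSequence,
    k: int = 3,
    *,
    cutoff_fraction: float = DEFAULT_CUTOFF,
    alignment: Mapping[str, str] | None = None,
    motif_table: Mapping[str, str] | None = None,
) -> PocketMotifReport:
    """Rank a database of alleles by pocket homology to a query.

    When no ``alignment`` is supplied, all sequences must already share
    the reference's length (pre-aligned, gap-free); otherwise the mapping
    from name to aligned string must cover the reference, the query and
    every database entry. ``motif_table`` maps subject allele names to
    known pocket-motif strings; the motifs of the top-``k`` passing,
    annotated subjects are transferred. An empty match list means no
    prediction is possible for this query pocket.
    """
    if not db:
        raise ValueError("empty database")
    if alignment is None:
        ref_len = len(reference.sequence)
        entries = {reference.name: reference.sequence, query.name: query.sequence}
        for a in db:
            entries[a.name] = a.sequence
        if any(len(s) != ref_len for s in entries.values()):
            raise ConfigurationError(
                "sequences differ in length; supply a precomputed alignment"
            )
        alignment = entries
    else:
        needed = {reference.name, query.name, *(a.name for a in db)}
        missing = needed - set(alignment)
        if missing:
            raise ConfigurationError(f"alignment missing sequences: {sorted(missing)}")

    positions = model.expanded_positions(
        max_position=len(alignment[reference.name].replace(GAP, ""))
    )
    mapped = map_reference_positions(alignment, reference.name, positions)
    q_res = mapped[query.name]
    matches = []
    for a in db:
        match = pocket_score(
            q_res,
            mapped[a.name],
            model,
            positions,
            query=query.name,
            subject=a.name,
            cutoff_fraction=cutoff_fraction,
        )
        if match.passes:
            matches.append(match)
    matches.sort(key=lambda m: (-m.relative_score, m.subject))
    transferred = []
    if motif_table:
        for m in matches:
            if m.subject in motif_table:
                transferred.append((m.subject, motif_table[m.subject]))
            if len(transferred) == k:
                break
    return PocketMotifReport(query.name, model.name, tuple(matches), tuple(transferred))


# ---------------------------------------------------------------------------
# Alignment helpers
# ---------------------------------------------------------------------------

def pairwise_align_to_reference(
    sequence: str, reference: str
) -> tuple[str, str]:
    """Global pairwise alignment of a sequence against the reference.

    Needleman-Wunsch with BLOSUM62 and affine gap penalties (open 10,
    extend 1); intended for toy and synthetic inputs where a full
    multiple alignment is unnecessary. Returns (aligned_sequence,
    aligned_reference).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(sequence, reference)[0]
    return str(aln[0]), str(aln[1])


def align_with_mafft(sequences: Mapping[str, str]) -> dict[str, str]:
    """Multiple sequence alignment through an external ``mafft`` binary.

    Writes the sequences to a temporary FASTA, runs ``mafft --auto`` and
    returns the aligned rows keyed by name. Requires mafft on PATH.
    """
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with fasta.open("w") as fh:
            for name, seq in sequences.items():
                fh.write(f">{name}\n{seq}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line.strip().upper()
    return out
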