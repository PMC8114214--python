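"""MHC-I allotype assignment and label-free quantification.

Peptides from digested alpha-chain fractions are assigned to allotype
groups by exact substring matching against the allele sequences (the
enzymatic fragments of an intact alpha chain are exact subsequences of
it). A peptide matching more than one group is ambiguous and excluded
from quantification; per replicate, each group's intensity is the sum of
its assigned peptide intensities divided by the replicate's total
peptide intensity, and a group is retained only when detected in at
least ``presence_threshold`` replicates (default 3 of 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import AlleleSequence, PeptideRecord


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of mapping peptide sequences onto allotype groups.

    ``assigned`` maps each uniquely-assigned sequence to its single group;
    ``ambiguous`` maps sequences hitting more than one group to the full
    set of groups they hit; ``unmatched`` lists sequences found in no
    allele.
    """

    assigned: Mapping[str, str]
    ambiguous: Mapping[str, frozenset[str]]
    unmatched: frozenset[str]

    def groups_for(self, sequence: str) -> frozenset[str]:
        if sequence in self.assigned:
            return frozenset({self.assigned[sequence]})
        return self.ambiguous.get(sequence, frozenset())


def assign_peptides_to_alleles(
    peptides: Iterable[str] | Iterable[PeptideRecord],
    alleles: Sequence[AlleleSequence],
) -> AssignmentResult:
    """Assign peptide sequences to allotype groups by exact substring match.

    A peptide maps to a group iff its sequence occurs verbatim in any
    allele sequence of that group, so alleles collapsed into one group
    (e.g. two alleles one substitution apart) never make a peptide
    ambiguous. Matching >1 group flags the peptide ambiguous; matching
    none leaves it unmatched. Both categories are excluded from
    quantification downstream.
    """
    if not alleles:
        raise ValueError("empty allele set")
    seqs = {
        p.sequence if isinstance(p, PeptideRecord) else str(p) for p in peptides
    }
    assigned: dict[str, str] = {}
    ambiguous: dict[str, frozenset[str]] = {}
    unmatched: set[str] = set()
    for seq in sorted(seqs):
        groups = {a.group for a in alleles if seq in a.sequence}
        if not groups:
            unmatched.add(seq)
        elif len(groups) == 1:
            assigned[seq] = next(iter(groups))
        else:
            ambiguous[seq] = frozenset(groups)
    return AssignmentResult(assigned, ambiguous, frozenset(unmatched))


@dataclass
class AllotypeQuant:
    """Quantification of one allotype group within one cell line."""

    group: str
    per_replicate: dict[int, float] = field(default_factory=dict)
    n_replicates_detected: int = 0
    retained: bool = False

    @property
    def mean(self) -> float:
        vals = list(self.per_replicate.values())
        return float(np.mean(vals)) if vals else 0.0

    @property
    def sem(self) -> float:
        vals = list(self.per_replicate.values())
        if len(vals) < 2:
            return float("nan")
        return float(np.std(vals, ddof=1) / math.sqrt(len(vals)))


def quantify_allotypes(
    records: Iterable[PeptideRecord],
    alleles: Sequence[AlleleSequence],
    presence_threshold: int = 3,
    assignment: AssignmentResult | None = None,
) -> dict[str, dict[str, AllotypeQuant]]:
    """Normalized-intensity quantification of allotype groups per cell line.

    Within each replicate, a group's normalized intensity is the summed
    intensity of its uniquely-assigned peptides divided by the total
    intensity of all peptides observed in that replicate (so group values
    sum to at most 1; ambiguous and unmatched peptides make up the
    remainder). A group counts as detected in a replicate when at least
    one assigned peptide is observed there, and is retained iff detected
    in >= ``presence_threshold`` replicates.
    """
    records = list(records)
    if assignment is None:
        assignment = assign_peptides_to_alleles(records, alleles)
    by_line: dict[str, list[PeptideRecord]] = {}
    for r in records:
        by_line.setdefault(r.cell_line, []).append(r)

    groups = sorted({a.group for a in alleles})
    out: dict[str, dict[str, AllotypeQuant]] = {}
    for line, recs in by_line.items():
        replicates = sorted({r.replicate for r in recs})
        totals: dict[int, float] = {}
        for rep in replicates:
            total = sum(
                r.intensity for r in recs if r.replicate == rep and r.intensity
            )
            if total <= 0:
                raise ValueError(
                    f"cell line {line} replicate {rep}: zero total intensity"
                )
            totals[rep] = total
        quants = {g: AllotypeQuant(g) for g in groups}
        for rep in replicates:
            sums = {g: 0.0 for g in groups}
            detected = {g: False for g in groups}
            for r in recs:
                if r.replicate != rep:
                    continue
                g = assignment.assigned.get(r.sequence)
                if g is None:
                    continue
                detected[g] = True
                if r.intensity:
                    sums[g] += r.intensity
            for g in groups:
                if detected[g]:
                    quants[g].per_replicate[rep] = sums[g] / totals[rep]
        for g, q in quants.items():
            q.n_replicates_detected = len(q.per_replicate)
            q.retained = q.n_replicates_detected >= presence_threshold
        out[line] = quants
    return out


def compare_allotypes(
    quant_a: AllotypeQuant, quant_b: AllotypeQuant
) -> tuple[float, float]:
    """Two-sample Student's t-test on per-replicate normalized intensities.

    Returns (t, p). Mirrors the equal-variance test used for the
    whole-cell proteome comparisons; no multiple-testing correction is
    applied here.
    """
    a = np.array(list(quant_a.per_replicate.values()))
    b = np.array(list(quant_b.per_replicate.values()))
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicate values per group for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
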