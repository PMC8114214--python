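"""Repertoire-level statistics for eluted MHC-I peptide sets.

Counts and percentages of unique sequences and 7-15mers per cell line,
length distributions (optionally per replicate with mean +/- SEM),
replicate reproducibility (in how many of n replicates each unique
peptide was found), three-set overlaps between cell lines, and a
two-sample Student's t-test for differential source-protein expression
in log2 space.

"Unique" throughout means exact string equality of the peptide sequence
within a cell line, pooled across replicates; cross-cell-line overlaps
use the same pooled sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PeptideRecord

logger = logging.getLogger("sahapep")

DEFAULT_MIN_LEN = 7
DEFAULT_MAX_LEN = 15


def display_percent(x: float) -> int:
    """Integer display form of a percentage: truncation toward zero.

    The published summary-table percentages are truncated, not rounded
    (e.g. 67.52% prints as 67); raw values are retained internally.
    """
    return int(x)


@dataclass(frozen=True)
class RepertoireSummary:
    """Per-cell-line repertoire counts in the style of a summary table row.

    ``pct_7_15`` is the raw percentage of unique sequences falling in the
    7-15mer window; ``pct_display`` truncates it to an integer for
    reporting (matching how the published counts print).
    """

    cell_line: str
    n_total_observations: int
    n_unique_sequences: int
    n_unique_7_15: int

    def __post_init__(self) -> None:
        if not (
            self.n_unique_7_15 <= self.n_unique_sequences <= self.n_total_observations
        ):
            raise ValueError(
                f"{self.cell_line}: counts must satisfy "
                "unique 7-15 <= unique <= total observations"
            )

    @property
    def pct_7_15(self) -> float:
        if self.n_unique_sequences == 0:
            return 0.0
        return 100.0 * self.n_unique_7_15 / self.n_unique_sequences

    @property
    def pct_display(self) -> int:
        return display_percent(self.pct_7_15)

    @classmethod
    def from_counts(
        cls,
        cell_line: str,
        n_total_observations: int,
        n_unique_sequences: int,
        n_unique_7_15: int,
    ) -> "RepertoireSummary":
        """Build a summary directly from published counts.

        Useful for recomputing the derived percentage from a printed table
        without the underlying peptide lists.
        """
        return cls(cell_line, n_total_observations, n_unique_sequences, n_unique_7_15)


def _by_cell_line(records: Iterable[PeptideRecord]) -> dict[str, list[PeptideRecord]]:
    out: dict[str, list[PeptideRecord]] = {}
    for r in records:
        out.setdefault(r.cell_line, []).append(r)
    return out


def summarize_repertoire(
    records: Iterable[PeptideRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[str, RepertoireSummary]:
    """Per-cell-line totals, unique sequences, and unique peptides in the
    length window (default 7-15mers).

    Observations are table rows (duplicates across replicates/fractions
    count); unique sequences are pooled over replicates within a cell line.
    """
    summaries: dict[str, RepertoireSummary] = {}
    for line, recs in _by_cell_line(records).items():
        uniq = {r.sequence for r in recs}
        n_window = sum(1 for s in uniq if min_len <= len(s) <= max_len)
        if not recs:
            logger.warning("cell line %s has no records", line)
        summaries[line] = RepertoireSummary(line, len(recs), len(uniq), n_window)
    return summaries


def length_distribution(
    records: Iterable[PeptideRecord],
    per_replicate: bool = False,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> pd.DataFrame:
    """Counts and percentages of unique sequences per length.

    Pooled mode returns, per cell line and length in [min_len, max_len],
    the unique-sequence count and its percentage of unique peptides in the
    window (percentages sum to 100 per cell line). With ``per_replicate``,
    percentages are computed within each replicate's unique set and the
    mean and standard error of the mean (sd/sqrt(n)) across replicates are
    added; with a single replicate the SEM is reported missing (NaN).
    """
    lengths = range(min_len, max_len + 1)
    rows = []
    for line, recs in _by_cell_line(records).items():
        uniq = {r.sequence for r in recs}
        window = [s for s in uniq if min_len <= len(s) <= max_len]
        n_window = len(window)
        per_rep_pct: dict[int, dict[int, float]] = {}
        if per_replicate:
            reps = sorted({r.replicate for r in recs})
            for rep in reps:
                rep_uniq = {
                    r.sequence
                    for r in recs
                    if r.replicate == rep and min_len <= r.length <= max_len
                }
                denom = len(rep_uniq) or 1
                for L in lengths:
                    per_rep_pct.setdefault(L, {})[rep] = (
                        100.0 * sum(1 for s in rep_uniq if len(s) == L) / denom
                    )
        for L in lengths:
            count = sum(1 for s in window if len(s) == L)
            row = {
                "cell_line": line,
                "length": L,
                "count": count,
                "percent": 100.0 * count / n_window if n_window else 0.0,
            }
            if per_replicate:
                vals = np.array(list(per_rep_pct[L].values()))
                row["mean_percent"] = vals.mean() if vals.size else np.nan
                row["sem_percent"] = (
                    vals.std(ddof=1) / math.sqrt(vals.size) if vals.size > 1 else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def replicate_reproducibility(
    records: Iterable[PeptideRecord],
    n_replicates: Mapping[str, int] | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[str, dict[int, float]]:
    """Percentage of unique 7-15mers found in exactly k of n replicates.

    ``n_replicates`` declares the replicate count per cell line; when
    omitted it is inferred as the maximum replicate number observed.
    Percentages over k = 1..n sum to 100 per cell line.
    """
    out: dict[str, dict[int, float]] = {}
    for line, recs in _by_cell_line(records).items():
        n_rep = (
            n_replicates[line]
            if n_replicates is not None
            else max(r.replicate for r in recs)
        )
        if n_rep < 2:
            raise ValueError(f"cell line {line}: need >= 2 declared replicates")
        seen: dict[str, set[int]] = {}
        for r in recs:
            if min_len <= r.length <= max_len:
                seen.setdefault(r.sequence, set()).add(r.replicate)
        n_uniq = len(seen)
        counts = {k: 0 for k in range(1, n_rep + 1)}
        for reps in seen.values():
            counts[len(reps)] += 1
        out[line] = {
            k: (100.0 * v / n_uniq if n_uniq else 0.0) for k, v in counts.items()
        }
    return out


def venn_overlap(
    sets_by_group: Mapping[str, Iterable[str]] | Iterable[PeptideRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[frozenset[str], int]:
    """Partition counts of unique 7-15mer sequences across cell lines.

    Accepts either a mapping group -> sequences or raw records (grouped by
    cell line). Returns the full Venn partition: each region is keyed by
    the exact (frozen) set of groups containing its sequences, and region
    counts are disjoint, summing to the union size. Three groups give the
    classic 7-region partition; two are permitted.
    """
    if not isinstance(sets_by_group, Mapping):
        grouped = _by_cell_line(sets_by_group)
        sets = {
            line: {r.sequence for r in recs if min_len <= r.length <= max_len}
            for line, recs in grouped.items()
        }
    else:
        sets = {
            g: {s for s in seqs if min_len <= len(s) <= max_len}
            for g, seqs in sets_by_group.items()
        }
    if len(sets) < 2:
        raise ValueError("venn_overlap needs at least two groups")
    regions: dict[frozenset[str], int] = {}
    universe = set().union(*sets.values())
    for seq in universe:
        members = frozenset(g for g, s in sets.items() if seq in s)
        regions[members] = regions.get(members, 0) + 1
    # report zero counts for empty regions so the partition is explicit
    from itertools import combinations

    names = list(sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions.setdefault(frozenset(combo), 0)
    return regions


def differential_source_proteins(
    expr_a: Mapping[str, Sequence[float]] | pd.DataFrame,
    expr_b: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Two-sample Student's t-test per protein accession on log2 values.

    Inputs map accession -> per-replicate log2 expression (or DataFrames
    with accessions as index and replicates as columns). The fold change is
    the difference of group means in log2 space (group A minus group B);
    the test is the equal-variance Student's form, producing output
    suitable for a volcano plot. When both groups have zero variance and
    equal means the p-value is defined as 1.
    """
    if isinstance(expr_a, pd.DataFrame):
        expr_a = {acc: row.to_numpy() for acc, row in expr_a.iterrows()}
    if isinstance(expr_b, pd.DataFrame):
        expr_b = {acc: row.to_numpy() for acc, row in expr_b.iterrows()}
    common = sorted(set(expr_a) & set(expr_b))
    rows = []
    for acc in common:
        a = np.asarray(expr_a[acc], dtype=float)
        b = np.asarray(expr_b[acc], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"{acc}: need >= 2 replicates per group")
        log2fc = float(a.mean() - b.mean())
        if a.std() == 0 and b.std() == 0:
            p = 1.0 if log2fc == 0 else 0.0
            t = 0.0 if log2fc == 0 else math.inf * np.sign(log2fc)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {"accession": acc, "log2fc": log2fc, "t": float(t), "p_value": float(p)}
        )
    return pd.DataFrame(rows, columns=["accession", "log2fc", "t", "p_value"])


def log2_expression(
    raw: Mapping[str, Sequence[float]]
) -> dict[str, np.ndarray]:
    """Convert raw intensities to log2, excluding non-positive values."""
    out: dict[str, np.ndarray] = {}
    n_dropped = 0
    for acc, vals in raw.items():
        arr = np.asarray(vals, dtype=float)
        keep = arr > 0
        n_dropped += int((~keep).sum())
        out[acc] = np.log2(arr[keep])
    if n_dropped:
        logger.warning("excluded %d non-positive intensities before log2", n_dropped)
    return out
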