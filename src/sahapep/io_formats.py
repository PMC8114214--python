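"""Readers, writers and domain types for all external representations.

Peptide identification tables (search-engine exports), MHC-I allele
sequences (alpha-1/alpha-2 region FASTA), 20x20 amino-acid similarity
matrices, per-residue contact-probability weights, and the YAML run
configuration are parsed here into validated domain objects. Parsers
reject malformed mandatory fields rather than coercing them; rejection
counts are reported so that upstream search-engine artefacts (non-standard
residues, modified sequence strings) are visible instead of silently
dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("sahapep")

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

#: Default logical-field -> column-name mapping for peptide tables.
DEFAULT_SCHEMA: dict[str, str] = {
    "sequence": "sequence",
    "cell_line": "cell_line",
    "replicate": "replicate",
    "intensity": "intensity",
    "source_accessions": "source_accessions",
}


class ConfigurationError(ValueError):
    """An input file or configuration does not meet its contract."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide observation (a row of a search-engine export).

    ``intensity`` is a label-free quantification value in arbitrary units;
    ``None`` means not quantified (permitted for presence/absence analyses,
    mandatory for allotype quantification). ``source_accessions`` lists the
    protein accessions the peptide maps to, possibly empty.
    """

    sequence: str
    cell_line: str
    replicate: int
    intensity: float | None = None
    source_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlleleSequence:
    """A named MHC-I allele protein sequence (alpha-1/alpha-2 region).

    ``group`` is the allotype-group label: alleles that cannot be
    distinguished by the observed peptides (e.g. SahaI*27 and SahaI*27-1,
    one substitution apart) share a group and are quantified together.
    """

    name: str
    sequence: str
    group: str | None = None

    def __post_init__(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            raise ValueError(
                f"allele {self.name}: sequence contains non-standard residues"
            )
        if self.group is None:
            object.__setattr__(self, "group", self.name)


class SimilarityMatrix:
    """A symmetric 20x20 amino-acid similarity matrix (PMBEC-style PSSM).

    Wraps a :class:`pandas.DataFrame` indexed by the 20 standard one-letter
    codes in both dimensions. The pocket scorer treats an alignment gap as
    scoring the matrix's global minimum, exposed as :attr:`min_value`.
    """

    def __init__(self, values: pd.DataFrame, *, tol: float = 1e-9) -> None:
        missing = _AA_SET - set(values.index)
        if missing or len(values.index) != 20:
            raise ConfigurationError(
                f"similarity matrix must have exactly the 20 standard "
                f"amino acids as labels; missing {sorted(missing)}"
            )
        values = values.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].astype(float)
        arr = values.to_numpy()
        dev = np.abs(arr - arr.T)
        if dev.max() > tol:
            i, j = np.unravel_index(np.argmax(dev), dev.shape)
            raise ConfigurationError(
                f"similarity matrix is asymmetric: "
                f"M[{AMINO_ACIDS[i]}][{AMINO_ACIDS[j]}] differs from its "
                f"transpose by {dev[i, j]:.3g}"
            )
        self._df = values

    @property
    def dataframe(self) -> pd.DataFrame:
        return self._df

    @property
    def labels(self) -> str:
        return AMINO_ACIDS

    @property
    def min_value(self) -> float:
        return float(self._df.to_numpy().min())

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self._df.at[a, b])

    def is_diagonal_row_max(self) -> bool:
        """True when every diagonal entry is the maximum of its row.

        PMBEC and BLOSUM-family matrices have this property; it guarantees
        the self-score is the maximum attainable pocket score.
        """
        arr = self._df.to_numpy()
        return bool(np.all(np.diag(arr) >= arr.max(axis=1)))


@dataclass(frozen=True)
class ContactWeights:
    """Per-position peptide-binding-region contact probabilities.

    Maps reference-numbered residue positions (1-based, ungapped numbering
    of the reference allele) to weights in [0, 1]. Each pocket position,
    after any adjacency expansion, must carry a weight.
    """

    weights: Mapping[int, float]

    def __post_init__(self) -> None:
        for pos, w in self.weights.items():
            if pos < 1:
                raise ConfigurationError(f"contact-weight position {pos} < 1")
            if not (0.0 <= w <= 1.0):
                raise ConfigurationError(
                    f"contact weight at position {pos} is {w}; must be in [0, 1]"
                )

    def __getitem__(self, pos: int) -> float:
        try:
            return float(self.weights[pos])
        except KeyError:
            raise ConfigurationError(
                f"no contact weight for pocket position {pos}"
            ) from None

    def __contains__(self, pos: int) -> bool:
        return pos in self.weights

    @classmethod
    def uniform(cls, positions: Iterable[int], value: float = 1.0) -> "ContactWeights":
        return cls({int(p): float(value) for p in positions})


# ---------------------------------------------------------------------------
# Peptide tables
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    header = path.open().readline()
    return "\t" if "\t" in header else ","


def read_peptide_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    replicate_sets: Mapping[str, Iterable[int]] | None = None,
    collect_rejected: list[str] | None = None,
) -> list[PeptideRecord]:
    """Read a delimited peptide identification table into records.

    The delimiter (comma or tab) is auto-detected from the header line.
    ``schema`` maps the logical fields ``sequence``, ``cell_line``,
    ``replicate``, ``intensity`` and ``source_accessions`` to column names;
    the last two columns are optional. Sequences are uppercased; rows whose
    sequence contains anything outside the 20 standard residues are
    rejected and counted (appended to ``collect_rejected`` when given).
    Duplicate rows are retained: rows are observations, not unique
    sequences. ``replicate_sets`` optionally declares the valid replicate
    numbers per cell line; out-of-set replicates raise.
    """
    path = Path(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if df.empty:
        logger.warning("peptide table %s is empty", path)
        return []
    for logical in ("sequence", "cell_line", "replicate"):
        if schema[logical] not in df.columns:
            raise ConfigurationError(
                f"peptide table {path} is missing mandatory column "
                f"{schema[logical]!r} (logical field {logical!r})"
            )
    has_intensity = schema["intensity"] in df.columns
    has_sources = schema["source_accessions"] in df.columns

    col_idx = {name: i for i, name in enumerate(df.columns)}
    records: list[PeptideRecord] = []
    n_rejected = 0
    for values in df.itertuples(index=False, name=None):
        row = {name: values[i] for name, i in col_idx.items()}
        seq = str(row[schema["sequence"]]).strip().upper()
        if not _SEQ_RE.match(seq):
            n_rejected += 1
            if collect_rejected is not None:
                collect_rejected.append(seq)
            continue
        replicate = int(row[schema["replicate"]])
        cell_line = str(row[schema["cell_line"]])
        if replicate_sets is not None:
            declared = set(replicate_sets.get(cell_line, ()))
            if replicate not in declared:
                raise ConfigurationError(
                    f"replicate {replicate} not in the declared set "
                    f"{sorted(declared)} for cell line {cell_line!r}"
                )
        intensity: float | None = None
        if has_intensity:
            raw = row[schema["intensity"]]
            if raw is not None and str(raw) not in ("", "nan"):
                intensity = float(raw)
        sources: tuple[str, ...] = ()
        if has_sources:
            raw = row[schema["source_accessions"]]
            if raw is not None and str(raw) not in ("", "nan"):
                sources = tuple(s for s in str(raw).split(";") if s)
        records.append(
            PeptideRecord(seq, cell_line, replicate, intensity, sources)
        )
    if n_rejected:
        logger.warning(
            "peptide table %s: rejected %d row(s) with non-standard residues",
            path,
            n_rejected,
        )
    return records


def write_peptide_table(
    records: Iterable[PeptideRecord], path: str | Path, *, sep: str = "\t"
) -> None:
    """Write records in the canonical peptide-table schema (see module doc)."""
    rows = [
        {
            "sequence": r.sequence,
            "cell_line": r.cell_line,
            "replicate": r.replicate,
            "intensity": "" if r.intensity is None else repr(r.intensity),
            "source_accessions": ";".join(r.source_accessions),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["sequence", "cell_line", "replicate", "intensity", "source_accessions"],
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Allele FASTA
# ---------------------------------------------------------------------------

def read_allele_fasta(
    path: str | Path,
    group_map: Mapping[str, str] | None = None,
) -> list[AlleleSequence]:
    """Read MHC-I allele protein sequences from FASTA.

    ``group_map`` maps allele names to allotype-group labels; alleles not in
    the map (or when no map is given) default to their own name as group.
    Duplicate headers raise; a sequence drawn only from {A, C, G, T, N}
    triggers a nucleotide-suspicion warning but is kept.
    """
    seen: set[str] = set()
    alleles: list[AlleleSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise ConfigurationError(f"duplicate FASTA header {name!r} in {path}")
        seen.add(name)
        seq = str(rec.seq).upper()
        if seq and set(seq) <= set("ACGTN"):
            logger.warning(
                "allele %s looks nucleotide (only ACGTN); expected protein", name
            )
        group = group_map.get(name) if group_map else None
        alleles.append(AlleleSequence(name=name, sequence=seq, group=group))
    return alleles


def write_allele_fasta(alleles: Iterable[AlleleSequence], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for a in alleles:
            fh.write(f">{a.name}\n{a.sequence}\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (allele, group) delimited table into a dict."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if df.shape[1] < 2:
        raise ConfigurationError(f"group map {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_group_map(group_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"allele": list(group_map), "group": list(group_map.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Similarity matrix and contact weights
# ---------------------------------------------------------------------------

def read_similarity_matrix(path: str | Path, *, tol: float = 1e-9) -> SimilarityMatrix:
    """Read a labelled 20x20 similarity matrix (comma or whitespace delimited)."""
    path = Path(path)
    header = path.open().readline()
    sep = "," if "," in header else r"\s+"
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python", comment="#")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return SimilarityMatrix(df, tol=tol)


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    matrix.dataframe.to_csv(path, sep="\t")


def similarity_from_substitution_matrix(name: str = "BLOSUM62") -> SimilarityMatrix:
    """Build a SimilarityMatrix from a published substitution matrix.

    Loads the named matrix from biopython's substitution-matrix collection
    and restricts it to the 20 standard residues. BLOSUM62 shares the
    property the pocket scorer relies on: diagonal entries are row maxima.
    """
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load(name)
    data = {
        a: {b: float(sub[a, b]) for b in AMINO_ACIDS} for a in AMINO_ACIDS
    }
    return SimilarityMatrix(pd.DataFrame(data).T)


def read_contact_weights(path: str | Path) -> ContactWeights:
    """Read a two-column (position, weight) delimited table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), comment="#")
    if df.shape[1] < 2:
        raise ConfigurationError(f"contact weights {path} needs two columns")
    return ContactWeights(
        {int(p): float(w) for p, w in zip(df.iloc[:, 0], df.iloc[:, 1])}
    )


def write_contact_weights(weights: ContactWeights, path: str | Path) -> None:
    pd.DataFrame(
        {"position": list(weights.weights), "weight": list(weights.weights.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the structured YAML run configuration."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return cfg
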