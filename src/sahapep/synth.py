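"""Synthetic immunopeptidome generation.

Emulates the statistical structure of a pan-beta-2-microglobulin capture
experiment on a multi-allotype cell line so that every analysis stage is
testable without external data: unique peptide repertoires drawn from a
planted anchor-motif mixture over 7-15mer lengths, per-replicate
detection, log-normal label-free intensities, controlled sequence
sharing between cell lines, allele sequence sets with controlled
identity at pocket positions, alpha-chain digest tables with planted
allotype abundances, and whole-proteome log2 expression matrices.

All generators are deterministic given a seed, and planted parameters
are returned alongside the data so they can serve as the oracle in
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AMINO_ACIDS,
    AlleleSequence,
    ConfigurationError,
    PeptideRecord,
    SimilarityMatrix,
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

OMEGA = "omega"


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class MotifComponent:
    """One component of a motif mixture.

    ``anchors`` maps a 1-based position (int) or ``"omega"`` (the
    C-terminal position) to a residue -> probability dict; probability
    mass not assigned at an anchor is spread over the unnamed residues in
    proportion to the background. ``background`` defaults to uniform over
    the 20 standard residues.
    """

    weight: float = 1.0
    anchors: dict[int | str, dict[str, float]] = field(default_factory=dict)
    background: dict[str, float] | None = None


@dataclass
class CellLineSynthConfig:
    """Generative specification of one cell line's peptidome."""

    name: str
    n_unique_target: int
    length_distribution: dict[int, float]
    motif_mixture: list[MotifComponent] = field(default_factory=lambda: [MotifComponent()])
    n_replicates: int = 4
    detection_probability: float = 0.45
    intensity_log_mu: float = 16.0
    intensity_log_sigma: float = 1.5

    def __post_init__(self) -> None:
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"{self.name}: length distribution sums to {total}, not 1"
            )
        w = sum(c.weight for c in self.motif_mixture)
        if abs(w - 1.0) > 1e-6:
            raise ConfigurationError(f"{self.name}: mixture weights sum to {w}, not 1")
        if not (0 < self.detection_probability <= 1):
            raise ConfigurationError("detection_probability must be in (0, 1]")


@dataclass
class AlleleUniverseConfig:
    """Plan for a synthetic allele set with controlled pocket identity."""

    n_db: int = 50
    seq_length: int = 182
    identity_baseline: float = 0.3
    planted_pocket: str = "F"
    adjacent_radius: int = 1
    n_paired_groups: int = 1  # groups holding two near-identical alleles


@dataclass
class DigestConfig:
    """Plan for a synthetic alpha-chain digest table."""

    cell_line: str = "fibroblasts"
    n_replicates: int = 4
    n_peptides_per_replicate: int = 500
    group_abundances: dict[str, float] = field(default_factory=dict)
    present_replicates: dict[str, list[int]] = field(default_factory=dict)
    min_len: int = 7
    max_len: int = 25
    intensity_log_mu: float = 16.0
    intensity_log_sigma: float = 0.5
    exact_fractions: bool = True


@dataclass
class SyntheticConfig:
    """Full generative specification of a simulated study."""

    seed: int = 0
    cell_lines: list[CellLineSynthConfig] = field(default_factory=list)
    shared_fraction: float = 0.06
    n_source_proteins: int = 2000
    neural_fraction: float = 0.1
    allele_universe: AlleleUniverseConfig = field(default_factory=AlleleUniverseConfig)
    digest: DigestConfig = field(default_factory=DigestConfig)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        lines = []
        for line in d.get("cell_lines", []):
            line = dict(line)
            mixture = [
                MotifComponent(
                    weight=c.get("weight", 1.0),
                    anchors={
                        (k if k == OMEGA else int(k)): dict(v)
                        for k, v in c.get("anchors", {}).items()
                    },
                    background=c.get("background"),
                )
                for c in line.pop("motif_mixture", [{}])
            ]
            line["length_distribution"] = {
                int(k): float(v) for k, v in line["length_distribution"].items()
            }
            lines.append(CellLineSynthConfig(motif_mixture=mixture, **line))
        universe = AlleleUniverseConfig(**d.get("allele_universe", {}))
        digest = DigestConfig(**d.get("digest", {}))
        return cls(
            seed=int(d.get("seed", 0)),
            cell_lines=lines,
            shared_fraction=float(d.get("shared_fraction", 0.06)),
            n_source_proteins=int(d.get("n_source_proteins", 2000)),
            neural_fraction=float(d.get("neural_fraction", 0.1)),
            allele_universe=universe,
            digest=digest,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-like default: three cell lines with a shared leucine anchor.

    Unique 7-15mer targets (12838 / 9207 / 3509) follow the yields of a
    four-replicate pan-capture experiment on a fibroblast line and two
    tumour lines; all three plant a leucine anchor at p3 (dominant in
    fibroblasts and DFT2, strong in DFT1 + IFN-g) and hydrophobic
    preferences (L/V/F/P) at the C terminus, with one line-specific
    secondary anchor each. 8mers outnumber 9mers except in DFT1 + IFN-g.
    """
    lengths_8 = {7: 0.05, 8: 0.26, 9: 0.22, 10: 0.15, 11: 0.11,
                 12: 0.08, 13: 0.06, 14: 0.04, 15: 0.03}
    lengths_9 = {7: 0.05, 8: 0.22, 9: 0.26, 10: 0.15, 11: 0.11,
                 12: 0.08, 13: 0.06, 14: 0.04, 15: 0.03}
    omega = {"L": 0.30, "V": 0.15, "F": 0.12, "P": 0.08}
    lines = [
        CellLineSynthConfig(
            name="fibroblasts",
            n_unique_target=12838,
            length_distribution=lengths_8,
            motif_mixture=[
                MotifComponent(anchors={3: {"L": 0.35}, 2: {"Q": 0.25}, OMEGA: omega})
            ],
        ),
        CellLineSynthConfig(
            name="DFT1_IFNg",
            n_unique_target=9207,
            length_distribution=lengths_9,
            motif_mixture=[MotifComponent(anchors={3: {"L": 0.25}, OMEGA: omega})],
        ),
        CellLineSynthConfig(
            name="DFT2",
            n_unique_target=3509,
            length_distribution=lengths_8,
            motif_mixture=[
                MotifComponent(anchors={3: {"L": 0.35}, 1: {"D": 0.22}, OMEGA: omega})
            ],
        ),
    ]
    cfg = SyntheticConfig(seed=seed, cell_lines=lines)
    cfg.digest = DigestConfig(
        group_abundances={"G0": 0.5, "G1": 0.3, "G2": 0.2},
        present_replicates={"G2": [1, 2]},
    )
    return cfg


# ---------------------------------------------------------------------------
# Peptide sampling
# ---------------------------------------------------------------------------

def position_probabilities(
    length: int, component: MotifComponent
) -> np.ndarray:
    """L x 20 per-position residue probabilities for one mixture component."""
    if component.background is None:
        bg = np.full(20, 1.0 / 20)
    else:
        bg = np.zeros(20)
        for res, p in component.background.items():
            bg[_AA_INDEX[res]] = p
        if abs(bg.sum() - 1.0) > 1e-6:
            raise ConfigurationError("background frequencies must sum to 1")
    probs = np.tile(bg, (length, 1))
    for key, dist in component.anchors.items():
        pos = length if key == OMEGA else int(key)
        if not (1 <= pos <= length):
            continue  # anchor beyond this peptide length
        row = np.zeros(20)
        named = 0.0
        for res, p in dist.items():
            row[_AA_INDEX[res]] = p
            named += p
        if named > 1.0 + 1e-9:
            raise ConfigurationError("anchor probabilities exceed 1")
        unnamed = np.array([a not in dist for a in AMINO_ACIDS])
        rest = bg[unnamed]
        if rest.sum() > 0:
            row[unnamed] = rest / rest.sum() * (1.0 - named)
        probs[pos - 1] = row
    return probs


def _draw_sequences(n: int, probs: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Draw n sequences from per-position categorical distributions."""
    length = probs.shape[0]
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0
    idx = np.empty((n, length), dtype=np.intp)
    u = rng.random((n, length))
    for p in range(length):
        idx[:, p] = np.searchsorted(cum[p], u[:, p], side="right")
    np.clip(idx, 0, 19, out=idx)
    flat = _AA_BYTES[idx].tobytes().decode()
    return [flat[i * length : (i + 1) * length] for i in range(n)]


def sample_unique_peptides(
    n: int,
    length: int,
    component: MotifComponent,
    rng: int | np.random.Generator,
    exclude: set[str] | None = None,
) -> list[str]:
    """Sample n distinct peptides of one length from a motif component.

    Raises when the request exceeds half the sequence space (degenerate
    uniqueness by rejection would stall).
    """
    rng = _as_rng(rng)
    space = 20 ** length
    if n > 0.5 * space:
        raise ConfigurationError(
            f"cannot draw {n} unique length-{length} peptides from a space of {space}"
        )
    probs = position_probabilities(length, component)
    seen: set[str] = set(exclude) if exclude else set()
    out: list[str] = []
    while len(out) < n:
        batch = _draw_sequences(max(n - len(out), 32) * 2, probs, rng)
        for s in batch:
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


@dataclass
class PeptidomeResult:
    """Generated peptidome plus its planted ground truth."""

    records: list[PeptideRecord]
    unique_by_line: dict[str, list[str]]
    shared_sequences: list[str]
    accession_of: dict[str, str]
    neural_accessions: frozenset[str]
    config: SyntheticConfig


def generate_peptidome(
    config: SyntheticConfig, rng: int | np.random.Generator | None = None
) -> PeptidomeResult:
    """Generate per-cell-line peptide observation tables.

    Unique sequences are drawn per cell line from its motif mixture and
    length distribution; a ``shared_fraction`` of each line's target is
    replaced by a common pool injected into every line (controlled
    overlap). Each unique sequence is observed independently in each
    replicate with the line's detection probability (sequences detected
    nowhere are absent from the table), with log-normal intensities per
    observation and one synthetic source accession per unique sequence.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    if not config.cell_lines:
        raise ConfigurationError("no cell lines configured")

    n_shared = int(round(config.shared_fraction * min(
        c.n_unique_target for c in config.cell_lines
    )))
    shared: list[str] = []
    if n_shared:
        first = config.cell_lines[0]
        comp = first.motif_mixture[0]
        lengths = sorted(first.length_distribution)
        weights = np.array([first.length_distribution[L] for L in lengths])
        counts = rng.multinomial(n_shared, weights)
        for L, c in zip(lengths, counts):
            if c:
                shared.extend(sample_unique_peptides(int(c), L, comp, rng))

    accessions = [f"SYNP{i:05d}" for i in range(config.n_source_proteins)]
    n_neural = int(round(config.neural_fraction * config.n_source_proteins))
    neural = frozenset(accessions[:n_neural])
    accession_of: dict[str, str] = {}

    records: list[PeptideRecord] = []
    unique_by_line: dict[str, list[str]] = {}
    for line in config.cell_lines:
        n_own = line.n_unique_target - len(shared)
        if n_own < 0:
            raise ConfigurationError(
                f"{line.name}: shared pool exceeds the unique-sequence target"
            )
        seqs: list[str] = list(shared)
        exclude = set(shared)
        comp_weights = np.array([c.weight for c in line.motif_mixture])
        comp_counts = rng.multinomial(n_own, comp_weights)
        lengths = sorted(line.length_distribution)
        lweights = np.array([line.length_distribution[L] for L in lengths])
        for comp, n_comp in zip(line.motif_mixture, comp_counts):
            if not n_comp:
                continue
            len_counts = rng.multinomial(int(n_comp), lweights)
            for L, c in zip(lengths, len_counts):
                if c:
                    new = sample_unique_peptides(int(c), L, comp, rng, exclude=exclude)
                    exclude.update(new)
                    seqs.extend(new)
        unique_by_line[line.name] = seqs
        for s in seqs:
            if s not in accession_of:
                accession_of[s] = accessions[int(rng.integers(len(accessions)))]
        detected = rng.random((len(seqs), line.n_replicates)) < line.detection_probability
        log_int = rng.normal(
            line.intensity_log_mu,
            line.intensity_log_sigma,
            size=(len(seqs), line.n_replicates),
        )
        for i, s in enumerate(seqs):
            for rep in range(line.n_replicates):
                if detected[i, rep]:
                    records.append(
                        PeptideRecord(
                            sequence=s,
                            cell_line=line.name,
                            replicate=rep + 1,
                            intensity=float(np.exp(log_int[i, rep])),
                            source_accessions=(accession_of[s],),
                        )
                    )
    return PeptidomeResult(records, unique_by_line, shared, accession_of, neural, config)


# ---------------------------------------------------------------------------
# Allele sets
# ---------------------------------------------------------------------------

def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@dataclass
class AlleleSetResult:
    """Synthetic allele universe with planted pocket-identity ground truth."""

    reference: AlleleSequence
    query: AlleleSequence
    db: list[AlleleSequence]
    group_map: dict[str, str]
    planted_top: dict[str, str]  # pocket name -> db allele planted identical

    @property
    def all_alleles(self) -> list[AlleleSequence]:
        return [self.reference, self.query, *self.db]


def generate_allele_set(
    config: AlleleUniverseConfig,
    matrix: SimilarityMatrix | None = None,
    rng: int | np.random.Generator = 0,
) -> AlleleSetResult:
    """Generate a reference, a query and a database of allele sequences.

    All sequences share the reference length (gap-free, trivially
    aligned). One database entry is planted identical to the query at all
    (adjacency-expanded) positions of the configured pocket and divergent
    elsewhere; the rest copy the query residue at any position with the
    baseline identity probability. ``n_paired_groups`` database groups
    hold two alleles one substitution apart (outside the pocket), the
    rest are singleton groups.
    """
    rng = _as_rng(rng)
    L = config.seq_length
    from .pocket import B_POCKET_POSITIONS, F_POCKET_POSITIONS

    base_positions = (
        B_POCKET_POSITIONS if config.planted_pocket == "B" else F_POCKET_POSITIONS
    )
    if L < max(base_positions) + 1:
        raise ConfigurationError(
            f"sequence length {L} shorter than the pocket span "
            f"({max(base_positions)} + 1)"
        )
    pocket_positions: set[int] = set()
    if config.planted_pocket == "F":
        for p in base_positions:
            for q in range(p - config.adjacent_radius, p + config.adjacent_radius + 1):
                if 1 <= q <= L:
                    pocket_positions.add(q)
    else:
        pocket_positions = set(base_positions)

    reference = AlleleSequence("REF", _random_protein(L, rng))
    query = AlleleSequence("QUERY", _random_protein(L, rng))

    db: list[AlleleSequence] = []
    group_map: dict[str, str] = {}
    planted_name = "DB000"
    for i in range(config.n_db):
        name = f"DB{i:03d}"
        chars = []
        for pos in range(1, L + 1):
            if i == 0 and pos in pocket_positions:
                chars.append(query.sequence[pos - 1])
            elif rng.random() < config.identity_baseline:
                chars.append(query.sequence[pos - 1])
            else:
                chars.append(AMINO_ACIDS[int(rng.integers(20))])
        db.append(AlleleSequence(name, "".join(chars), group=f"G{i}"))
        group_map[name] = f"G{i}"
    # paired groups: a near-copy of an existing allele, one substitution
    # outside the pocket, sharing its group
    for j in range(config.n_paired_groups):
        base = db[j]
        pos = None
        order = rng.permutation(L)
        for cand in order:
            if (cand + 1) not in pocket_positions:
                pos = int(cand)
                break
        seq = list(base.sequence)
        old = seq[pos]
        choices = [a for a in AMINO_ACIDS if a != old]
        seq[pos] = choices[int(rng.integers(len(choices)))]
        name = f"{base.name}b"
        db.append(AlleleSequence(name, "".join(seq), group=base.group))
        group_map[name] = base.group
    return AlleleSetResult(
        reference, query, db, group_map, {config.planted_pocket: planted_name}
    )


# ---------------------------------------------------------------------------
# Alpha-chain digests
# ---------------------------------------------------------------------------

@dataclass
class DigestResult:
    records: list[PeptideRecord]
    planted_fractions: dict[str, float]
    present_replicates: dict[str, list[int]]


def generate_alpha_chain_digest(
    alleles: Sequence[AlleleSequence],
    config: DigestConfig,
    rng: int | np.random.Generator = 0,
) -> DigestResult:
    """Simulate an enzymatic digest of immunoprecipitated alpha chains.

    Peptides are substrings (default 7-25mers) of the allele sequences,
    drawn per replicate with group frequencies proportional to the planted
    abundances, log-normal intensities, and an optional per-group presence
    plan (``present_replicates``) to exercise the >= 3-of-4 rule. With
    ``exact_fractions`` (default) each replicate's group intensity totals
    are rescaled so the planted normalized-intensity split is recovered
    exactly by downstream quantification.
    """
    rng = _as_rng(rng)
    if not config.group_abundances:
        raise ConfigurationError("digest config declares no group abundances")
    groups = sorted(config.group_abundances)
    missing = set(groups) - {a.group for a in alleles}
    if missing:
        raise ConfigurationError(f"abundance groups absent from allele set: {missing}")
    by_group = {g: [a for a in alleles if a.group == g] for g in groups}
    present = {
        g: list(config.present_replicates.get(g, range(1, config.n_replicates + 1)))
        for g in groups
    }

    records: list[PeptideRecord] = []
    for rep in range(1, config.n_replicates + 1):
        rep_groups = [g for g in groups if rep in present[g]]
        weights = np.array([config.group_abundances[g] for g in rep_groups])
        weights = weights / weights.sum()
        choice = rng.choice(len(rep_groups), size=config.n_peptides_per_replicate, p=weights)
        intensities = np.exp(
            rng.normal(
                config.intensity_log_mu,
                config.intensity_log_sigma,
                size=config.n_peptides_per_replicate,
            )
        )
        rep_records: list[tuple[str, str, float]] = []
        for gi, raw_int in zip(choice, intensities):
            g = rep_groups[int(gi)]
            allele = by_group[g][int(rng.integers(len(by_group[g])))]
            max_len = min(config.max_len, len(allele.sequence))
            plen = int(rng.integers(config.min_len, max_len + 1))
            start = int(rng.integers(0, len(allele.sequence) - plen + 1))
            rep_records.append((allele.sequence[start : start + plen], g, float(raw_int)))
        if config.exact_fractions:
            totals = {g: sum(x for _, gg, x in rep_records if gg == g) for g in rep_groups}
            grand = sum(totals.values())
            target = {
                g: config.group_abundances[g]
                / sum(config.group_abundances[h] for h in rep_groups)
                for g in rep_groups
            }
            for g in rep_groups:
                if totals[g] <= 0:
                    raise ConfigurationError(
                        f"group {g} drew no intensity in replicate {rep}; "
                        "increase n_peptides_per_replicate"
                    )
            scale = {g: target[g] * grand / totals[g] for g in rep_groups}
            rep_records = [(s, g, x * scale[g]) for s, g, x in rep_records]
        for seq, _g, x in rep_records:
            records.append(
                PeptideRecord(
                    sequence=seq,
                    cell_line=config.cell_line,
                    replicate=rep,
                    intensity=x,
                )
            )
    return DigestResult(records, dict(config.group_abundances), present)


# ---------------------------------------------------------------------------
# Whole-cell proteome expression
# ---------------------------------------------------------------------------

def generate_proteome(
    n_proteins: int,
    n_replicates: int = 3,
    rng: int | np.random.Generator = 0,
    *,
    base_log2: float = 25.0,
    sd_log2: float = 1.0,
    de_fraction: float = 0.0,
    effect_log2: float = 1.0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, float]]:
    """Two groups of log2 expression values with an optional planted shift.

    Returns (group A, group B, truth) where truth maps each accession to
    its planted log2 fold change (0 under the null). With
    ``de_fraction`` > 0 that fraction of proteins receives a mean shift
    of ``effect_log2`` in group A.
    """
    rng = _as_rng(rng)
    expr_a: dict[str, np.ndarray] = {}
    expr_b: dict[str, np.ndarray] = {}
    truth: dict[str, float] = {}
    n_de = int(round(de_fraction * n_proteins))
    for i in range(n_proteins):
        acc = f"SYNP{i:05d}"
        mu = rng.normal(base_log2, 2.0)
        shift = effect_log2 if i < n_de else 0.0
        expr_a[acc] = rng.normal(mu + shift, sd_log2, size=n_replicates)
        expr_b[acc] = rng.normal(mu, sd_log2, size=n_replicates)
        truth[acc] = shift
    return expr_a, expr_b, truth


# ---------------------------------------------------------------------------
# Synthetic similarity matrix
# ---------------------------------------------------------------------------

def generate_similarity_matrix(rng: int | np.random.Generator = 0) -> SimilarityMatrix:
    """A synthetic PMBEC-style similarity matrix.

    Symmetric 20x20, off-diagonal values in roughly [-0.3, 0.6], each
    diagonal entry strictly its row's maximum — the structural properties
    the pocket scorer relies on. A stand-in with the published matrix's
    shape, not its values.
    """
    rng = _as_rng(rng)
    vals = rng.uniform(-0.3, 0.6, size=(20, 20))
    vals = (vals + vals.T) / 2.0
    off_max = (vals - np.diag(np.diag(vals))).max(axis=1)
    np.fill_diagonal(vals, off_max + rng.uniform(0.1, 0.4, size=20))
    df = pd.DataFrame(vals, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    return SimilarityMatrix(df)
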