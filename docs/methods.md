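# Methods

## Scope and data model

The unit of observation is one identified peptide row from a
search-engine export: sequence, cell line, replicate, optional
label-free intensity, optional source accessions. Sequences are taken
verbatim (uppercased) over the 20 standard residues; rows containing
anything else are rejected and counted rather than coerced, because
non-standard characters in exported sequence strings usually indicate
modifications or ambiguous calls that the downstream counting must not
absorb silently. Isoleucine and leucine are never collapsed: residue
frequencies are reported exactly as the upstream identification
produced them. Missing intensity is allowed everywhere except allotype
quantification, which needs it by definition.

"Unique" always means exact string equality of the peptide sequence
within a cell line, pooled across replicates. Observation counts keep
duplicates (rows, not sequences). Cross-cell-line overlaps are computed
on the same pooled per-line sets, restricted to 7–15mers, the length
window expected for MHC-I ligands.

## Repertoire statistics

Percent displays truncate toward zero (67.52% prints as 67); raw values
are retained internally. Length distributions are reported both pooled
(percent of unique 7–15mers per cell line) and per replicate, where the
percentage is computed within each replicate's unique set and
summarised as mean ± SEM (sd/√n; undefined and reported missing for a
single replicate). Replicate reproducibility is the fraction of unique
7–15mers found in exactly k of the declared n replicates; the
percentages sum to 100 by construction.

Differential source-protein expression uses the equal-variance
two-sample Student's t-test on log2 values, with the fold change as
the difference of group means in log2 space. Non-positive raw
intensities are excluded before the log with a warning. The degenerate
case of zero variance in both groups with equal means is defined as
p = 1 (no evidence of difference), rather than propagating a NaN.

## Consensus motifs

PFMs are count/n frequencies over unique sequences of exactly one
length, pooled across replicates. Consensus classes use half-open
boundaries — dominant strictly above 30%, strong in (20%, 30%], moderate
in (10%, 20%] — because the class labels are stated with a strict ">"
only at the top boundary; a frequency of exactly 30% is therefore
strong, and exactly 10% is omitted. Within a class, residues are
ordered by descending frequency with alphabetical tie-break so output
is deterministic. The C-terminal position (p-omega) is the last
position of each peptide whatever its length. The small/bulky usage
analysis pools residue occurrences over the unique peptides of each
length; the nine residues in neither set contribute to neither
fraction, so the two fractions do not sum to 1.

## Allotype assignment and quantification

Peptides from digested alpha-chain fractions are matched to allotype
groups by exact substring search over the allele protein sequences.
Exact matching is appropriate because enzymatic digestion of an intact
alpha chain yields exact subsequences; no mismatch tolerance is
modelled. Alleles indistinguishable by the observed peptides share a
group (the SahaI*27 / SahaI*27-1 situation — one substitution apart), so
a peptide present in both is uniquely assigned, not ambiguous. Peptides
matching more than one group are excluded from quantification entirely
rather than fractionally shared: splitting would require an allocation
model the data do not support.

Within each replicate, a group's normalized intensity is the sum of its
assigned peptide intensities divided by the replicate's total peptide
intensity (all peptides, so group values sum to ≤ 1 and the remainder
is the ambiguous/unmatched mass). Detection in a replicate means ≥ 1
assigned peptide observed; retention requires detection in ≥ 3 of 4
replicates by default. Normalization makes the quantity invariant to
uniform intensity rescaling within a replicate, which is the point of
the per-sample normalization. Pairwise comparisons between groups use
the same equal-variance t-test as the proteome analysis.

## Pocket homology scoring

The scorer compares a query allele with database alleles at the residue
positions lining the B pocket (7, 9, 24, 34, 45, 63, 66, 67, 70, 99)
and F pocket (77, 80, 81, 84, 94, 115, 122, 142, 145, 146), numbered in
the 1-based ungapped coordinates of a designated reference sequence and
located in each allele through a multiple alignment containing that
reference. The F pocket additionally includes residues adjacent to the
defined set; adjacency is implemented as ±1 in reference numbering with
a configurable radius (default 1), since no explicit expanded set is
published. The score is

    score(q, s) = Σ_p w(p) · M[q(p), s(p)]
    max_score(q) = Σ_p w(p) · M[q(p), q(p)]

with M a symmetric 20×20 similarity matrix whose diagonal entries are
row maxima (a property of PMBEC- and BLOSUM-family matrices that makes
the self-score the attainable maximum, so relative scores are ≤ 1) and
w(p) the contact-probability weight of position p. A subject passes
when score ≥ 0.93 × max_score; the comparison carries a 1e-9 relative
tolerance so a score sitting exactly on the cutoff is not rejected by
floating-point rounding of the product. Relative scores are invariant
to uniform positive rescaling of the weights.

An alignment gap at a pocket position contributes the matrix's global
minimum (weighted), so missing pocket residues penalise a match rather
than inflating the relative score by shrinking the denominator.
Degenerate inputs (self-score ≤ 0) raise instead of producing
meaningless ratios.

Ranked passing matches break ties by subject name. Motif transfer is
table-driven: known pocket motifs of the top 3 passing annotated
subjects are attached to the report; when nothing passes, the report
states that no prediction is possible. Binding-affinity prediction
itself is out of scope — motifs enter as an external annotation table.

The contact weights are an input file with a uniform default of 1.0
per position, because the structure-derived contact probabilities the
weighting contract anticipates are configuration, not something this
package can compute. Likewise the published PMBEC matrix is not bundled;
`similarity_from_substitution_matrix("BLOSUM62")` provides a real,
published, diagonal-dominant matrix at run time, and
`generate_similarity_matrix` provides a synthetic matrix with the same
structural properties for tests. Multiple alignment is delegated: the
scorer consumes a precomputed alignment (or treats equal-length
gap-free sets as trivially aligned); helpers wrap an external `mafft`
binary and a Needleman–Wunsch pairwise fallback (BLOSUM62, gap open 10,
extend 1) for toy inputs.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analyses assume,
at the scale of the motivating study design (three cell lines, four
replicates, pan-capture of a multi-allotype mixture):

- **Peptidomes.** Unique-sequence targets default to 12 838 / 9 207 /
  3 509 for the fibroblast-like, DFT1-like and DFT2-like lines — the
  7–15mer yields such an experiment produces. All three lines plant a
  leucine anchor at p3 (35% in the fibroblast- and DFT2-like lines,
  25% in the DFT1-like line) and hydrophobic C-terminal preferences
  (L 30%, V 15%, F 12%, P 8%), each with one line-specific secondary
  anchor; the background is uniform over the 20 residues (the simplest
  testable null — an organism-specific composition is a config option,
  not the default). Lengths span 7–15 with 8mers most abundant except
  in the DFT1-like line, where 9mers lead. Each unique sequence is
  detected independently per replicate with probability 0.45, matching
  the single-replicate-dominated reproducibility such datasets show;
  intensities are log-normal (μ = 16, σ = 1.5 in ln units, i.e. a
  median around 9 × 10⁶ arbitrary LFQ units). Controlled overlap is
  produced by injecting an explicitly shared pool (6% of the smallest
  line target) into every line, so expected Venn regions are known
  exactly rather than hoped for through collisions.
- **Allele sets.** Gap-free equal-length sequences (182 residues,
  covering the alpha-1/alpha-2 region) with one database entry planted
  identical to the query at all expanded positions of the chosen
  pocket, decoys sharing each query residue with probability 0.3, and
  optional two-member groups one substitution apart to mirror
  indistinguishable allele pairs.
- **Digests.** Peptides are random 7–25mer windows of the allele
  sequences with planted group abundances; per-group intensity totals
  within each replicate are rescaled so the planted normalized-intensity
  split is exact (the spread across peptides stays log-normal,
  σ = 0.5). This makes split recovery a sharp correctness check of the
  quantification arithmetic rather than a sampling-noise measurement.
  A per-group presence plan (e.g. present in replicates 1–2 only)
  exercises the 3-of-4 retention rule.

Not emulated: mass spectra, retention behaviour, search-engine scoring
and FDR, shared peptides between unrelated source proteins, intensity
correlation between replicates, or allele sequences with realistic
phylogenetic structure. Passing tests therefore demonstrate that the
statistics, counting rules and scoring are implemented correctly under
the planted model — not that the pipeline is robust to the
identification artefacts of real data, which enter upstream of this
package.

All generators are deterministic given a seed and return their planted
parameters, which the tests use as oracles (planted-anchor recovery
within binomial tolerance, conditional-binomial replicate
reproducibility, exact Venn centre counts, planted pocket-identical
top hits).

## Numerical and design choices

- Summary-percent display truncates toward zero; raw percentages are
  kept.
- Consensus boundaries half-open as above; classification never assigns
  two classes to one residue-position pair.
- t-test: equal-variance form throughout; zero-variance equal-mean
  case defined as p = 1.
- Pocket cutoff comparison ≥ with 1e-9 relative tolerance; gap scores
  the matrix minimum; tie-break by subject name.
- Seeds: one integer seeds a numpy Generator that drives every
  stochastic step; the pipeline reuses a single stream across stages so
  one seed fixes the whole run.
- Problem sizes in tests and the acceptance script (5 000 peptides per
  motif-recovery run, 100 seeded runs per class, databases of 50
  sequences, 10 000 sequences for the reproducibility check, 1 000
  proteins for the null calibration) are chosen so sampling error is an
  order of magnitude below each tolerance while a full run stays
  interactive.

## Known limitations

- Exact substring assignment cannot place peptides carrying
  identification errors or residues outside an allele's database
  sequence; such peptides land in "unmatched".
- Motif analysis is per cell line, not per allotype: a pan-capture
  experiment mixes the motifs of all expressed allotypes, and no
  deconvolution (e.g. mixture modelling) is attempted.
- The pocket scorer's biological validity depends on the alignment and
  on the contact weights supplied; with the uniform default, every
  pocket position counts equally.
- Figure-quality plotting is out of scope; all outputs are tables.
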