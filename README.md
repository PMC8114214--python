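# sahapep

Analysis toolkit for MHC class I immunopeptidomes of the Tasmanian devil
(*Sarcophilus harrisii*) and its two transmissible cancers, DFT1 and
DFT2. The devil's facial tumours are clonally transmissible cell lines
that evade allograft rejection; one clue to how lies in the peptides
their MHC-I molecules present. This package implements the computational
side of that question for anyone working with eluted-ligand mass
spectrometry data from non-model species: repertoire statistics,
consensus binding motifs, label-free allotype quantification, and a
pocket-level homology method for predicting binding preferences of
uncharacterised MHC-I alleles.

## What it computes

**Repertoire statistics** (`sahapep.repertoire`) — per cell line: total
observations, unique sequences, unique 7–15mers and their percentage
(displayed truncated, as the source counts print); length distributions
with per-replicate mean ± SEM; the percentage of unique 7–15mers found
in exactly *k* of *n* replicates; the full Venn partition of unique
peptides between cell lines; and a two-sample Student's *t*-test on
log2 expression for differential source proteins (volcano-plot input).

**Consensus motifs** (`sahapep.motif`) — position frequency matrices
(PFMs) over unique peptides of one length, with per-position residue
preferences classified by frequency *f*:

- dominant: *f* > 30%
- strong: 20% < *f* ≤ 30%
- moderate: 10% < *f* ≤ 20%

plus single-position frequencies (e.g. leucine at p3) and
small ({A,D,G,N,P,S}) versus bulky ({F,H,K,R,Y}) residue usage by
peptide length.

**Allotype quantification** (`sahapep.allotype`) — peptides from
digested alpha-chain fractions are assigned to allotype groups by exact
substring matching (ambiguous assignments excluded); per replicate,
each group's intensity is normalized to the replicate's total peptide
intensity; a group is retained when detected in ≥ 3 of 4 replicates.

**Pocket homology scoring** (`sahapep.pocket`) — the binding preferences
of an uncharacterised allele are inferred by comparing the residues
lining its B pocket (positions 7, 9, 24, 34, 45, 63, 66, 67, 70, 99 in
reference numbering) and F pocket (77, 80, 81, 84, 94, 115, 122, 142,
145, 146, plus adjacent residues) with a database of aligned MHC-I
sequences. A subject *s* is scored against a query *q* as

    score(q, s) = Σ_p  w(p) · M[q(p), s(p)]

summed over pocket positions *p*, where *M* is a 20×20 amino-acid
similarity matrix (PMBEC-style; a BLOSUM62 import ships as a working
default) and *w(p)* the position's probability of contacting the
peptide-binding region. Subjects scoring ≥ 0.93 × the query's self-score
are homologous; the known motifs of the top 3 matches are transferred.

**Synthetic data** (`sahapep.synth`) — seeded generators for peptide
repertoires with planted anchor motifs, replicate detection and
log-normal intensities; allele sets with controlled identity at pocket
positions; alpha-chain digests with planted abundance splits; and null
or shifted proteome expression matrices. Planted parameters are
returned with the data, so every analysis has a ground-truth oracle.

## Worked example

```python
import sahapep

cfg = sahapep.default_config(seed=1)          # three cell lines, n = 4
result = sahapep.generate_peptidome(cfg)
for s in sahapep.summarize_repertoire(result.records).values():
    print(s.cell_line, s.n_total_observations, s.n_unique_sequences, s.pct_display)

pfm = sahapep.build_pfm(result.records, length=9, cell_line="fibroblasts")
print(pfm.n_peptides, round(pfm.frequency(3, "L"), 3))
motif = sahapep.classify_consensus(pfm)
print(motif.positions["p3"][:1], motif.positions["p9"][:1])
```

prints

```
fibroblasts 23290 11637 100
DFT1_IFNg 16538 8376 100
DFT2 6313 3188 100
2600 0.347
(('L', 0.34692307692307695, 'dominant'),) (('L', 0.2896153846153846, 'strong'),)
```

Each cell line's ~45% per-replicate detection rate turns ~12 800 / 9 200
/ 3 500 generated unique peptides into the observation counts shown; the
9mer PFM built from 2600 unique fibroblast peptides recovers the planted
leucine anchor at p3 (34.7% ≈ the planted 35%, classified dominant) and
the hydrophobic C-terminal preference (L strong at p9).

A pocket scan against a synthetic database ranks a planted
pocket-identical subject first at relative score 1.000 and reports "no
prediction" when nothing clears the 0.93 cutoff:

```python
report = sahapep.scan_database(query, db, sahapep.PocketModel.f_pocket(matrix), reference)
```

The same pipeline runs from the shell:

```
sahapep run --config src/sahapep/data/demo_config.yaml --outdir out/ --seed 7
```

writing per-stage tables (repertoire summary, length distribution,
reproducibility, overlaps, PFMs, consensus motifs, usage, allotype
quantification, pocket matches) and a `manifest.json` with record
counts per stage.

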