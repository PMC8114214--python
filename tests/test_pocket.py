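"""Reference-coordinate mapping, contact-weighted pocket scoring and scans."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sahapep import (
    AMINO_ACIDS,
    AlleleSequence,
    B_POCKET_POSITIONS,
    ContactWeights,
    F_POCKET_POSITIONS,
    PocketModel,
    SimilarityMatrix,
    generate_allele_set,
    generate_similarity_matrix,
    map_reference_positions,
    pocket_score,
    scan_database,
    similarity_from_substitution_matrix,
)
from sahapep.io_formats import ConfigurationError
from sahapep.pocket import align_with_mafft, pairwise_align_to_reference
from sahapep.synth import AlleleUniverseConfig, _random_protein


def identity_matrix():
    df = pd.DataFrame(np.eye(20), index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    return SimilarityMatrix(df)


class TestReferenceMapping:
    def test_gap_free_identity_alignment(self):
        ref = "MKTAYIAKQR"
        aln = {"REF": ref, "Q": ref}
        mapped = map_reference_positions(aln, "REF", [1, 5, 10])
        assert mapped["Q"] == ["M", "Y", "R"]

    def test_reference_gap_shifts_columns(self):
        # ungapped reference ACDE: position 3 (D) sits in alignment column 4
        aln = {"REF": "AC-DE", "Q": "ACLDE"}
        mapped = map_reference_positions(aln, "REF", [3])
        assert mapped["REF"] == ["D"]
        assert mapped["Q"] == ["D"]
        mapped2 = map_reference_positions(aln, "REF", [2])
        assert mapped2["Q"] == ["C"]

    def test_subject_gap_reported_as_gap_marker(self):
        aln = {"REF": "ACDE", "Q": "A-DE"}
        assert map_reference_positions(aln, "REF", [2])["Q"] == ["-"]

    def test_position_beyond_reference_raises(self):
        with pytest.raises(ConfigurationError, match="beyond"):
            map_reference_positions({"REF": "ACDE"}, "REF", [5])

    def test_missing_reference_raises(self):
        with pytest.raises(ConfigurationError, match="reference"):
            map_reference_positions({"Q": "ACDE"}, "REF", [1])

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_coordinate_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ref_res = _random_protein(n, rng)
        # scatter gaps into both rows independently, keeping columns equal
        cols = []
        q_cols = []
        i = 0
        while i < n:
            r = rng.random()
            if r < 0.2:
                cols.append("-")
                q_cols.append(AMINO_ACIDS[int(rng.integers(20))])
            else:
                cols.append(ref_res[i])
                q_cols.append(
                    "-" if rng.random() < 0.2 else AMINO_ACIDS[int(rng.integers(20))]
                )
                i += 1
        aln = {"REF": "".join(cols), "Q": "".join(q_cols)}
        positions = sorted(set(int(p) for p in rng.integers(1, n + 1, size=5)))
        mapped = map_reference_positions(aln, "REF", positions)
        non_gap_cols = [c for c, ch in enumerate(aln["REF"]) if ch != "-"]
        for p, res in zip(positions, mapped["Q"]):
            assert res == aln["Q"][non_gap_cols[p - 1]]


class TestPocketScore:
    def test_self_match_scores_one_and_passes(self):
        model = PocketModel.b_pocket(similarity_from_substitution_matrix())
        residues = list("ACDEFGHIKL")
        m = pocket_score(residues, residues, model)
        assert m.relative_score == pytest.approx(1.0)
        assert m.passes

    def test_identity_matrix_nine_of_ten_matches(self):
        model = PocketModel.b_pocket(identity_matrix())
        q = list("ACDEFGHIKL")
        s = list("ACDEFGHIKV")  # one mismatch
        m = pocket_score(q, s, model)
        assert m.score == 9.0 and m.max_score == 10.0
        assert m.relative_score == 0.9
        assert not m.passes  # 0.9 < 0.93

    def test_cutoff_is_greater_or_equal(self):
        # 93 matches out of 100 positions: relative score exactly 0.93
        positions = tuple(range(1, 101))
        model = PocketModel("B", positions, identity_matrix())
        q = ["A"] * 100
        s = ["A"] * 93 + ["C"] * 7
        m = pocket_score(q, s, model, positions)
        assert m.relative_score == pytest.approx(0.93)
        assert m.passes

    def test_gap_scores_matrix_minimum(self):
        blosum = similarity_from_substitution_matrix()
        positions = (1, 2)
        model = PocketModel("B", positions, blosum)
        m = pocket_score(["A", "A"], ["A", "-"], model, positions)
        assert m.score == pytest.approx(blosum["A", "A"] + blosum.min_value)

    def test_contact_weights_scale_contributions(self):
        positions = (1, 2)
        w = ContactWeights({1: 1.0, 2: 0.5})
        model = PocketModel("B", positions, identity_matrix(), weights=w)
        m = pocket_score(["A", "C"], ["A", "G"], model, positions)
        assert m.score == 1.0  # position 2 mismatch contributes 0
        assert m.max_score == 1.5

    def test_relative_score_invariant_to_weight_rescaling(self):
        positions = tuple(range(1, 11))
        rng = np.random.default_rng(3)
        base = {p: float(rng.uniform(0.2, 1.0)) for p in positions}
        q = [AMINO_ACIDS[i] for i in rng.integers(0, 20, 10)]
        s = [AMINO_ACIDS[i] for i in rng.integers(0, 20, 10)]
        blosum = similarity_from_substitution_matrix()
        m1 = pocket_score(
            q, s, PocketModel("B", positions, blosum, weights=ContactWeights(base)), positions
        )
        scaled = ContactWeights({p: w * 0.37 for p, w in base.items()})
        m2 = pocket_score(
            q, s, PocketModel("B", positions, blosum, weights=scaled), positions
        )
        assert abs(m1.relative_score - m2.relative_score) < 1e-9

    def test_missing_weight_raises(self):
        positions = (1, 2)
        model = PocketModel(
            "B", positions, identity_matrix(), weights=ContactWeights({1: 1.0})
        )
        with pytest.raises(ConfigurationError, match="position 2"):
            pocket_score(["A", "A"], ["A", "A"], model, positions)

    def test_degenerate_zero_self_score_raises(self):
        zero = SimilarityMatrix(
            pd.DataFrame(
                np.zeros((20, 20)), index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
            )
        )
        model = PocketModel("B", (1,), zero)
        with pytest.raises(ValueError, match="self-score"):
            pocket_score(["A"], ["A"], model, (1,))

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_weighted_sum(self, seed):
        rng = np.random.default_rng(seed)
        positions = tuple(sorted(rng.choice(np.arange(1, 50), size=8, replace=False)))
        weights = {int(p): float(rng.uniform(0, 1)) for p in positions}
        blosum = similarity_from_substitution_matrix()
        q = [AMINO_ACIDS[i] for i in rng.integers(0, 20, 8)]
        s = [AMINO_ACIDS[i] for i in rng.integers(0, 20, 8)]
        model = PocketModel("B", positions, blosum, weights=ContactWeights(weights))
        m = pocket_score(q, s, model, positions)
        expected = sum(
            weights[p] * blosum[a, b] for p, a, b in zip(positions, q, s)
        )
        assert m.score == pytest.approx(expected, abs=1e-12)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_matching_residues(self, seed):
        # replacing a subject residue with the query's never lowers the
        # score when the matrix diagonal is row-maximal
        rng = np.random.default_rng(seed)
        positions = tuple(range(1, 11))
        blosum = similarity_from_substitution_matrix()
        model = PocketModel("B", positions, blosum)
        q = [AMINO_ACIDS[i] for i in rng.integers(0, 20, 10)]
        s = [AMINO_ACIDS[i] for i in rng.integers(0, 20, 10)]
        base = pocket_score(q, s, model, positions).score
        k = int(rng.integers(10))
        s2 = list(s)
        s2[k] = q[k]
        assert pocket_score(q, s2, model, positions).score >= base


class TestPocketModel:
    def test_b_pocket_positions(self):
        assert B_POCKET_POSITIONS == (7, 9, 24, 34, 45, 63, 66, 67, 70, 99)

    def test_f_pocket_expands_adjacent_positions(self):
        model = PocketModel.f_pocket(identity_matrix())
        expanded = model.expanded_positions()
        for p in F_POCKET_POSITIONS:
            assert {p - 1, p, p + 1} <= set(expanded)
        assert list(expanded) == sorted(set(expanded))

    def test_expansion_clips_to_sequence_bounds(self):
        model = PocketModel("X", (1, 5), identity_matrix(), include_adjacent=True)
        assert model.expanded_positions(max_position=5) == (1, 2, 4, 5)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ConfigurationError):
            PocketModel("B", (9, 7), identity_matrix())


class TestScanDatabase:
    def test_database_containing_query_ranks_it_first(self, rng):
        universe = generate_allele_set(AlleleUniverseConfig(n_db=10), rng=rng)
        model = PocketModel.f_pocket(generate_similarity_matrix(rng))
        db = universe.db + [AlleleSequence("SELF", universe.query.sequence)]
        report = scan_database(universe.query, db, model, universe.reference)
        assert report.matches[0].relative_score == pytest.approx(1.0)
        assert report.matches[0].subject in ("SELF", "DB000")

    def test_planted_pocket_identical_subject_is_top_hit(self, rng):
        universe = generate_allele_set(
            AlleleUniverseConfig(n_db=50, identity_baseline=0.3), rng=rng
        )
        model = PocketModel.f_pocket(similarity_from_substitution_matrix())
        report = scan_database(universe.query, universe.db, model, universe.reference)
        assert report.matches[0].subject == universe.planted_top["F"]
        assert report.matches[0].relative_score == pytest.approx(1.0)

    def test_no_passing_subject_reports_no_prediction(self, rng):
        universe = generate_allele_set(
            AlleleUniverseConfig(n_db=5, identity_baseline=0.05, n_paired_groups=0),
            rng=rng,
        )
        db = universe.db[1:]  # drop the planted identical subject
        model = PocketModel.f_pocket(identity_matrix())
        report = scan_database(universe.query, db, model, universe.reference)
        assert report.no_prediction
        assert report.transferred_motifs == ()

    def test_motifs_transferred_from_top_k_annotated_matches(self, rng):
        universe = generate_allele_set(AlleleUniverseConfig(n_db=20), rng=rng)
        model = PocketModel.f_pocket(similarity_from_substitution_matrix())
        motif_table = {a.name: f"motif-{a.name}" for a in universe.db}
        report = scan_database(
            universe.query, universe.db, model, universe.reference, k=3,
            motif_table=motif_table,
        )
        assert len(report.transferred_motifs) <= 3
        assert report.transferred_motifs[0] == (
            report.matches[0].subject,
            f"motif-{report.matches[0].subject}",
        )

    def test_invariant_to_substitutions_outside_pocket(self, rng):
        universe = generate_allele_set(AlleleUniverseConfig(n_db=10), rng=rng)
        model = PocketModel.f_pocket(similarity_from_substitution_matrix())
        expanded = set(model.expanded_positions())
        report1 = scan_database(universe.query, universe.db, model, universe.reference)
        mutated = []
        for a in universe.db:
            seq = list(a.sequence)
            for pos in range(1, len(seq) + 1):
                if pos not in expanded and rng.random() < 0.3:
                    seq[pos - 1] = AMINO_ACIDS[int(rng.integers(20))]
            mutated.append(AlleleSequence(a.name, "".join(seq), group=a.group))
        report2 = scan_database(universe.query, mutated, model, universe.reference)
        scores1 = {m.subject: m.score for m in report1.matches}
        scores2 = {m.subject: m.score for m in report2.matches}
        assert scores1 == pytest.approx(scores2)

    def test_empty_database_raises(self, rng):
        universe = generate_allele_set(AlleleUniverseConfig(n_db=3), rng=rng)
        model = PocketModel.f_pocket(identity_matrix())
        with pytest.raises(ValueError):
            scan_database(universe.query, [], model, universe.reference)

    def test_unequal_lengths_without_alignment_rejected(self, rng):
        universe = generate_allele_set(AlleleUniverseConfig(n_db=3), rng=rng)
        short = AlleleSequence("SHORT", universe.db[0].sequence[:-5])
        model = PocketModel.f_pocket(identity_matrix())
        with pytest.raises(ConfigurationError, match="alignment"):
            scan_database(
                universe.query, [short], model, universe.reference
            )


class TestAlignmentHelpers:
    def test_pairwise_alignment_of_identical_sequences_is_gapless(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        a, b = pairwise_align_to_reference(seq, seq)
        assert a == b == seq

    def test_pairwise_alignment_restores_deletion(self):
        ref = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        query = ref[:10] + ref[13:]  # 3-residue deletion
        a, r = pairwise_align_to_reference(query, ref)
        assert r == ref
        assert a.replace("-", "") == query
        assert a.count("-") == 3

    def test_mafft_alignment_round_trips_sequences(self, rng):
        base = _random_protein(60, rng)
        seqs = {
            "REF": base,
            "A": base[:20] + base[23:],
            "B": base[:40] + "W" + base[40:],
            "C": base,
        }
        aligned = align_with_mafft(seqs)
        assert set(aligned) == set(seqs)
        assert len({len(s) for s in aligned.values()}) == 1
        for name, seq in seqs.items():
            assert aligned[name].replace("-", "") == seq
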