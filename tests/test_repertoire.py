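"""Repertoire counts, length distributions, reproducibility and overlaps."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sahapep import (
    RepertoireSummary,
    differential_source_proteins,
    length_distribution,
    replicate_reproducibility,
    summarize_repertoire,
    venn_overlap,
)
from sahapep.repertoire import display_percent

from conftest import make_records


class TestSummaries:
    @pytest.mark.parametrize(
        "line, total, unique, unique_7_15, pct",
        [
            ("fibroblasts", 28198, 15581, 12838, 82),
            ("DFT1_IFNg", 17280, 13636, 9207, 67),
            ("DFT2", 6879, 4648, 3509, 75),
            ("total", 52357, 33865, 25554, 75),
        ],
    )
    def test_percentage_from_published_counts(self, line, total, unique, unique_7_15, pct):
        s = RepertoireSummary.from_counts(line, total, unique, unique_7_15)
        assert s.pct_display == pct

    def test_count_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            RepertoireSummary.from_counts("x", 10, 20, 5)

    def test_all_length_nine_gives_100_percent(self):
        recs = make_records(["ADLDEFGHI", "AAYAAAAQL"])
        s = summarize_repertoire(recs)["fibroblasts"]
        assert s.pct_display == 100

    def test_enumeration_oracle_on_synthetic_lengths(self):
        # 60 in-window 8mers + 40 sequences of length 6 or 16 -> 60 percent
        pairs = [a + b for a in "ACDEFGHIKL" for b in "ACDEFGHIKL"]
        in_window = ["AAAAAA" + p for p in pairs[:60]]
        out_window = ["CCCC" + p for p in pairs[:20]] + [
            "W" * 14 + p for p in pairs[:20]
        ]
        assert all(7 <= len(s) <= 15 for s in in_window)
        assert all(len(s) in (6, 16) for s in out_window)
        s = summarize_repertoire(make_records(in_window + out_window))["fibroblasts"]
        assert s.n_unique_sequences == 100
        assert s.pct_display == 60

    def test_display_percent_truncates(self):
        # 67.52% must print as 67, as in the published table
        assert display_percent(67.52) == 67
        assert display_percent(82.39) == 82


class TestLengthDistribution:
    def test_percentages_sum_to_100(self, rng):
        seqs = {
            "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=L))
            for L in rng.integers(7, 16, size=400)
            for _ in range(1)
        }
        df = length_distribution(make_records(sorted(seqs)))
        assert df["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_agrees_with_summary_counts(self, small_synthetic_config):
        from sahapep import generate_peptidome

        records = generate_peptidome(small_synthetic_config).records
        df = length_distribution(records)
        summaries = summarize_repertoire(records)
        for line, s in summaries.items():
            assert df[df.cell_line == line]["count"].sum() == s.n_unique_7_15

    def test_single_replicate_sem_is_missing(self):
        recs = make_records([("ADLDEFGHI", 1), ("AAYAAAAQL", 1)])
        df = length_distribution(recs, per_replicate=True)
        assert df["sem_percent"].isna().all()

    def test_planted_length_fractions_recovered(self, rng):
        # 40% 8mers / 30% 9mers / 30% 10mers at n=5000, within 2 points
        from sahapep import MotifComponent, sample_unique_peptides

        comp = MotifComponent()
        counts = rng.multinomial(5000, [0.4, 0.3, 0.3])
        seqs = []
        for L, n in zip((8, 9, 10), counts):
            seqs.extend(sample_unique_peptides(int(n), L, comp, rng))
        df = length_distribution(make_records(seqs))
        pct = dict(zip(df["length"], df["percent"]))
        assert pct[8] == pytest.approx(40, abs=2)
        assert pct[9] == pytest.approx(30, abs=2)


class TestReplicateReproducibility:
    def test_everything_in_all_four_replicates(self):
        recs = make_records([("ADLDEFGHI", r) for r in (1, 2, 3, 4)])
        out = replicate_reproducibility(recs, {"fibroblasts": 4})
        assert out["fibroblasts"] == {1: 0.0, 2: 0.0, 3: 0.0, 4: 100.0}

    def test_disjoint_replicates(self):
        recs = make_records([("ADLDEFGHI", 1), ("AAYAAAAQL", 2)])
        out = replicate_reproducibility(recs, {"fibroblasts": 2})
        assert out["fibroblasts"] == {1: 100.0, 2: 0.0}

    def test_single_declared_replicate_rejected(self):
        recs = make_records([("ADLDEFGHI", 1)])
        with pytest.raises(ValueError):
            replicate_reproducibility(recs, {"fibroblasts": 1})

    def test_percentages_sum_to_100(self, rng):
        recs = []
        for i in range(200):
            seq = "".join("ACDEFGHIKLMNPQRSTVWY"[j] for j in rng.integers(0, 20, 9))
            for r in range(1, 5):
                if rng.random() < 0.5:
                    recs.append((seq, r))
        recs = make_records(recs)
        out = replicate_reproducibility(recs, {"fibroblasts": 4})
        assert sum(out["fibroblasts"].values()) == pytest.approx(100.0, abs=1e-9)


def _venn_oracle(sets):
    """Independent partition via subset algebra (intersection minus union)."""
    names = list(sets)
    out = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(set(sets[n]) for n in inside))
            for n in outside:
                region -= set(sets[n])
            out[frozenset(inside)] = len(region)
    return out


class TestVennOverlap:
    def test_identical_sets_concentrate_in_centre(self):
        seqs = [f"ADLDEFGH{a}" for a in "ACDEFGHIKL"]
        sets = {g: seqs for g in ("a", "b", "c")}
        regions = venn_overlap(sets)
        assert regions[frozenset(("a", "b", "c"))] == 10
        assert sum(regions.values()) == 10

    def test_pairwise_only_pattern(self):
        a, b, c = "ADLDEFGHA", "ADLDEFGHC", "ADLDEFGHD"
        regions = venn_overlap({"x": [a, b], "y": [b, c], "z": [c, a]})
        for pair in (("x", "y"), ("y", "z"), ("z", "x")):
            assert regions[frozenset(pair)] == 1
        assert regions[frozenset(("x", "y", "z"))] == 0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            venn_overlap({"only": ["ADLDEFGHI"]})

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_partition(self, data):
        pool = [f"ADLDEFG{x}{y}" for x in "ACDEFGHIKL" for y in "ACDEFGHIKL"]
        sets = {
            g: data.draw(st.lists(st.sampled_from(pool), max_size=40))
            for g in ("a", "b", "c")
        }
        regions = venn_overlap(sets)
        oracle = _venn_oracle({g: set(s) for g, s in sets.items()})
        assert regions == oracle


class TestDifferentialSourceProteins:
    def test_identical_groups_yield_null_result(self):
        expr = {"P1": [20.0, 21.0, 22.0]}
        df = differential_source_proteins(expr, expr)
        assert df.loc[0, "log2fc"] == 0.0
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_unit_shift_in_log2_space(self, rng):
        jitter = rng.normal(0, 1e-6, size=3)
        a = {"P1": 2.0 + jitter}
        b = {"P1": 1.0 + jitter}
        df = differential_source_proteins(a, b)
        assert df.loc[0, "log2fc"] == pytest.approx(1.0, abs=1e-5)
        assert df.loc[0, "p_value"] < 0.01

    def test_zero_variance_equal_means_p_is_one(self):
        df = differential_source_proteins({"P": [1.0, 1.0]}, {"P": [1.0, 1.0]})
        assert df.loc[0, "p_value"] == 1.0

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            differential_source_proteins({"P": [1.0]}, {"P": [1.0, 2.0]})

    def test_log2_excludes_nonpositive(self, caplog):
        from sahapep.repertoire import log2_expression

        with caplog.at_level("WARNING", logger="sahapep"):
            out = log2_expression({"P": [4.0, 0.0, -2.0]})
        assert list(out["P"]) == [2.0]
        assert "non-positive" in caplog.text
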