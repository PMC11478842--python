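"""SNP/indel calling, Ts/Tv, nucleotide diversity, hotspots, p-distances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plastomarker.core import AlignmentMatrix
from plastomarker import io as pio
from plastomarker.variation import (
    call_indels,
    call_snps,
    classify_substitution,
    locus_pi,
    locus_table,
    pairwise_p_distance,
    intraspecific_diversity,
    rank_hotspots,
    substitution_summary,
    window_pi,
)

from .oracles import pi_oracle


def aln_of(rows: dict[str, str], ref: str) -> AlignmentMatrix:
    return AlignmentMatrix(
        list(rows), list(rows.values()), {k: k for k in rows}, ref
    )


class TestClassifySubstitution:
    def test_enumeration_four_ts_eight_tv(self):
        pairs = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
        ts = [p for p in pairs if classify_substitution(*p) == "Ts"]
        tv = [p for p in pairs if classify_substitution(*p) == "Tv"]
        assert len(ts) == 4 and len(tv) == 8
        assert ("A", "G") in ts and ("A", "C") in tv


class TestCallSnps:
    def test_single_difference(self):
        aln = aln_of({"r": "ACGT", "q": "ACGA"}, "r")
        snps = call_snps(aln, "q")
        assert len(snps) == 1
        s = snps[0]
        assert (s.ref_pos, s.ref_allele, s.alt_allele, s.ts_tv) == (
            3, "T", "A", "Tv"
        )

    def test_gap_column_skipped(self):
        aln = aln_of({"r": "AC-T", "q": "ACGT"}, "r")
        assert call_snps(aln, "q") == []

    def test_query_equals_reference_empty(self):
        aln = aln_of({"r": "ACGT", "q": "AAAA"}, "r")
        assert call_snps(aln, "r") == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 200))
    def test_count_equals_hamming_on_gapfree_pairs(self, seed, n):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), n))
        b = "".join(rng.choice(list("ACGT"), n))
        aln = aln_of({"r": a, "q": b}, "r")
        hamming = sum(x != y for x, y in zip(a, b))
        assert len(call_snps(aln, "q")) == hamming


class TestCallIndels:
    def test_deletion_event(self):
        aln = aln_of({"r": "ACGTACGT", "q": "ACG--CGT"}, "r")
        events = call_indels(aln, "q")
        assert [(e.kind, e.length) for e in events] == [("deletion", 2)]

    def test_insertion_event(self):
        aln = aln_of({"r": "A---T", "q": "ACGGT"}, "r")
        events = call_indels(aln, "q")
        assert [(e.kind, e.length) for e in events] == [("insertion", 3)]

    def test_double_gap_columns_ignored(self):
        aln = aln_of({"r": "A--T", "q": "A--T"}, "r")
        assert call_indels(aln, "q") == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_gap_bases_equal_sum_of_event_lengths(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        r = rng.choice(list("ACGT-"), n, p=[0.22, 0.22, 0.22, 0.22, 0.12])
        q = rng.choice(list("ACGT-"), n, p=[0.22, 0.22, 0.22, 0.22, 0.12])
        aln = aln_of({"r": "".join(r), "q": "".join(q)}, "r")
        events = call_indels(aln, "q")
        single_gaps = sum(
            1 for x, y in zip(r, q) if (x == "-") != (y == "-")
        )
        assert sum(e.length for e in events) == single_gaps


class TestWindowPi:
    def test_identical_rows_zero(self):
        aln = aln_of({"a": "ACGT" * 50, "b": "ACGT" * 50}, "a")
        df = window_pi(aln, window=100, step=100)
        assert (df.pi == 0).all()

    def test_hand_computed_value(self):
        aln = aln_of({"a": "ACGT", "b": "ACGA", "c": "ACGT"}, "a")
        df = window_pi(aln, window=4, step=4)
        assert df.pi.iloc[0] == pytest.approx((1 / 4 + 0 + 1 / 4) / 3)

    def test_matches_pair_enumeration_oracle(self, rng):
        """π equals explicit pair enumeration for n <= 6 rows."""
        for n_rows in (2, 3, 4, 5, 6):
            rows = {}
            for i in range(n_rows):
                rows[f"s{i}"] = "".join(
                    rng.choice(list("ACGT-N"), 80,
                               p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06])
                )
            aln = aln_of(rows, "s0")
            df = window_pi(aln, window=80, step=80)
            expect = pi_oracle(list(rows.values()))
            assert df.pi.iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_duplicate_row_changes_pi_through_pair_weighting(self, rng):
        rows = {
            "a": "".join(rng.choice(list("ACGT"), 60)),
            "b": "".join(rng.choice(list("ACGT"), 60)),
        }
        rows2 = dict(rows, c=rows["a"])
        pi2 = window_pi(aln_of(rows, "a"), 60, 60).pi.iloc[0]
        pi3 = window_pi(aln_of(rows2, "a"), 60, 60).pi.iloc[0]
        assert pi3 == pytest.approx(pi_oracle(list(rows2.values())))
        assert pi3 == pytest.approx(2 / 3 * pi2)

    def test_all_gap_window_flagged_undefined(self):
        aln = aln_of({"a": "----ACGT", "b": "----ACGT"}, "a")
        df = window_pi(aln, window=4, step=4)
        assert not df.defined.iloc[0]
        assert df.defined.iloc[1]


class TestLocusPi:
    def _dataset_tables(self, ds):
        aln = ds.alignment
        ref = ds.records[aln.reference_id]
        ann = pio.annotate_regions(ref)
        part = ds.truth["partitions"][aln.reference_id]
        return locus_table(aln, ann, part), ann

    def test_identical_rows_zero(self):
        from plastomarker.core import GeneFeature, PlastomeRecord

        seq = "ACGT" * 25
        rec = PlastomeRecord("r", "s", seq,
                             [GeneFeature("g", "CDS", "+", [(0, 100)])])
        ann = pio.annotate_regions(rec)
        aln = aln_of({"r": seq, "q": seq}, "r")
        table = locus_table(aln, ann)
        assert (table.pi == 0).all()

    def test_planted_hotspot_ranks_first(self, compact_dataset):
        table, _ = self._dataset_tables(compact_dataset)
        hotspot_name = compact_dataset.truth["hotspot"][2]
        ranked = rank_hotspots(table, k=5)
        assert ranked.iloc[0].locus == hotspot_name

    def test_class_mean_is_unweighted_mean(self, compact_dataset):
        ds = compact_dataset
        aln = ds.alignment
        ann = pio.annotate_regions(ds.records[aln.reference_id])
        table, means = locus_pi(aln, ann)
        for cls, grp in table.dropna(subset=["pi"]).groupby("class"):
            assert means[cls] == pytest.approx(grp.pi.mean())


class TestRankHotspots:
    def _table(self):
        return pd.DataFrame(
            {
                "locus": ["a", "b", "c", "d"],
                "class": ["IGS"] * 4,
                "pi": [0.01, 0.05, 0.03, 0.05],
                "indel_diversity": [0.0] * 4,
                "mutations": [1, 9, 3, 2],
                "length": [100] * 4,
                "polymorphic_columns": [1, 9, 3, 2],
            }
        )

    def test_k_larger_than_table(self):
        assert len(rank_hotspots(self._table(), k=20)) == 4

    def test_order_invariance(self):
        t = self._table()
        shuffled = t.sample(frac=1.0, random_state=7)
        assert rank_hotspots(t, 3).locus.tolist() == \
            rank_hotspots(shuffled, 3).locus.tolist()

    def test_tie_broken_by_mutations(self):
        ranked = rank_hotspots(self._table(), 4)
        assert ranked.locus.tolist() == ["b", "d", "c", "a"]


class TestPDistance:
    def test_identical_pair_zero(self):
        aln = aln_of({"a": "ACGT" * 25, "b": "ACGT" * 25}, "a")
        d = pairwise_p_distance(aln)
        assert d.loc["a", "b"] == 0

    def test_one_diff_over_100(self):
        s = "ACGT" * 25
        q = "T" + s[1:]
        aln = aln_of({"a": s, "b": q}, "a")
        assert pairwise_p_distance(aln).loc["a", "b"] == pytest.approx(0.01)

    def test_symmetric_zero_diagonal(self, rng):
        rows = {
            f"s{i}": "".join(rng.choice(list("ACGT-"), 100)) for i in range(4)
        }
        d = pairwise_p_distance(aln_of(rows, "s0"))
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)

    def test_intraspecific_diversity_groups_by_species(self, compact_dataset):
        div = intraspecific_diversity(compact_dataset.alignment)
        assert set(div) == {"P_lanceolata"}  # only species with 2 accessions
        assert 0 <= div["P_lanceolata"] < 0.01


class TestSummaries:
    def test_ts_plus_tv_equals_total(self, compact_dataset):
        aln = compact_dataset.alignment
        snps = {
            acc: call_snps(aln, acc)
            for acc in aln.ids if acc != aln.reference_id
        }
        table = substitution_summary(snps)
        assert (table["Ts"] + table["Tv"] == table["Total"]).all()
        pair_cols = ["A/G", "C/T", "A/C", "C/G", "G/T", "A/T"]
        assert (table[pair_cols].sum(axis=1) == table["Total"]).all()
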