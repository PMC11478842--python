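"""SSR, dispersed and tandem repeat detection against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastomarker.core import revcomp
from plastomarker import io as pio
from plastomarker.repeats import (
    attribute_repeats,
    canonical_motif,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
)

from .conftest import random_seq
from .oracles import dispersed_oracle, ssr_oracle


def ssr_tuples(calls):
    return sorted(
        (c.motif, c.unit_len, c.copies, c.start, c.end) for c in calls
    )


class TestFindSSRs:
    def test_mononucleotide_threshold(self):
        assert len(find_ssrs("AAAAAAA")) == 1
        assert find_ssrs("AAAAAA") == []

    def test_dinucleotide_threshold(self):
        calls = find_ssrs("ATATATAT")
        assert len(calls) == 1
        assert (calls[0].motif, calls[0].copies) == ("AT", 4)
        assert find_ssrs("ATATAT") == []

    def test_homopolymer_not_reported_at_larger_period(self):
        calls = find_ssrs("G" + "A" * 8 + "G")
        assert len(calls) == 1
        assert calls[0].unit_len == 1

    def test_canonical_motif_minimal_rotation(self):
        assert canonical_motif("TA") == "AT"
        assert canonical_motif("GAA") == "AAG"
        calls = find_ssrs("GG" + "TA" * 5 + "GG")
        assert calls[0].motif == "AT"

    def test_n_breaks_runs(self):
        assert find_ssrs("AAAANAAAA") == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_bruteforce_oracle_on_repeatful_sequences(self, seed):
        rng = np.random.default_rng(seed)
        # low-cardinality alphabet chunks make SSRs frequent
        chunks = []
        for _ in range(40):
            if rng.random() < 0.4:
                motif = "".join(rng.choice(list("ACGT"),
                                           rng.integers(1, 4)))
                chunks.append(motif * int(rng.integers(2, 10)))
            else:
                chunks.append(
                    "".join(rng.choice(list("AT"), rng.integers(3, 12)))
                )
        seq = "".join(chunks)
        assert ssr_tuples(find_ssrs(seq)) == sorted(
            ssr_oracle(seq), key=lambda r: (r[3], r[1])
        ) or ssr_tuples(find_ssrs(seq)) == sorted(ssr_oracle(seq))

    def test_maximality_no_call_extendable(self, rng):
        seq = "".join(rng.choice(list("AT"), 2000))
        for c in find_ssrs(seq):
            unit = seq[c.start : c.start + c.unit_len]
            if c.start >= c.unit_len:
                assert seq[c.start - c.unit_len : c.start] != unit


class TestFindDispersedRepeats:
    def test_planted_forward_copy(self, rng):
        """A planted 40 bp duplicate surfaces as an F call whose maximal
        window covers both planted occurrences."""
        s = random_seq(rng, 3000)
        seg = s[100:140]
        seq = s[:1200] + seg + s[1200:]
        calls = find_dispersed_repeats(seq)
        assert any(
            c.kind == "F" and c.length >= 40
            and c.pos1 <= 100 and c.pos1 + c.length >= 140
            for c in calls
        )

    def test_planted_palindromic_copy(self, rng):
        s = random_seq(rng, 3000)
        seg = s[100:140]
        seq = s[:2000] + revcomp(seg) + s[2000:]
        assert any(
            c.kind == "P" and c.length >= 40
            and c.pos1 <= 100 and c.pos1 + c.length >= 140
            for c in find_dispersed_repeats(seq)
        )

    def test_swap_invariance_of_kind(self, rng):
        """pos1/pos2 are stored sorted, so classification does not depend
        on which occurrence is seen first."""
        s = random_seq(rng, 2000)
        seq = s + s[500:540] + s[-200:]
        for c in find_dispersed_repeats(seq):
            assert c.pos1 < c.pos2

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), 700))
        # plant 2-3 degraded copies in assorted orientations
        seq = base
        for kind in rng.choice(["F", "P", "R", "C"], size=2, replace=False):
            src = int(rng.integers(0, 400))
            L = int(rng.integers(32, 60))
            seg = list(base[src : src + L])
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, L))
                seg[i] = rng.choice([b for b in "ACGT" if b != seg[i]])
            seg = "".join(seg)
            if kind == "P":
                seg = revcomp(seg)
            elif kind == "R":
                seg = seg[::-1]
            elif kind == "C":
                seg = revcomp(seg)[::-1]
            at = int(rng.integers(450, len(seq) - 1))
            seq = seq[:at] + seg + seq[at:]
        impl = {
            (c.kind, c.length, c.pos1, c.pos2, c.mismatches)
            for c in find_dispersed_repeats(seq, max_results=10_000)
        }
        assert impl == set(dispersed_oracle(seq))

    def test_result_cap_by_descending_length(self, rng):
        s = random_seq(rng, 500)
        seq = s + s + s  # repeat-rich
        calls = find_dispersed_repeats(seq, max_results=5)
        assert len(calls) <= 5
        lengths = [c.length for c in calls]
        assert lengths == sorted(lengths, reverse=True)


class TestFindTandemRepeats:
    def test_planted_exact_array(self, rng):
        s = random_seq(rng, 1500)
        unit = s[700:730]
        seq = s[:500] + unit * 3 + s[500:1000]
        calls = [c for c in find_tandem_repeats(seq) if c.period == 30]
        assert len(calls) == 1
        c = calls[0]
        assert round(c.copies) == 3
        # span covers the planted array (short chance extensions allowed)
        assert c.start <= 500 and c.end >= 590
        assert c.end - c.start <= 100

    def test_random_sequence_usually_empty_and_self_consistent(self, rng):
        for _ in range(5):
            seq = random_seq(rng, 1000)
            for c in find_tandem_repeats(seq):
                assert c.span_length == pytest.approx(c.period * c.copies,
                                                      rel=0.25)
                assert c.period >= 7

    def test_mutated_array_still_detected(self, rng):
        s = random_seq(rng, 1500)
        unit = s[700:730]
        arr = list(unit * 4)
        for idx in rng.choice(len(arr), size=12, replace=False):
            arr[idx] = rng.choice([b for b in "ACGT" if b != arr[idx]])
        seq = s[:500] + "".join(arr) + s[500:1000]
        calls = find_tandem_repeats(seq)
        assert any(
            c.period == 30 and c.start < 530 and c.end > 590 for c in calls
        )


class TestAttributeRepeats:
    def test_attribution_and_conservation(self, compact_dataset):
        acc = "P_lanceolata_01"
        rec = compact_dataset.records[acc]
        part = compact_dataset.truth["partitions"][acc]
        ann = pio.annotate_regions(rec)
        ssrs = find_ssrs(rec.sequence)
        table = attribute_repeats(ssrs, part, ann)
        assert len(table) == len(ssrs)  # every call attributed exactly once
        assert set(table.structural_region) <= {"LSC", "SSC", "IR"}
        assert set(table.functional_region) <= {"CDS", "intron", "IGS"}

    def test_call_in_known_region(self, compact_dataset):
        acc = "P_lanceolata_01"
        rec = compact_dataset.records[acc]
        part = compact_dataset.truth["partitions"][acc]
        ann = pio.annotate_regions(rec)
        truth = compact_dataset.truth["ssr_loci"]
        mine = truth[truth.accession == acc]
        ssrs = find_ssrs(rec.sequence)
        table = attribute_repeats(ssrs, part, ann)
        # planted loci live in single-copy non-exonic sequence
        for _, t in mine.iterrows():
            hit = table[(table.start <= t.start) & (table.end >= t.end)]
            if len(hit):
                assert set(hit.structural_region) <= {"LSC", "SSC"}
                assert set(hit.functional_region) <= {"IGS", "intron"}
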