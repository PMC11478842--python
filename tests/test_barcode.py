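"""Diagnostic SNP discovery, allele-specific primer design, in-silico PCR."""

import numpy as np
import pytest

from plastomarker.core import AlignmentMatrix, PlastomeRecord, revcomp
from plastomarker.barcode import (
    PrimerConstraints,
    PrimerPair,
    design_control_pair,
    design_diagnostic_pair,
    find_diagnostic_snps,
    in_silico_pcr,
    primer_tm,
)

from .conftest import random_seq


def aln_for(rows, species, ref):
    return AlignmentMatrix(list(rows), list(rows.values()), species, ref)


def toy_alignment(rng, n_target=3, n_background=4, length=200, col=100):
    base = random_seq(rng, length)
    rows, species = {}, {}
    for i in range(n_target):
        rows[f"t{i}"] = base[:col] + "T" + base[col + 1 :]
        species[f"t{i}"] = "target"
    for i in range(n_background):
        rows[f"b{i}"] = base[:col] + "C" + base[col + 1 :]
        species[f"b{i}"] = f"bg{i % 2}"
    return aln_for(rows, species, "b0")


class TestFindDiagnosticSNPs:
    def test_toy_fixed_column_found(self, rng):
        aln = toy_alignment(rng)
        snps = find_diagnostic_snps(aln, "target")
        assert len(snps) == 1
        s = snps[0]
        assert s.column == 100 and s.target_allele == "T"
        assert s.background_alleles == ("C",)
        assert s.flank_conservation == 1.0

    def test_polymorphic_within_target_excluded(self, rng):
        aln = toy_alignment(rng)
        rows = {a: aln.row_str(a) for a in aln.ids}
        rows["t2"] = rows["t2"][:100] + "C" + rows["t2"][101:]
        aln2 = aln_for(rows, aln.species_of, "b0")
        assert find_diagnostic_snps(aln2, "target") == []

    def test_gap_in_column_excluded(self, rng):
        aln = toy_alignment(rng)
        rows = {a: aln.row_str(a) for a in aln.ids}
        rows["b3"] = rows["b3"][:100] + "-" + rows["b3"][101:]
        aln2 = aln_for(rows, aln.species_of, "b0")
        assert find_diagnostic_snps(aln2, "target") == []

    def test_absent_target_species_rejected(self, rng):
        with pytest.raises(ValueError, match="not in alignment"):
            find_diagnostic_snps(toy_alignment(rng), "nosuch")

    def test_planted_columns_recovered_exactly(self, compact_dataset):
        ds = compact_dataset
        snps = find_diagnostic_snps(ds.alignment, "P_lanceolata",
                                    min_flank_conservation=0.0)
        truth = set(ds.truth["diagnostic_columns"]["alignment_column"])
        assert {s.column for s in snps} == truth

    def test_adding_background_can_only_shrink(self, compact_dataset):
        """Monotonicity: restricting to fewer background rows yields a
        superset of the diagnostic columns of the full alignment."""
        aln = compact_dataset.alignment
        full = {s.column for s in find_diagnostic_snps(aln, "P_lanceolata",
                                                       0.0)}
        keep = [a for a in aln.ids
                if aln.species_of[a] in ("P_lanceolata", "P_argentea")]
        sub = AlignmentMatrix(
            keep, [aln.row_str(a) for a in keep],
            {a: aln.species_of[a] for a in keep}, keep[-1],
        )
        reduced = {
            s.column for s in find_diagnostic_snps(sub, "P_lanceolata", 0.0)
        }
        assert full <= reduced

    def test_brute_force_column_scan_agreement(self, compact_dataset):
        """Zero false diagnostics against a direct per-column predicate."""
        aln = compact_dataset.alignment
        target = [i for i, a in enumerate(aln.ids)
                  if aln.species_of[a] == "P_lanceolata"]
        bg = [i for i in range(aln.n_rows) if i not in target]
        M = aln.matrix
        expected = set()
        for col in range(aln.n_cols):
            column = M[:, col]
            if any(chr(b) not in "ACGT" for b in column):
                continue
            t_alleles = {column[i] for i in target}
            if len(t_alleles) != 1:
                continue
            allele = next(iter(t_alleles))
            if all(column[i] != allele for i in bg):
                expected.add(col)
        got = {s.column for s in find_diagnostic_snps(aln, "P_lanceolata",
                                                      0.0)}
        assert got == expected


class TestDesignDiagnosticPair:
    def test_pairs_anchor_three_prime_on_target_allele(self, compact_dataset):
        from plastomarker.barcode import find_diagnostic_snps

        aln = compact_dataset.alignment
        snps = find_diagnostic_snps(aln, "P_lanceolata")
        pairs = design_diagnostic_pair(aln, snps)
        assert pairs
        for p in pairs:
            up, down = p.anchor_snps
            assert p.forward[-1] == up.target_allele
            # reverse primer 3' end is the complement of the target allele
            assert p.reverse[-1] == revcomp(down.target_allele)
            c = PrimerConstraints()
            assert c.min_len <= len(p.forward) <= c.max_len
            assert c.min_gc <= p.gc_forward <= c.max_gc
            assert c.min_tm <= p.tm_forward <= c.max_tm
            assert c.min_product <= p.product_size <= c.max_product

    def test_close_snps_yield_empty_under_default_product_range(self, rng):
        base = random_seq(rng, 400)
        rows, species = {}, {}
        for i in range(2):
            r = list(base)
            r[150], r[180] = "T", "T"
            rows[f"t{i}"] = "".join(r)
            species[f"t{i}"] = "target"
        for i in range(2):
            r = list(base)
            r[150], r[180] = "C", "C"
            rows[f"b{i}"] = "".join(r)
            species[f"b{i}"] = "bg"
        aln = aln_for(rows, species, "b0")
        snps = find_diagnostic_snps(aln, "target")
        assert len(snps) == 2
        assert design_diagnostic_pair(aln, snps) == []


class TestDesignControlPair:
    def test_fully_invariant_alignment_deterministic(self, rng):
        seq = random_seq(rng, 1200)
        rows = {f"a{i}": seq for i in range(4)}
        species = {f"a{i}": f"sp{i}" for i in range(4)}
        aln = aln_for(rows, species, "a0")
        p1 = design_control_pair(aln)
        p2 = design_control_pair(aln)
        assert p1 == p2
        assert p1.product_size == pytest.approx(400, abs=60)

    def test_primers_confined_to_invariant_block(self, rng):
        seq = random_seq(rng, 2400)
        rows = {}
        species = {}
        for i in range(4):
            # variable everywhere except one central 1 kb block
            s = list(random_seq(rng, 2400))
            s[700:1700] = seq[700:1700]
            rows[f"a{i}"] = "".join(s)
            species[f"a{i}"] = f"sp{i}"
        aln = aln_for(rows, species, "a0")
        p = design_control_pair(aln)
        assert 700 <= p.forward_start and p.reverse_start + 18 <= 1700

    def test_no_invariant_run_rejected(self, rng):
        rows = {
            "a": random_seq(rng, 300),
            "b": random_seq(rng, 300),
        }
        aln = aln_for(rows, {"a": "x", "b": "y"}, "a")
        with pytest.raises(ValueError):
            design_control_pair(aln)

    def test_control_amplifies_every_accession(self, compact_dataset):
        ds = compact_dataset
        pair = design_control_pair(ds.alignment)
        for rec in ds.records.values():
            assert len(in_silico_pcr(rec, pair)) == 1


class TestInSilicoPCR:
    def _pair(self, fwd, rev):
        return PrimerPair(forward=fwd, reverse=rev, forward_start=0,
                          reverse_start=0, product_size=0, role="control")

    def test_perfect_pair_single_amplicon(self, rng):
        seq = random_seq(rng, 2000)
        fwd = seq[100:120]
        rev = revcomp(seq[580:600])
        amps = in_silico_pcr(seq, self._pair(fwd, rev), circular=False)
        assert len(amps) == 1
        assert amps[0].size == 500
        assert amps[0].start == 100

    def test_three_prime_mismatch_blocks_amplification(self, rng):
        seq = random_seq(rng, 2000)
        fwd = seq[100:120]
        bad = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
        rev = revcomp(seq[580:600])
        assert in_silico_pcr(seq, self._pair(bad, rev), circular=False) == []
        relaxed = in_silico_pcr(seq, self._pair(bad, rev),
                                three_prime_strict=False, circular=False)
        assert len(relaxed) == 1

    def test_internal_mismatches_tolerated_up_to_two(self, rng):
        seq = random_seq(rng, 2000)
        fwd = list(seq[100:120])
        for i in (3, 9):
            fwd[i] = "A" if fwd[i] != "A" else "C"
        rev = revcomp(seq[580:600])
        amps = in_silico_pcr(seq, self._pair("".join(fwd), rev),
                             circular=False)
        assert len(amps) == 1
        fwd[14] = "A" if fwd[14] != "A" else "C"  # third internal mismatch
        assert in_silico_pcr(seq, self._pair("".join(fwd), rev),
                             circular=False) == []

    def test_diagnostic_pair_specificity(self, compact_dataset):
        from plastomarker.barcode import find_diagnostic_snps

        ds = compact_dataset
        aln = ds.alignment
        pairs = design_diagnostic_pair(
            aln, find_diagnostic_snps(aln, "P_lanceolata")
        )
        pair = pairs[0]
        for acc, rec in ds.records.items():
            amps = in_silico_pcr(rec, pair)
            if aln.species_of[acc] == "P_lanceolata":
                assert len(amps) == 1
                assert amps[0].size == pair.product_size
            else:
                assert amps == []

    def test_amplicon_across_origin(self, rng):
        seq = random_seq(rng, 3000)
        rot = seq[2800:] + seq[:2800]  # binding sites straddle the origin
        fwd = seq[2900:2920]
        rev = revcomp(seq[200:220])
        amps = in_silico_pcr(rot, self._pair(fwd, rev))
        assert len(amps) == 1
        assert amps[0].size == 320


class TestPrimerTm:
    def test_gc_monotonicity(self):
        assert primer_tm("G" * 20) > primer_tm("A" * 20)

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(5):
            p = random_seq(rng, 22)
            assert primer_tm(p) == pytest.approx(primer_tm(revcomp(p)),
                                                 abs=1e-6)

    def test_balanced_20mer_in_plausible_range(self, rng):
        p = "AT" * 5 + "GC" * 5
        assert 45 < primer_tm(p) < 70
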