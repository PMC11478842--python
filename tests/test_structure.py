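"""Quadripartite detection, composition and junction reports."""

import numpy as np
import pytest

from plastomarker.core import GeneFeature, PlastomeRecord, revcomp
from plastomarker import io as pio
from plastomarker.structure import (
    NoIRFound,
    canonical_rotation,
    detect_partition,
    gene_content_summary,
    junction_report,
    region_gc,
)

from .conftest import random_seq


def toy_genome(rng, lsc=400, ir=200, ssc=200):
    L = random_seq(rng, lsc)
    I = random_seq(rng, ir)
    S = random_seq(rng, ssc)
    # guard the junction-adjacent bases against chance symmetric extension
    L = "A" + L[1:-1] + "A"
    S = "A" + S[1:-1] + "A"
    return L + I + S + revcomp(I)


class TestDetectPartition:
    def test_toy_construction(self, rng):
        seq = toy_genome(rng)
        part = detect_partition(seq, min_ir_len=100)
        assert part.lengths == {"LSC": 400, "IRb": 200, "SSC": 200, "IRa": 200}
        assert part.lsc == (0, 400)
        assert part.irb == (400, 600)

    def test_no_ir_in_random_sequence(self, rng):
        with pytest.raises(NoIRFound):
            detect_partition(random_seq(rng, 5000), min_ir_len=1000)

    def test_detection_across_origin(self, rng):
        """Rotating the genome so a region wraps the origin preserves the
        detected region lengths."""
        seq = toy_genome(rng)
        part0 = detect_partition(seq, min_ir_len=100)
        for shift in (150, 450, 700, 950):
            rot = seq[shift:] + seq[:shift]
            part = detect_partition(rot, min_ir_len=100)
            assert part.lengths == part0.lengths

    def test_partition_covers_genome(self, compact_dataset):
        for rec in compact_dataset.records.values():
            part = detect_partition(rec.sequence, min_ir_len=1000)
            assert sum(part.lengths.values()) == rec.length

    def test_recovers_planted_boundaries(self, compact_dataset):
        for acc, rec in compact_dataset.records.items():
            truth = compact_dataset.truth["partitions"][acc]
            det = detect_partition(rec.sequence, min_ir_len=1000)
            assert (det.lsc, det.irb, det.ssc, det.ira) == (
                truth.lsc, truth.irb, truth.ssc, truth.ira
            )

    def test_recovers_ir_expansion(self, expansion_dataset):
        ds = expansion_dataset
        normal = ds.truth["partitions"]["P_lanceolata_01"]
        expanded = ds.truth["partitions"]["P_maritima_01"]
        assert expanded.ir_length > normal.ir_length
        for acc, rec in ds.records.items():
            truth = ds.truth["partitions"][acc]
            det = detect_partition(rec.sequence, min_ir_len=1000)
            assert det.lengths == truth.lengths

    def test_mismatch_tolerance_extension(self, rng):
        seq = toy_genome(rng, lsc=800, ir=400, ssc=300)
        part = detect_partition(seq, min_ir_len=100)
        # exact detection unaffected by allowing mismatches
        part2 = detect_partition(seq, min_ir_len=100, max_mismatch_frac=0.02)
        assert part2.ir_length >= part.ir_length


class TestRegionGC:
    def _rec_part(self, seq):
        rec = PlastomeRecord("a", "s", seq)
        part = detect_partition(seq, min_ir_len=50)
        return rec, part

    def test_all_a_sequence_zero(self, rng):
        ir = random_seq(rng, 100)
        seq = "A" * 200 + ir + "A" * 100 + revcomp(ir)
        rec, part = self._rec_part(seq)
        gc = region_gc(rec, part)
        assert gc["LSC"] == 0.0 and gc["SSC"] == 0.0

    def test_uniform_half_gc(self):
        ir = "ACGT" * 30
        # ACGT-repeat IR is self-complementary under revcomp; build an
        # explicit quadripartite string instead
        rng = np.random.default_rng(5)
        seq = toy_genome(rng)
        rec, part = self._rec_part(seq)
        gc = region_gc(rec, part)
        total = rec.sequence
        expect = (total.count("G") + total.count("C")) / len(total)
        assert gc["total"] == pytest.approx(expect)

    def test_weighted_region_mean_equals_total(self, compact_dataset):
        for acc, rec in compact_dataset.records.items():
            part = compact_dataset.truth["partitions"][acc]
            gc = region_gc(rec, part)
            lens = part.lengths
            weighted = (
                gc["LSC"] * lens["LSC"] + gc["SSC"] * lens["SSC"]
                + gc["IRb"] * lens["IRb"] + gc["IRa"] * lens["IRa"]
            ) / rec.length
            assert weighted == pytest.approx(gc["total"], abs=1e-12)


class TestGeneContent:
    def test_empty_features(self, rng):
        seq = toy_genome(rng)
        rec = PlastomeRecord("a", "s", seq)
        part = detect_partition(seq, min_ir_len=100)
        summary = gene_content_summary(rec, part)
        assert summary["unique_genes"] == 0
        assert summary["duplicated_in_ir"] == 0

    def test_planted_duplicates_counted(self, compact_dataset):
        rec = compact_dataset.records["P_lanceolata_01"]
        part = compact_dataset.truth["partitions"]["P_lanceolata_01"]
        summary = gene_content_summary(rec, part)
        genes = compact_dataset.truth["genes"]
        assert summary["unique_genes"] == len({g.name for g in genes})
        # the planted IR-internal genes are duplicated by assembly
        planted_ir = {g.name for g in genes if g.in_ir}
        assert planted_ir <= set(summary["duplicated_gene_names"])

    def test_intron_gene_counted_once(self, rng):
        seq = toy_genome(rng)
        rec = PlastomeRecord(
            "a", "s", seq,
            [GeneFeature("atpF", "CDS", "+", [(10, 100), (200, 290)],
                         intron_count=1)],
        )
        part = detect_partition(seq, min_ir_len=100)
        summary = gene_content_summary(rec, part)
        assert summary["unique_genes"] == 1
        assert summary["intron_genes"] == ["atpF"]


class TestJunctionReport:
    def test_spanning_gene_side_arithmetic(self, rng):
        seq = toy_genome(rng)  # JSA at 800 (SSC 600..800, IRa 800..1000)
        rec = PlastomeRecord(
            "a", "s", seq, [GeneFeature("ycf1", "CDS", "+", [(790, 850)])]
        )
        part = detect_partition(seq, min_ir_len=100)
        report = junction_report([(rec, part)])
        row = report[report.junction == "JSA"].iloc[0]
        assert (row.left_bases, row.right_bases) == (10, 50)
        assert row.distance == 0

    def test_non_overlapping_gene_convention(self, rng):
        seq = toy_genome(rng)
        rec = PlastomeRecord(
            "a", "s", seq, [GeneFeature("ndhF", "CDS", "-", [(650, 750)])]
        )
        part = detect_partition(seq, min_ir_len=100)
        report = junction_report([(rec, part)])
        row = report[report.junction == "JSA"].iloc[0]
        assert row.gene == "ndhF"
        assert (row.left_bases, row.right_bases) == (0, 100)
        assert row.distance > 0

    def test_sides_sum_to_span(self, compact_dataset):
        records = [
            (rec, compact_dataset.truth["partitions"][acc])
            for acc, rec in compact_dataset.records.items()
        ]
        report = junction_report(records)
        spanning = report[report.distance == 0]
        assert len(spanning) > 0
        for _, row in spanning.iterrows():
            rec = compact_dataset.records[row.accession]
            gene_spans = [
                f.span[1] - f.span[0] if f.span[1] > f.span[0] else 0
                for f in rec.features
                if f.name == row.gene
            ]
            assert row.left_bases + row.right_bases in gene_spans

    def test_matches_planted_junction_truth(self, compact_dataset):
        records = [
            (rec, compact_dataset.truth["partitions"][acc])
            for acc, rec in compact_dataset.records.items()
        ]
        report = junction_report(records).set_index(
            ["accession", "junction", "gene"]
        )
        truth = compact_dataset.truth["junction_spans"]
        checked = 0
        for _, t in truth.iterrows():
            key = (t.accession, t.junction, t.gene)
            if key in report.index:
                row = report.loc[key]
                assert int(row.left_bases) == int(t.left_bases)
                assert int(row.right_bases) == int(t.right_bases)
                checked += 1
        assert checked >= len(compact_dataset.records)  # rps19/ycf1 spans

    def test_pseudogene_fragment_flagged(self, compact_dataset):
        """The truncated rps19 copy mirrored into the IRa is reported as a
        pseudogene fragment near JLA."""
        records = [
            (rec, compact_dataset.truth["partitions"][acc])
            for acc, rec in compact_dataset.records.items()
        ]
        report = junction_report(records)
        frags = report[report.pseudogene_fragment]
        assert (frags.gene == "rps19").any()


class TestCanonicalRotation:
    def test_rotation_puts_lsc_at_zero(self, rng):
        seq = toy_genome(rng)
        rot = seq[250:] + seq[:250]
        part = detect_partition(rot, min_ir_len=100)
        rec = PlastomeRecord("a", "s", rot)
        rec2, part2 = canonical_rotation(rec, part)
        assert part2.lsc[0] == 0
        assert part2.lengths == part.lengths
        # rotated sequence is the original toy layout
        assert rec2.sequence == seq
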