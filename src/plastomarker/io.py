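"""Readers and writers for the formats the pipeline touches.

GenBank and FASTA go through Biopython; variant output is a minimal VCF v4.2
plus TSV tables. Region annotation attaches a functional class (gene region /
intron / IGS) and a locus name to every genome position.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .core import (
    CLS_CDS,
    CLS_IGS,
    CLS_INTRON,
    AlignmentMatrix,
    GeneFeature,
    PlastomeRecord,
    RegionAnnotation,
)

log = logging.getLogger(__name__)

_FEATURE_KINDS = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Read a single circular plastome record from a GenBank flat file.

    CDS/tRNA/rRNA features are captured (a ``/pseudo`` qualifier demotes a
    feature to kind ``pseudogene``); join/complement locations decompose into
    ordered 0-based half-open parts. Unknown feature kinds are skipped with a
    logged warning.
    """
    seqrec = SeqIO.read(str(path), "genbank")
    sequence = str(seqrec.seq).upper()
    if not sequence or set(sequence) == {"N"}:
        raise ValueError(f"{path}: record has no usable sequence")
    features: list[GeneFeature] = []
    skipped: set[str] = set()
    for feat in seqrec.features:
        if feat.type in ("source", "gene", "misc_feature", "repeat_region"):
            continue
        if feat.type not in _FEATURE_KINDS:
            skipped.add(feat.type)
            continue
        kind = _FEATURE_KINDS[feat.type]
        if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
            kind = "pseudogene"
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        parts = sorted(
            (int(p.start), int(p.end)) for p in feat.location.parts
        )
        strand = "-" if (feat.location.strand or 1) < 0 else "+"
        features.append(
            GeneFeature(
                name=name,
                kind=kind,
                strand=strand,
                parts=parts,
                intron_count=len(parts) - 1,
            )
        )
    if skipped:
        log.warning("skipped unknown feature kinds: %s", sorted(skipped))
    return PlastomeRecord(
        accession=seqrec.id or seqrec.name,
        species=seqrec.annotations.get("organism", ""),
        sequence=sequence,
        features=features,
    )


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Emit a PlastomeRecord as a GenBank flat file (inverse of read_genbank)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=f"{record.species} plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": record.species,
        },
    )
    type_of = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "CDS"}
    for gf in record.features:
        strand = -1 if gf.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand) for s, e in gf.parts]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [gf.name]}
        if gf.kind == "pseudogene":
            quals["pseudo"] = [""]
        seqrec.features.append(
            SeqFeature(location, type=type_of[gf.kind], qualifiers=quals)
        )
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """TSV with two columns: accession <tab> species (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: species map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_alignment(
    fasta_path: str | Path, species_tsv: str | Path, reference_id: str
) -> AlignmentMatrix:
    """Load an aligned FASTA plus an accession->species TSV.

    Raises on ragged rows and on accessions absent from the map.
    """
    seqs = read_fasta(fasta_path)
    if not seqs:
        raise ValueError(f"{fasta_path}: empty alignment")
    species_of = read_species_map(species_tsv)
    missing = [a for a in seqs if a not in species_of]
    if missing:
        raise ValueError(f"accessions missing from species map: {missing}")
    return AlignmentMatrix(
        ids=list(seqs), rows=list(seqs.values()), species_of=species_of,
        reference_id=reference_id,
    )


def write_alignment(aln: AlignmentMatrix, path: str | Path) -> None:
    write_fasta({a: aln.row_str(a) for a in aln.ids}, path)


# ---------------------------------------------------------------------------
# region annotation


def annotate_regions(record: PlastomeRecord) -> RegionAnnotation:
    """Assign every genome position to exactly one of {gene region, intron,
    IGS} and name the locus it belongs to.

    Exonic parts of CDS/tRNA/rRNA features are gene regions; gaps between
    parts of one feature are introns; everything else is IGS, with spacers
    named ``upstream-downstream`` from the flanking genes in forward-strand
    order. Overlaps resolve by precedence CDS > tRNA/rRNA > pseudogene.
    """
    n = record.length
    classes = np.full(n, CLS_IGS, dtype=np.uint8)
    locus_index = np.full(n, -1, dtype=np.int32)
    locus_names: list[str] = []
    locus_classes: list[int] = []
    precedence = {"CDS": 0, "tRNA": 1, "rRNA": 1, "pseudogene": 2}
    claimed = np.zeros(n, dtype=bool)

    def add_locus(name: str, cls: int) -> int:
        locus_names.append(name)
        locus_classes.append(cls)
        return len(locus_names) - 1

    overlaps = 0
    for gf in sorted(record.features, key=lambda f: precedence.get(f.kind, 3)):
        gene_locus = add_locus(gf.name, CLS_CDS)
        segs = [(s, e, CLS_CDS, gene_locus) for s, e in gf.parts]
        for i, ((_, e_prev), (s_next, _)) in enumerate(
            zip(gf.parts, gf.parts[1:]), start=1
        ):
            if s_next > e_prev:
                intron_locus = add_locus(f"{gf.name}_intron{i}", CLS_INTRON)
                segs.append((e_prev, s_next, CLS_INTRON, intron_locus))
        for s, e, cls, locus in segs:
            idx = np.arange(s, e) % n
            free = ~claimed[idx]
            if not free.all():
                overlaps += 1
            classes[idx[free]] = cls
            locus_index[idx[free]] = locus
            claimed[idx] = True
    if overlaps:
        log.info("%d feature segments overlapped previously claimed bases", overlaps)

    # name IGS runs from flanking genes (forward-strand order, circular)
    gene_feats = sorted(record.features, key=lambda f: f.start)
    igs_mask = classes == CLS_IGS
    if igs_mask.any():
        runs = _bool_runs(igs_mask)
        for s, e in runs:
            if gene_feats:
                up = _nearest_gene_before(gene_feats, s, n)
                down = _nearest_gene_after(gene_feats, e, n)
                name = f"{up}-{down}" if up != down else f"{up}-circle"
            else:
                name = "IGS"
            locus = len(locus_names)
            locus_names.append(name)
            locus_classes.append(CLS_IGS)
            locus_index[s:e] = locus
    return RegionAnnotation(classes, locus_index, locus_names, locus_classes)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _nearest_gene_before(feats, pos: int, n: int) -> str:
    best, best_d = feats[-1].name, None
    for f in feats:
        d = (pos - f.end) % n
        if best_d is None or d < best_d:
            best, best_d = f.name, d
    return best


def _nearest_gene_after(feats, pos: int, n: int) -> str:
    best, best_d = feats[0].name, None
    for f in feats:
        d = (f.start - pos) % n
        if best_d is None or d < best_d:
            best, best_d = f.name, d
    return best


# ---------------------------------------------------------------------------
# variant tables


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=plastomarker
##contig=<ID={chrom},length={length}>
##INFO=<ID=ACC,Number=1,Type=String,Description="Query accession">
##INFO=<ID=TSTV,Number=1,Type=String,Description="Transition or transversion">
##INFO=<ID=SREG,Number=1,Type=String,Description="Structural region">
##INFO=<ID=FREG,Number=1,Type=String,Description="Functional region">
##INFO=<ID=LOCUS,Number=1,Type=String,Description="Locus name">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variant_tables(
    snps,
    indels,
    out_prefix: str | Path,
    reference_id: str = "reference",
    reference_length: int = 0,
) -> dict[str, Path]:
    """Write SNPs as minimal VCF (1-based POS) and indels as TSV.

    Returns the paths written, keyed ``snps_vcf`` and ``indels_tsv``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = out_prefix.with_suffix(".vcf")
    tsv_path = out_prefix.parent / (out_prefix.name + "_indels.tsv")

    with open(vcf_path, "w") as fh:
        fh.write(
            VCF_HEADER.format(chrom=reference_id, length=max(reference_length, 1))
        )
        for s in sorted(snps, key=lambda s: (s.ref_pos, s.accession)):
            info = (
                f"ACC={s.accession};TSTV={s.ts_tv};SREG={s.structural_region};"
                f"FREG={s.functional_region};LOCUS={s.locus or '.'}"
            )
            fh.write(
                f"{reference_id}\t{s.ref_pos + 1}\t.\t{s.ref_allele}\t"
                f"{s.alt_allele}\t.\t.\t{info}\n"
            )

    rows = [
        {
            "accession": d.accession,
            "ref_pos": d.ref_pos,
            "length": d.length,
            "kind": d.kind,
            "structural_region": d.structural_region,
            "locus": d.locus,
        }
        for d in sorted(indels, key=lambda d: (d.ref_pos, d.accession))
    ]
    pd.DataFrame(
        rows,
        columns=["accession", "ref_pos", "length", "kind", "structural_region", "locus"],
    ).to_csv(tsv_path, sep="\t", index=False)
    return {"snps_vcf": vcf_path, "indels_tsv": tsv_path}


def read_variant_tables(out_prefix: str | Path):
    """Read back tables written by :func:`write_variant_tables` (round-trip)."""
    from .variation import IndelRecord, SNPRecord

    out_prefix = Path(out_prefix)
    snps: list[SNPRecord] = []
    with open(out_prefix.with_suffix(".vcf")) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in info.split(";"))
            snps.append(
                SNPRecord(
                    ref_pos=int(pos) - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    accession=kv["ACC"],
                    ts_tv=kv["TSTV"],
                    structural_region=kv["SREG"],
                    functional_region=kv["FREG"],
                    locus="" if kv["LOCUS"] == "." else kv["LOCUS"],
                )
            )
    df = pd.read_csv(
        out_prefix.parent / (out_prefix.name + "_indels.tsv"), sep="\t"
    )
    indels = [
        IndelRecord(
            ref_pos=int(r.ref_pos),
            length=int(r.length),
            kind=str(r.kind),
            accession=str(r.accession),
            structural_region=str(r.structural_region),
            locus="" if pd.isna(r.locus) else str(r.locus),
        )
        for r in df.itertuples()
    ]
    return snps, indels
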