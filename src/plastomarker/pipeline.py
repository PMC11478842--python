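"""End-to-end orchestration: structure -> variation -> repeats -> codon
usage/selection -> barcode, writing one report directory of TSV/VCF/BED
tables plus a run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, barcode, codon, io as pio, repeats, structure, variation
from .core import PlastomeRecord

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "records", "alignment", "species_map", "reference_id", "target_species",
    "out_dir", "seed", "stages", "window", "step", "hotspot_k",
    "primer", "min_ir_len", "ssr_thresholds",
}
ALL_STAGES = ("structure", "variation", "repeats", "codon", "barcode")


@dataclass
class PipelineConfig:
    records: list[str]  # GenBank paths
    alignment: str
    species_map: str
    reference_id: str
    target_species: str = ""
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    window: int = 100
    step: int = 100
    hotspot_k: int = 20
    min_ir_len: int = 1000
    primer: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured stages in order on all inputs; returns the report
    directory. Any stage failure halts with a stage-tagged error; outputs
    written so far are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: %d stages -> %s", len(config.stages), out)

    records = [pio.read_genbank(p) for p in config.records]
    aln = pio.read_alignment(config.alignment, config.species_map,
                             config.reference_id)
    ref_record = next(
        (r for r in records if r.accession == config.reference_id), None
    )

    parts: dict[str, structure.QuadripartitePartition | None] = {}
    annotations = {}
    for rec in records:
        try:
            parts[rec.accession] = structure.detect_partition(
                rec.sequence, min_ir_len=config.min_ir_len
            )
        except structure.NoIRFound:
            log.warning("%s: no IR found; treated as IR-lacking", rec.accession)
            parts[rec.accession] = None
        annotations[rec.accession] = pio.annotate_regions(rec)
    ref_part = parts.get(config.reference_id)
    ref_ann = annotations.get(config.reference_id)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "records"
        },
        "records": [r.accession for r in records],
    }

    if "structure" in config.stages:
        _stage_structure(records, parts, annotations, out)
    if "variation" in config.stages:
        _stage_variation(aln, ref_part, ref_ann, config, out)
    if "repeats" in config.stages:
        _stage_repeats(records, parts, annotations, out)
    if "codon" in config.stages:
        _stage_codon(records, out)
    if "barcode" in config.stages and config.target_species:
        _stage_barcode(aln, records, config, out)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete")
    return out


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kw):
            log.info("stage %s", name)
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


@_stage("structure")
def _stage_structure(records, parts, annotations, out: Path):
    rows = []
    beds = []
    for rec in records:
        part = parts[rec.accession]
        if part is None:
            continue
        gc = structure.region_gc(rec, part, annotations[rec.accession])
        summary = structure.gene_content_summary(rec, part)
        rows.append(
            {
                "accession": rec.accession,
                "species": rec.species,
                "length": rec.length,
                **{f"len_{k}": v for k, v in part.lengths.items()},
                **{f"gc_{k}": round(v, 4) for k, v in gc.items()},
                "unique_genes": summary["unique_genes"],
                "duplicated_in_ir": summary["duplicated_in_ir"],
            }
        )
        beds.append(part.to_bed(rec.accession))
    pd.DataFrame(rows).to_csv(out / "table1_structure.tsv", sep="\t",
                              index=False)
    if beds:
        pd.concat(beds).to_csv(out / "partitions.bed", sep="\t", index=False,
                               header=False)
    junc = structure.junction_report(
        [(r, parts[r.accession]) for r in records]
    )
    junc.to_csv(out / "junctions.tsv", sep="\t", index=False)


@_stage("variation")
def _stage_variation(aln, ref_part, ref_ann, config, out: Path):
    snps, indels = {}, {}
    for acc in aln.ids:
        if acc == aln.reference_id:
            continue
        snps[acc] = variation.call_snps(aln, acc, ref_part, ref_ann)
        indels[acc] = variation.call_indels(aln, acc, ref_part, ref_ann)
    variation.substitution_summary(snps).to_csv(
        out / "table3_substitutions.tsv", sep="\t"
    )
    variation.indel_summary(indels).to_csv(
        out / "table4_indels.tsv", sep="\t", index=False
    )
    all_snps = [s for lst in snps.values() for s in lst]
    all_indels = [d for lst in indels.values() for d in lst]
    pio.write_variant_tables(
        all_snps, all_indels, out / "variants", reference_id=aln.reference_id,
        reference_length=len(aln.ungapped(aln.reference_id)),
    )
    variation.window_pi(aln, config.window, config.step).to_csv(
        out / "window_pi.tsv", sep="\t", index=False
    )
    if ref_ann is not None:
        table, class_means = variation.locus_pi(aln, ref_ann, ref_part)
        table.to_csv(out / "locus_pi.tsv", sep="\t", index=False)
        variation.rank_hotspots(table, config.hotspot_k).to_csv(
            out / "table5_hotspots.tsv", sep="\t", index=False
        )
        pd.Series(class_means).to_csv(out / "class_pi.tsv", sep="\t",
                                      header=False)
    variation.pairwise_p_distance(aln).to_csv(out / "p_distance.tsv", sep="\t")


@_stage("repeats")
def _stage_repeats(records, parts, annotations, out: Path):
    ssr_rows, disp_rows, tandem_rows = [], [], []
    for rec in records:
        part = parts[rec.accession]
        ann = annotations[rec.accession]
        ssrs = repeats.find_ssrs(rec.sequence)
        attributed = repeats.attribute_repeats(ssrs, part, ann)
        attributed.insert(0, "accession", rec.accession)
        for (_, row), ssr in zip(attributed.iterrows(), ssrs):
            ssr_rows.append({**row.to_dict(), "motif": ssr.motif,
                             "copies": ssr.copies})
        for d in repeats.find_dispersed_repeats(rec.sequence):
            disp_rows.append(
                {"accession": rec.accession, "kind": d.kind,
                 "length": d.length, "pos1": d.pos1, "pos2": d.pos2,
                 "mismatches": d.mismatches}
            )
        for t in repeats.find_tandem_repeats(rec.sequence):
            tandem_rows.append(
                {"accession": rec.accession, "period": t.period,
                 "copies": t.copies, "start": t.start, "end": t.end}
            )
    pd.DataFrame(ssr_rows).to_csv(out / "ssr.tsv", sep="\t", index=False)
    pd.DataFrame(disp_rows).to_csv(out / "repeats.tsv", sep="\t", index=False)
    pd.DataFrame(tandem_rows).to_csv(out / "tandem.tsv", sep="\t", index=False)


@_stage("codon")
def _stage_codon(records, out: Path):
    rows = []
    for rec in records:
        cds = [
            "".join(rec.sequence[s:e] for s, e in gf.parts)
            for gf in rec.features
            if gf.kind == "CDS"
        ]
        if not cds:
            continue
        table = codon.rscu(cds)
        for c, v in sorted(table.rscu.items()):
            rows.append({"accession": rec.accession, "codon": c,
                         "count": table.codon_counts[c], "rscu": round(v, 4)})
    pd.DataFrame(rows).to_csv(out / "rscu.tsv", sep="\t", index=False)


@_stage("barcode")
def _stage_barcode(aln, records, config, out: Path):
    constraints = barcode.PrimerConstraints(**config.primer)
    snps = barcode.find_diagnostic_snps(aln, config.target_species)
    pd.DataFrame([s.__dict__ for s in snps]).to_csv(
        out / "diagnostic_snps.tsv", sep="\t", index=False
    )
    pairs = barcode.design_diagnostic_pair(aln, snps, constraints)
    rows = []
    all_pairs = list(pairs[:1])
    try:
        all_pairs.append(barcode.design_control_pair(aln, constraints))
    except ValueError as exc:
        log.warning("control pair design failed: %s", exc)
    for p in all_pairs:
        row = {
            "role": p.role, "forward": p.forward, "reverse": p.reverse,
            "product_size": p.product_size,
            "tm_forward": round(p.tm_forward, 2),
            "tm_reverse": round(p.tm_reverse, 2),
            "gc_forward": round(p.gc_forward, 3),
            "gc_reverse": round(p.gc_reverse, 3),
        }
        for rec in records:
            amps = barcode.in_silico_pcr(rec, p)
            row[f"amplicons_{rec.accession}"] = len(amps)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "primers.tsv", sep="\t", index=False)
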