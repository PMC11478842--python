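"""Synthetic plastome families with known truth.

An ancestral quadripartite genome (LSC + IRb + SSC + IRa, IRa the exact
reverse complement of IRb) is evolved along a phylogeny with
region-heterogeneous substitution rates (single-copy regions fast, IR slow,
one designated spacer a mutational hotspot), a two-parameter Ts:Tv kernel,
intergenic indels, SSR slippage, planted species-diagnostic SNPs with
conserved flanks and an optional IR-expansion event that captures the start
of the SSC into the IR.

Evolution happens on the ancestor coordinate frame, so the true alignment is
known by construction and no realignment step separates the generator from
the statistics it is meant to test. Inserted material does not mutate
further and indels are confined to single-copy intergenic spacers; the IR is
concerted by construction (one IR copy is simulated, the genome is assembled
with its reverse complement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import AlignmentMatrix, GeneFeature, PlastomeRecord, revcomp
from . import io as pio

log = logging.getLogger(__name__)

_A, _C, _G, _T = ord("A"), ord("C"), ord("G"), ord("T")
_BASES = np.array([_A, _C, _G, _T], dtype=np.uint8)
# transition partner and the two transversion partners of each base code
_TRANSITION = {_A: _G, _G: _A, _C: _T, _T: _C}
_TRANSVERSIONS = {_A: (_C, _T), _G: (_C, _T), _C: (_A, _G), _T: (_A, _G)}

DEFAULT_TREE = (
    "((((P_lanceolata:0.002,P_argentea:0.002):0.002,P_atrata:0.004):0.006,"
    "P_maritima:0.028):0.001,P_ovata:0.012);"
)

# plastid gene inventory used for naming planted genes (standard symbols)
GENE_NAMES = [
    "psbA", "matK", "rps16", "psbK", "psbI", "atpA", "atpF", "atpH", "atpI",
    "rps2", "rpoC2", "rpoC1", "rpoB", "petN", "psbM", "psbD", "psbC", "psbZ",
    "rps14", "psaB", "psaA", "ycf3", "rps4", "ndhJ", "ndhK", "ndhC", "atpE",
    "atpB", "rbcL", "accD", "psaI", "ycf4", "cemA", "petA", "psbJ", "psbL",
    "psbF", "psbE", "petL", "petG", "psaJ", "rpl33", "rps18", "rpl20", "rps12",
    "clpP", "psbB", "psbT", "psbN", "psbH", "petB", "petD", "rpoA", "rps11",
    "rpl36", "infA", "rps8", "rpl14", "rpl16", "rps3", "rpl22",
]


@dataclass
class DiagnosticPlan:
    target_species: str = "P_lanceolata"
    n_snps: int = 12
    spacing: int = 400  # bp between planted diagnostic columns
    flank: int = 25  # frozen (conserved) flank on each side


@dataclass
class SimulationConfig:
    """Study conditions for one simulated plastome family.

    Defaults mirror a Plantago-like plastome: ~150 kb genome with ~25 kb
    IRs, 38% GC, single-copy substitution rates an order of magnitude above
    the IR, transitions slightly outnumbering transversions, and indels an
    order of magnitude rarer than substitutions.
    """

    seed: int = 0
    genome_length: int = 150_000
    ir_length: int = 25_000
    lsc_length: int | None = None  # default: 82% of the single-copy total
    gc_content: float = 0.38
    gene_count: int = 60
    tree: str = DEFAULT_TREE
    accessions_per_species: dict[str, int] | None = None
    intraspecific_branch: float = 0.0003
    region_rate: dict[str, float] = field(
        default_factory=lambda: {"LSC": 1.0, "SSC": 1.0, "IR": 0.1}
    )
    hotspot_multiplier: float = 6.0
    ts_tv_ratio: float = 1.2
    indel_sub_ratio: float = 0.14  # indel events per substitution
    indel_mean_length: float = 8.0  # geometric
    ssr_loci: int = 12
    ssr_slippage: float = 0.3  # per branch per locus
    diagnostic_plan: DiagnosticPlan | None = field(default_factory=DiagnosticPlan)
    ir_expansion: tuple[str, int] | None = None  # (species, bp captured)

    def __post_init__(self) -> None:
        if 2 * self.ir_length >= self.genome_length:
            raise ValueError("two IR copies must fit inside the genome")
        if any(v < 0 for v in self.region_rate.values()):
            raise ValueError("region rates must be nonnegative")

    @classmethod
    def compact(cls, seed: int = 0, **kw) -> "SimulationConfig":
        """A desk-scale family (24 kb genome, 3 kb IRs, 18 genes) with the
        same rate structure as the full-size defaults."""
        params = dict(
            seed=seed, genome_length=24_000, ir_length=3_000,
            gene_count=14, ssr_loci=6,
        )
        params.update(kw)
        return cls(**params)


@dataclass
class _Gene:
    name: str
    kind: str
    strand: str
    parts: list[tuple[int, int]]  # ancestor-core coordinates
    in_ir: bool = False


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    records: dict[str, PlastomeRecord]
    alignment: AlignmentMatrix
    truth: dict[str, object]

    @property
    def reference_id(self) -> str:
        return self.alignment.reference_id


# ---------------------------------------------------------------------------
# ancestor


def simulate_ancestor(config: SimulationConfig):
    """Build the ancestral core (LSC+IRb+SSC as one array), the gene layout
    and auxiliary placement maps. Returns (core, genes, layout) where layout
    carries region boundaries, per-position rate multipliers, SSR loci and
    the hotspot interval."""
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    ir = config.ir_length
    single = n - 2 * ir
    lsc = config.lsc_length if config.lsc_length is not None else int(0.82 * single)
    ssc = single - lsc
    if min(lsc, ssc) <= 0:
        raise ValueError("invalid LSC/SSC split")
    core_len = lsc + ir + ssc
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    core = rng.choice(_BASES, size=core_len, p=probs).astype(np.uint8)

    genes = _place_genes(config, rng, lsc, ir, ssc)
    # per-position substitution-rate multiplier on the core
    mult = np.empty(core_len)
    mult[:lsc] = config.region_rate["LSC"]
    mult[lsc : lsc + ir] = config.region_rate["IR"]
    mult[lsc + ir :] = config.region_rate["SSC"]

    gene_mask = np.zeros(core_len, dtype=bool)
    for g in genes:
        for s, e in g.parts:
            gene_mask[s:e] = True

    hotspot = _pick_hotspot(genes, lsc, rng)
    if hotspot is not None:
        mult[hotspot[0] : hotspot[1]] *= config.hotspot_multiplier

    ssr_loci = _plant_ssrs(config, rng, core, gene_mask, lsc, ir)

    # boundary guards: fix the single-copy bases flanking each junction to a
    # non-self-complementary state so the IR pair cannot coincidentally
    # extend by symmetry; frozen during evolution
    guards = [0, lsc - 1, lsc + ir, core_len - 1]
    if config.ir_expansion is not None:
        guards.append(lsc + ir + int(config.ir_expansion[1]))
    for g in guards:
        core[g] = _A
    layout = {
        "lsc": lsc, "ir": ir, "ssc": ssc, "core_len": core_len,
        "mult": mult, "gene_mask": gene_mask, "hotspot": hotspot,
        "ssr_loci": ssr_loci, "guards": guards,
    }
    return core, genes, layout


def _place_genes(config, rng, lsc, ir, ssc):
    """Non-overlapping gene layout with junction-spanning genes: an
    rps19-like gene across JLB, duplicated IR genes, an ndhF-like SSC gene
    and a ycf1-like gene ending at the SSC/IRa boundary."""
    core_len = lsc + ir + ssc
    genes: list[_Gene] = []
    names = iter(GENE_NAMES * 3)

    def cds_len():
        return int(rng.integers(100, 420)) * 3

    # rps19-like across JLB: ends 60-140 bp inside IRb
    glen = 279
    over = int(rng.integers(60, min(141, ir // 4)))
    genes.append(_Gene("rps19", "CDS", "-", [(lsc - (glen - over), lsc + over)]))
    # IR-internal genes (duplicated by assembly): 2 rRNA + 1 tRNA-like
    pos = lsc + over + 200
    for nm, kind, L in (("rrn16", "rRNA", 1491), ("rrn23", "rRNA", 2109),
                        ("trnL_CAA", "tRNA", 81)):
        L = min(L, max(90, ir // 4))
        if pos + L < lsc + ir - 300:
            genes.append(_Gene(nm, kind, "+", [(pos, pos + L)], in_ir=True))
            pos += L + int(rng.integers(120, 300))
    # ycf1-like: occupies the tail of the SSC, ending at the SSC/IRa junction
    ylen = min(1800, ssc // 2)
    genes.append(_Gene("ycf1", "CDS", "+", [(core_len - ylen, core_len)]))
    # ndhF-like wholly in SSC near JSB
    nlen = min(2220, max(300, ssc // 3))
    s = lsc + ir + int(rng.integers(40, 120))
    if s + nlen < core_len - ylen - 100:
        genes.append(_Gene("ndhF", "CDS", "-", [(s, s + nlen)]))
    # remaining genes tile the LSC (some with introns)
    pos = int(rng.integers(150, 400))
    placed = len(genes)
    while placed < config.gene_count and pos < lsc - 2000:
        L = cds_len()
        name = next(names)
        if name in {g.name for g in genes}:
            continue
        r = rng.random()
        if r < 0.15:  # one intron
            e1 = L // 2 // 3 * 3
            intron = int(rng.integers(120, 600))
            parts = [(pos, pos + e1), (pos + e1 + intron, pos + L + intron)]
        elif r < 0.18:  # two introns (ycf3-like)
            e = L // 3 // 3 * 3
            i1 = int(rng.integers(120, 400))
            i2 = int(rng.integers(120, 400))
            parts = [
                (pos, pos + e),
                (pos + e + i1, pos + 2 * e + i1),
                (pos + 2 * e + i1 + i2, pos + L + i1 + i2),
            ]
        else:
            parts = [(pos, pos + L)]
        end = parts[-1][1]
        if end >= lsc - 300:
            break
        genes.append(
            _Gene(name, "CDS", "+" if rng.random() < 0.5 else "-", parts)
        )
        pos = end + int(rng.integers(150, 900))
        placed += 1
    return genes


def _pick_hotspot(genes, lsc, rng):
    """The IGS gap between the last two LSC genes becomes the planted
    mutational hotspot (if one exists and is >= 150 bp)."""
    lsc_genes = sorted(
        (g for g in genes if g.parts[-1][1] <= lsc), key=lambda g: g.parts[0][0]
    )
    best = None
    for a, b in zip(lsc_genes, lsc_genes[1:]):
        gap = (a.parts[-1][1], b.parts[0][0])
        if gap[1] - gap[0] >= 300:
            best = (gap[0] + 20, gap[1] - 20, f"{a.name}-{b.name}")
    return best


def _plant_ssrs(config, rng, core, gene_mask, lsc, ir):
    """Plant perfect SSR runs in single-copy IGS positions; returns a list
    of dicts with anchor, motif and copies."""
    core_len = len(core)
    motifs = ["A", "T", "AT", "TA", "AAG", "ATT"]
    loci = []
    taken = gene_mask.copy()
    tries = 0
    while len(loci) < config.ssr_loci and tries < 500:
        tries += 1
        if rng.random() < 0.8 or core_len - (lsc + ir) < 400:
            pos = int(rng.integers(100, lsc - 100))
        else:
            pos = int(rng.integers(lsc + ir + 50, core_len - 200))
        motif = motifs[int(rng.integers(0, len(motifs)))]
        copies = int(rng.integers(8, 13)) if len(motif) == 1 else int(
            rng.integers(5, 8)
        )
        span = len(motif) * copies
        if taken[max(0, pos - 30) : pos + span + 30].any():
            continue
        core[pos : pos + span] = np.frombuffer(
            (motif * copies).encode(), dtype=np.uint8
        )
        # flank with a base absent from the motif so the run cannot extend
        # or phase-shift across the boundary
        flank = next(b for b in "GCTA" if b not in motif)
        core[pos - 1] = ord(flank)
        core[pos + span] = ord(flank)
        taken[pos - 30 : pos + span + 30] = True
        loci.append(
            {"anchor": pos, "motif": motif, "unit_len": len(motif),
             "copies": copies}
        )
    return loci


# ---------------------------------------------------------------------------
# evolution


@dataclass
class _Indel:
    uid: int
    kind: str  # insertion | deletion
    anchor: int  # ancestor-core position (insertion goes after anchor)
    length: int
    bases: str = ""  # inserted material


class _Node:
    __slots__ = ("core", "events")

    def __init__(self, core: np.ndarray, events: list[_Indel]):
        self.core = core
        self.events = events


def evolve(ancestor_bundle, config: SimulationConfig) -> SimulatedDataset:
    """Evolve the ancestor along the configured tree and assemble records,
    the true alignment and truth tables.

    ``ancestor_bundle`` is the (core, genes, layout) triple from
    :func:`simulate_ancestor`.
    """
    core0, genes, layout = ancestor_bundle
    rng = np.random.default_rng((config.seed, 77))
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    species = [lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()]
    acc_per = config.accessions_per_species or {}
    plan = config.diagnostic_plan
    if plan is not None and plan.target_species not in species:
        raise ValueError(
            f"diagnostic target {plan.target_species!r} not among tree taxa"
        )
    if plan is not None:
        acc_per = {plan.target_species: 2, **acc_per}

    frozen = np.zeros(len(core0), dtype=bool)
    diag_cols = _choose_diagnostic_columns(config, layout, genes, rng)
    for p in diag_cols:
        frozen[max(0, p - plan.flank) : p + plan.flank + 1] = True
    for g in layout["guards"]:
        frozen[g] = True

    # eligible indel anchors: single-copy IGS, outside frozen zones and SSRs
    lsc, ir = layout["lsc"], layout["ir"]
    eligible = ~layout["gene_mask"] & ~frozen
    eligible[lsc : lsc + ir] = False
    for locus in layout["ssr_loci"]:
        s = locus["anchor"]
        eligible[s - 2 : s + locus["unit_len"] * locus["copies"] + 2] = False
    for g in layout["guards"]:
        eligible[max(0, g - 8) : g + 8] = False
    eligible_idx = np.flatnonzero(eligible)

    uid_counter = [0]
    mutation_log = {"ts": 0, "tv": 0}

    def evolve_branch(node: _Node, bl: float) -> _Node:
        core = node.core.copy()
        events = list(node.events)
        if bl > 0:
            p = np.minimum(bl * layout["mult"], 0.95)
            hit = np.flatnonzero(rng.random(len(core)) < p)
            hit = hit[~frozen[hit]]
            for pos in hit:
                base = core[pos]
                if base not in _TRANSITION:
                    continue
                if rng.random() < config.ts_tv_ratio / (1 + config.ts_tv_ratio):
                    core[pos] = _TRANSITION[base]
                    mutation_log["ts"] += 1
                else:
                    tv = _TRANSVERSIONS[base]
                    core[pos] = tv[int(rng.integers(0, 2))]
                    mutation_log["tv"] += 1
            # indels
            n_indel = rng.poisson(config.indel_sub_ratio * len(hit))
            for _ in range(n_indel):
                if eligible_idx.size == 0:
                    break
                anchor = int(eligible_idx[int(rng.integers(0, eligible_idx.size))])
                length = int(rng.geometric(1 / config.indel_mean_length))
                uid_counter[0] += 1
                if rng.random() < 0.5:
                    # deletion: clip to the eligible run around the anchor
                    end = anchor
                    while end < len(core) and eligible[end] and end - anchor < length:
                        end += 1
                    if end > anchor:
                        events.append(
                            _Indel(uid_counter[0], "deletion", anchor,
                                   end - anchor)
                        )
                else:
                    bases = "".join(
                        "ACGT"[i] for i in rng.choice(
                            4, size=length,
                            p=[0.31, 0.19, 0.19, 0.31],
                        )
                    )
                    events.append(
                        _Indel(uid_counter[0], "insertion", anchor, length,
                               bases)
                    )
            # SSR slippage: gain/lose one unit, phase-aligned with the run
            for locus in layout["ssr_loci"]:
                if rng.random() < config.ssr_slippage:
                    uid_counter[0] += 1
                    unit = locus["motif"]
                    if rng.random() < 0.5:
                        events.append(
                            _Indel(uid_counter[0], "insertion",
                                   locus["anchor"] + len(unit) - 1,
                                   len(unit), unit)
                        )
                    else:
                        events.append(
                            _Indel(uid_counter[0], "deletion",
                                   locus["anchor"], len(unit))
                        )
        return _Node(core, events)

    # walk the tree
    leaf_nodes: dict[str, _Node] = {}
    root_node = _Node(core0.copy(), [])
    stack = [(tree.seed_node, root_node)]
    while stack:
        tnode, sim = stack.pop()
        for child in tnode.child_nodes():
            bl = child.edge.length or 0.0
            child_sim = evolve_branch(sim, bl)
            if child.is_leaf():
                sp = child.taxon.label.replace(" ", "_")
                n_acc = acc_per.get(sp, 1)
                for i in range(n_acc):
                    tip = (
                        evolve_branch(child_sim, config.intraspecific_branch)
                        if n_acc > 1
                        else child_sim
                    )
                    leaf_nodes[f"{sp}_{i + 1:02d}"] = tip
            else:
                stack.append((child, child_sim))

    species_of = {acc: acc.rsplit("_", 1)[0] for acc in leaf_nodes}
    # the outgroup-like reference: the last taxon in newick order
    ref_species = species[-1]
    reference_acc = next(
        a for a in leaf_nodes if species_of[a] == ref_species
    )

    # plant diagnostic alleles after evolution (fixed in target, absent
    # elsewhere, conserved flanks guaranteed by the frozen mask)
    diag_truth = []
    if plan is not None:
        for p in diag_cols:
            anc = int(core0[p])
            alt = _TRANSITION[anc]
            for acc, node in leaf_nodes.items():
                node.core[p] = alt if species_of[acc] == plan.target_species else anc
            diag_truth.append(
                {"core_pos": int(p), "target_allele": chr(alt),
                 "ancestral_allele": chr(anc)}
            )

    dataset = _assemble(
        config, core0, genes, layout, leaf_nodes, species_of, reference_acc,
        diag_truth, mutation_log,
    )
    return dataset


def _choose_diagnostic_columns(config, layout, genes, rng):
    plan = config.diagnostic_plan
    if plan is None:
        return []
    lsc = layout["lsc"]
    free = ~layout["gene_mask"][:lsc]
    hotspot = layout["hotspot"]
    if hotspot is not None:
        free[hotspot[0] : hotspot[1]] = False
    for locus in layout["ssr_loci"]:
        s = locus["anchor"]
        free[max(0, s - 40) : s + 80] = False
    cols = []
    pos = 200
    while len(cols) < plan.n_snps and pos < lsc - 200:
        window = np.flatnonzero(free[pos : pos + 200])
        if window.size:
            p = pos + int(window[0])
            if free[max(0, p - plan.flank) : p + plan.flank + 1].all():
                cols.append(p)
                pos = p + plan.spacing
                continue
        pos += 100
    if len(cols) < plan.n_snps:
        raise ValueError(
            f"could not place {plan.n_snps} diagnostic columns in conserved "
            f"LSC spacers (placed {len(cols)})"
        )
    return cols


# ---------------------------------------------------------------------------
# assembly


def _suppress_emergent_diagnostics(config, core0, leaf_nodes, species_of,
                                   states, diag_truth, core_len) -> None:
    """Revert lineage-private substitutions that would create unplanned
    target-diagnostic columns, so the planted set is exactly the diagnostic
    truth of the emitted dataset."""
    plan = config.diagnostic_plan
    if plan is None:
        return
    t = [a for a in leaf_nodes if species_of[a] == plan.target_species]
    b = [a for a in leaf_nodes if species_of[a] != plan.target_species]
    if not t or not b:
        return
    planted = {d["core_pos"] for d in diag_truth}
    del_any = np.zeros(core_len, dtype=bool)
    for dmask, _ in states.values():
        del_any |= dmask
    for _round in range(2):
        tcores = np.stack([leaf_nodes[a].core for a in t])
        bcores = np.stack([leaf_nodes[a].core for a in b])
        fixed = (tcores == tcores[0]).all(axis=0)
        absent = (bcores != tcores[0]).all(axis=0)
        emergent = [
            int(p)
            for p in np.flatnonzero(fixed & absent & ~del_any)
            if int(p) not in planted
        ]
        if not emergent:
            return
        for p in emergent:
            if _round == 0:  # revert the target lineage to the ancestor
                for a in t:
                    leaf_nodes[a].core[p] = core0[p]
            else:  # double hit: give one background row the target allele
                leaf_nodes[b[0]].core[p] = leaf_nodes[t[0]].core[p]


def _leaf_state(core_len: int, node: _Node):
    """(deleted mask, insertions dict uid->event) for one leaf lineage."""
    deleted = np.zeros(core_len, dtype=bool)
    ins = {}
    for ev in node.events:
        if ev.kind == "deletion":
            deleted[ev.anchor : ev.anchor + ev.length] = True
        else:
            ins[ev.uid] = ev
    return deleted, ins


def _assemble(config, core0, genes, layout, leaf_nodes, species_of,
              reference_acc, diag_truth, mutation_log) -> SimulatedDataset:
    core_len = layout["core_len"]
    lsc, ir, ssc = layout["lsc"], layout["ir"], layout["ssc"]
    states = {a: _leaf_state(core_len, nd) for a, nd in leaf_nodes.items()}
    _suppress_emergent_diagnostics(
        config, core0, leaf_nodes, species_of, states, diag_truth, core_len
    )
    all_ins = {}
    for a, (_, ins) in states.items():
        all_ins.update(ins)
    ins_order = sorted(all_ins.values(), key=lambda e: (e.anchor, e.uid))
    ins_at: dict[int, list[_Indel]] = {}
    for ev in ins_order:
        ins_at.setdefault(ev.anchor, []).append(ev)

    # columns: one per ancestor position plus one per inserted base,
    # ordered (ancestor anchor, insertion uid, offset)
    core_col = np.empty(core_len, dtype=np.int64)
    ins_start: dict[int, int] = {}
    n_cols = 0
    for p in range(core_len):
        core_col[p] = n_cols
        n_cols += 1
        for ev in ins_at.get(p, ()):
            ins_start[ev.uid] = n_cols
            n_cols += ev.length

    rows = {}
    for acc, node in leaf_nodes.items():
        deleted, ins = states[acc]
        buf = np.full(n_cols, ord("-"), dtype=np.uint8)
        visible = ~deleted
        buf[core_col[visible]] = node.core[visible]
        for uid, ev in ins.items():
            start = ins_start[uid]
            buf[start : start + ev.length] = np.frombuffer(
                ev.bases.encode(), dtype=np.uint8
            )
        rows[acc] = buf.tobytes().decode()

    alignment = AlignmentMatrix(
        ids=list(rows), rows=list(rows.values()), species_of=species_of,
        reference_id=reference_acc,
    )

    # per-leaf genomes, features and partitions
    records = {}
    partitions = {}
    junction_truth = []
    ssr_truth = []
    expansion = config.ir_expansion
    for acc, node in leaf_nodes.items():
        deleted, ins = states[acc]
        core_seq = rows[acc].replace("-", "")
        anc2leaf = _ancestor_to_leaf_map(deleted, ins, core_len)
        x = 0
        if expansion is not None and species_of[acc] == expansion[0]:
            x = int(expansion[1])
        record, part = _build_record(
            acc, species_of[acc], core_seq, anc2leaf, genes, layout, x
        )
        records[acc] = record
        partitions[acc] = part
        junction_truth.extend(_junction_truth_rows(record, part))
        for locus in layout["ssr_loci"]:
            a = locus["anchor"]
            start = int(anc2leaf[a])
            span = _realized_ssr_span(record.sequence, start, locus)
            unit = locus["motif"]
            canonical = min(unit[i:] + unit[:i] for i in range(len(unit)))
            ssr_truth.append(
                {
                    "accession": acc, "start": span[0], "end": span[1],
                    "motif": canonical, "unit_len": locus["unit_len"],
                    "copies": (span[1] - span[0]) // locus["unit_len"],
                }
            )

    # truth tables from direct inspection of the emitted alignment
    M = alignment.matrix
    present = np.stack([(M == b).any(axis=0) for b in (_A, _C, _G, _T)])
    poly_cols = np.flatnonzero(present.sum(axis=0) >= 2)
    diag_col_rows = []
    for d in diag_truth:
        c = int(core_col[d["core_pos"]])
        diag_col_rows.append({**d, "alignment_column": c,
                              "ref_pos": int(alignment.column_map[c])})

    truth = {
        "partitions": partitions,
        "diagnostic_columns": pd.DataFrame(diag_col_rows),
        "polymorphic_columns": np.array(poly_cols, dtype=np.int64),
        "ssr_loci": pd.DataFrame(ssr_truth),
        "junction_spans": pd.DataFrame(junction_truth),
        "hotspot": layout["hotspot"],
        "mutation_log": dict(mutation_log),
        "layout": layout,
        "genes": genes,
    }
    return SimulatedDataset(
        config=config, records=records, alignment=alignment, truth=truth
    )


def _ancestor_to_leaf_map(deleted, ins, core_len) -> np.ndarray:
    """Leaf coordinate of each ancestor-core position (deleted positions
    map to the coordinate of the next surviving base); index core_len gives
    the leaf core length."""
    vis = np.concatenate(([0], np.cumsum(~deleted, dtype=np.int64)))
    extra = np.zeros(core_len + 1, dtype=np.int64)
    for ev in ins.values():
        extra[ev.anchor + 1] += ev.length  # inserted after its anchor
    return vis + np.cumsum(extra)


def _build_record(acc, sp, core_seq, anc2leaf, genes, layout, x):
    """Assemble the circular genome (core + reverse complement of the IR
    copy, optionally expanded by x bp of captured SSC) plus features."""
    from .structure import QuadripartitePartition

    lsc_a, ir_a = layout["lsc"], layout["ir"]
    core_len = layout["core_len"]
    L = int(anc2leaf[lsc_a])  # leaf LSC length
    I = int(anc2leaf[lsc_a + ir_a]) - L  # leaf IR core length
    total_core = int(anc2leaf[core_len])
    S = total_core - L - I
    if x:  # expansion given in ancestor coordinates; map to leaf bp
        x = int(anc2leaf[lsc_a + ir_a + x]) - (L + I)
    if x >= S:
        raise ValueError("IR expansion would consume the whole SSC")
    irb_seq = core_seq[L : L + I + x]  # includes captured SSC prefix
    genome = core_seq + revcomp(irb_seq)
    n = len(genome)
    part = QuadripartitePartition(
        lsc=(0, L), irb=(L, L + I + x), ssc=(L + I + x, total_core),
        ira=(total_core, n), genome_length=n,
    )

    features = []
    ir_lo, ir_hi = L, L + I + x  # leaf coords of the (expanded) IRb

    def mirror(s, e):
        """IRa copy of an IRb-side interval (leaf coordinates)."""
        return (n - (e - L), n - (s - L))

    for g in genes:
        parts = [(int(anc2leaf[s]), int(anc2leaf[e])) for s, e in g.parts]
        parts = [(s, e) for s, e in parts if e > s]
        if not parts:
            continue
        if g.name == "ycf1":
            # the gene crosses JSA: its tail continues into the IRa (the
            # mirror of the IRb end), so it spans the SSC/IRa boundary
            tail = min(500, I)
            parts[-1] = (parts[-1][0], total_core + tail)
            # truncated mirror copy (pseudogene) at the IRb/SSC boundary
            features.append(
                GeneFeature("ycf1", "pseudogene", "-",
                            [(ir_hi - tail, ir_hi)], 0)
            )
        intron_count = len(parts) - 1
        features.append(
            GeneFeature(g.name, g.kind, g.strand, parts, intron_count)
        )
        span_s, span_e = parts[0][0], parts[-1][1]
        # duplicate into IRa whatever falls inside the (expanded) IRb
        ov_s, ov_e = max(span_s, ir_lo), min(span_e, ir_hi)
        if ov_e > ov_s and g.name != "ycf1":
            ms, me = mirror(ov_s, ov_e)
            full = ov_s == span_s and ov_e == span_e
            features.append(
                GeneFeature(
                    g.name,
                    g.kind if full else "pseudogene",
                    "-" if g.strand == "+" else "+",
                    [(ms, me)],
                    0,
                )
            )
    return (
        PlastomeRecord(acc, sp, genome, features),
        part,
    )


def _junction_truth_rows(record, part):
    """Genes spanning a junction in the assembled record, with planted side
    lengths (direct arithmetic on the final feature spans)."""
    rows = []
    jpos = part.junction_positions()
    for gf in record.features:
        s, e = gf.span
        for jname, q in jpos.items():
            if s < q < e:
                rows.append(
                    {
                        "accession": record.accession, "junction": jname,
                        "gene": gf.name, "left_bases": q - s,
                        "right_bases": e - q,
                        "pseudogene_fragment": gf.kind == "pseudogene",
                    }
                )
    return rows


def _realized_ssr_span(sequence, start, locus):
    """Maximal phase-aligned run of the planted motif at its realized
    locus (slippage may have shifted the anchor)."""
    unit = locus["motif"]
    p = len(unit)
    s = None
    for cand in range(max(0, start - p), min(start + 3 * p,
                                             len(sequence) - p)):
        if sequence[cand : cand + p] == unit:
            s = cand
            break
    if s is None:
        return (start, start)
    while s - p >= 0 and sequence[s - p : s] == unit:
        s -= p
    e = s
    while e + p <= len(sequence) and sequence[e : e + p] == unit:
        e += p
    return (s, e)


# ---------------------------------------------------------------------------
# reports and export


def truth_report(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write machine-readable truth tables (TSV) for downstream tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    part_rows = []
    for acc, part in dataset.truth["partitions"].items():
        for name, length in part.lengths.items():
            part_rows.append({"accession": acc, "region": name, "length": length})
    writers = {
        "partitions": pd.DataFrame(part_rows),
        "diagnostic_columns": dataset.truth["diagnostic_columns"],
        "polymorphic_columns": pd.DataFrame(
            {"column": dataset.truth["polymorphic_columns"]}
        ),
        "ssr_loci": dataset.truth["ssr_loci"],
        "junction_spans": dataset.truth["junction_spans"],
    }
    for name, df in writers.items():
        p = out / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


def export_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit GenBank + FASTA per record, the aligned FASTA and the species
    map TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for acc, rec in dataset.records.items():
        pio.write_genbank(rec, out / f"{acc}.gb")
        pio.write_fasta({acc: rec.sequence}, out / f"{acc}.fasta")
    pio.write_alignment(dataset.alignment, out / "alignment.fasta")
    with open(out / "species_map.tsv", "w") as fh:
        for acc, sp in dataset.alignment.species_of.items():
            fh.write(f"{acc}\t{sp}\n")
    paths["alignment"] = out / "alignment.fasta"
    paths["species_map"] = out / "species_map.tsv"
    return paths


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Convenience wrapper: ancestor + evolution in one call."""
    return evolve(simulate_ancestor(config), config)


def simulate_codon_pair(n_codons: int, divergence: float, omega: float,
                        rng: np.random.Generator,
                        ts_tv_ratio: float = 1.2) -> tuple[str, str]:
    """A codon-aligned CDS pair evolved with a nonsynonymous:synonymous
    rate ratio ``omega`` (mutation-selection sampling; used by selection-
    recovery tests)."""
    from .codon import translate_codon

    sense = []
    while len(sense) < n_codons:
        codon = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if translate_codon(codon) != "*":
            sense.append(codon)
    s1 = list(sense)
    s2 = list(sense)
    accept_syn = min(1.0, 1.0 / omega)
    accept_non = min(1.0, omega)
    n_events = rng.poisson(divergence * 3 * n_codons)
    for _ in range(n_events):
        which = s2
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        codon = which[ci]
        base = codon[pos]
        if rng.random() < ts_tv_ratio / (1 + ts_tv_ratio):
            new = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
        else:
            choices = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}[base]
            new = choices[int(rng.integers(0, 2))]
        cand = codon[:pos] + new + codon[pos + 1 :]
        if translate_codon(cand) == "*":
            continue
        syn = translate_codon(cand) == translate_codon(codon)
        accept = accept_syn if syn else accept_non
        if rng.random() < accept:
            which[ci] = cand
    return "".join(s1), "".join(s2)
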