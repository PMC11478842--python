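"""Species-diagnostic SNP discovery and allele-specific PCR marker design.

The procedure: scan a multi-species plastome alignment for columns where
every accession of the target species carries one base and no other
accession carries it; anchor primer 3' termini on such columns (allele-
specific PCR fails on a 3'-terminal mismatch); add a control pair drawn from
columns invariant across all accessions; and validate both by in-silico PCR
against every genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp

from .core import GAP, AlignmentMatrix, PlastomeRecord, RegionAnnotation, is_base, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosticSNP:
    column: int  # alignment column
    ref_pos: int  # reference coordinate (-1 when reference is gapped)
    target_allele: str
    background_alleles: tuple[str, ...]
    locus: str = ""
    flank_conservation: float = 0.0  # invariant fraction of +-25 bp columns


@dataclass
class PrimerPair:
    forward: str  # 5'->3' on the plus strand
    reverse: str  # 5'->3' (reverse complement of the template)
    forward_start: int  # target-genome coordinate of forward 5' end
    reverse_start: int  # target-genome coordinate of reverse 3'-binding start
    product_size: int
    role: str  # "diagnostic" | "control"
    anchor_snps: tuple[DiagnosticSNP, ...] = ()
    tm_forward: float = 0.0
    tm_reverse: float = 0.0
    gc_forward: float = 0.0
    gc_reverse: float = 0.0


@dataclass(frozen=True)
class Amplicon:
    template: str  # accession
    start: int
    end: int
    size: int
    mismatches: int
    three_prime_mismatches: int


@dataclass
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 27
    min_gc: float = 0.35
    max_gc: float = 0.65
    min_tm: float = 52.0
    max_tm: float = 62.0
    min_product: int = 300
    max_product: int = 2500


def primer_tm(primer: str) -> float:
    """Nearest-neighbour melting temperature (deg C) at 50 mM monovalent
    salt and 500 nM primer."""
    return float(
        MeltingTemp.Tm_NN(primer, Na=50, dnac1=500, dnac2=0, saltcorr=5)
    )


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def find_diagnostic_snps(
    aln: AlignmentMatrix,
    target_species: str,
    min_flank_conservation: float = 0.8,
    flank: int = 25,
) -> list[DiagnosticSNP]:
    """Columns fixed for one base in all target-species rows, with that base
    absent from every background row and no gap/N anywhere in the column.

    Results carry the invariant fraction of the +-``flank`` surrounding
    columns and are sorted by flank conservation (descending) then
    reference coordinate; ``min_flank_conservation`` filters the output.
    """
    t_idx = [i for i, a in enumerate(aln.ids)
             if aln.species_of[a] == target_species]
    if not t_idx:
        raise ValueError(f"target species {target_species!r} not in alignment")
    b_idx = [i for i in range(aln.n_rows) if i not in t_idx]
    if not b_idx:
        raise ValueError("no background accessions")
    M = aln.matrix
    base_ok = is_base(M).all(axis=0)  # no gap/N in any row
    tgt = M[t_idx]
    bg = M[b_idx]
    fixed = (tgt == tgt[0]).all(axis=0)
    absent = (bg != tgt[0]).all(axis=0)
    diag_cols = np.flatnonzero(base_ok & fixed & absent)
    invariant = base_ok & (M == M[0]).all(axis=0)
    out = []
    for col in diag_cols:
        lo, hi = max(0, col - flank), min(aln.n_cols, col + flank + 1)
        neighbors = np.delete(np.arange(lo, hi), col - lo)
        cons = float(invariant[neighbors].mean()) if neighbors.size else 1.0
        if cons < min_flank_conservation:
            continue
        out.append(
            DiagnosticSNP(
                column=int(col),
                ref_pos=int(aln.column_map[col]),
                target_allele=chr(tgt[0, col]),
                background_alleles=tuple(
                    sorted({chr(b) for b in bg[:, col]})
                ),
                flank_conservation=cons,
            )
        )
    out.sort(key=lambda s: (-s.flank_conservation, s.ref_pos))
    return out


def _target_coordinates(aln: AlignmentMatrix, accession: str) -> np.ndarray:
    """Alignment column -> ungapped coordinate in the given accession's
    sequence (-1 at its gaps)."""
    row = aln.row(accession)
    non_gap = row != GAP
    cmap = np.cumsum(non_gap) - 1
    cmap = cmap.astype(np.int64)
    cmap[~non_gap] = -1
    return cmap


def _conserved_mask(aln: AlignmentMatrix) -> np.ndarray:
    M = aln.matrix
    return is_base(M).all(axis=0) & (M == M[0]).all(axis=0)


def design_diagnostic_pair(
    aln: AlignmentMatrix,
    diagnostic_snps: list[DiagnosticSNP],
    constraints: PrimerConstraints | None = None,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Allele-specific primer pairs anchored 3' on diagnostic SNPs.

    Enumerates SNP pairs whose spacing fits the product-size range; the
    forward primer ends 3' on the upstream SNP and the reverse primer
    (reverse complement) ends 3' on the downstream SNP. Primer bodies are
    restricted to columns conserved across all accessions except the anchor
    itself. Candidates are filtered by length/GC/Tm constraints and ranked
    by Tm balance then combined flank conservation.
    """
    constraints = constraints or PrimerConstraints()
    if not diagnostic_snps:
        return []
    target_acc = _target_accession(aln, diagnostic_snps)
    tcoord = _target_coordinates(aln, target_acc)
    tseq = aln.ungapped(target_acc)
    conserved = _conserved_mask(aln)
    snps = sorted(diagnostic_snps, key=lambda s: s.column)
    candidates = []
    for i, up in enumerate(snps):
        for down in snps[i + 1 :]:
            up_pos, down_pos = int(tcoord[up.column]), int(tcoord[down.column])
            if up_pos < 0 or down_pos < 0:
                continue
            spacing = down_pos - up_pos + 1
            if spacing < constraints.min_product - 2 * constraints.max_len:
                continue
            if spacing > constraints.max_product:
                break
            fwd = _anchored_primer(
                tseq, tcoord, conserved, up, aln, constraints, direction="fwd"
            )
            rev = _anchored_primer(
                tseq, tcoord, conserved, down, aln, constraints, direction="rev"
            )
            if fwd is None or rev is None:
                continue
            fseq, fstart = fwd
            rseq, rstart = rev
            # amplicon length: forward 5' end to reverse-primer 5' end
            product = (down_pos + len(rseq)) - fstart
            if not (constraints.min_product <= product
                    <= constraints.max_product):
                continue
            tm_f, tm_r = primer_tm(fseq), primer_tm(rseq)
            pair = PrimerPair(
                forward=fseq,
                reverse=rseq,
                forward_start=fstart,
                reverse_start=rstart,
                product_size=product,
                role="diagnostic",
                anchor_snps=(up, down),
                tm_forward=tm_f,
                tm_reverse=tm_r,
                gc_forward=_gc(fseq),
                gc_reverse=_gc(rseq),
            )
            score = (
                abs(tm_f - tm_r),
                -(up.flank_conservation + down.flank_conservation),
            )
            candidates.append((score, pair))
    if not candidates:
        log.info(
            "no diagnostic SNP pair fits the product range %d-%d bp; "
            "consider single-anchor mode (one anchored + one conserved primer)",
            constraints.min_product, constraints.max_product,
        )
        return []
    candidates.sort(key=lambda t: t[0])
    return [p for _, p in candidates[:max_pairs]]


def _target_accession(aln, snps) -> str:
    """Any accession carrying the target allele at the first diagnostic SNP."""
    s = snps[0]
    for a in aln.ids:
        if chr(aln.row(a)[s.column]) == s.target_allele:
            return a
    raise ValueError("no accession carries the target allele")


def _anchored_primer(tseq, tcoord, conserved, snp, aln, constraints, direction):
    """Build a primer ending 3' on the anchor SNP; body restricted to
    conserved columns. Returns (primer 5'->3', target-genome start) or None."""
    anchor_t = int(tcoord[snp.column])
    col_of = {}
    for col in range(max(0, snp.column - 3 * constraints.max_len),
                     min(len(tcoord), snp.column + 3 * constraints.max_len)):
        if tcoord[col] >= 0:
            col_of[int(tcoord[col])] = col
    for length in range(constraints.max_len, constraints.min_len - 1, -1):
        if direction == "fwd":
            start, end = anchor_t - length + 1, anchor_t + 1
        else:
            start, end = anchor_t, anchor_t + length
        if start < 0 or end > len(tseq):
            continue
        body = range(start, end)
        ok = True
        for pos in body:
            col = col_of.get(pos)
            if col is None:
                ok = False
                break
            if col == snp.column:
                continue
            if not conserved[col]:
                ok = False
                break
        if not ok:
            continue
        template = tseq[start:end]
        primer = template if direction == "fwd" else revcomp(template)
        if not (constraints.min_gc <= _gc(primer) <= constraints.max_gc):
            continue
        if not (constraints.min_tm <= primer_tm(primer) <= constraints.max_tm):
            continue
        return primer, start
    return None


def design_control_pair(
    aln: AlignmentMatrix,
    constraints: PrimerConstraints | None = None,
    target_product: int = 400,
) -> PrimerPair:
    """Control pair drawn entirely from columns invariant across every
    accession, with product size as close as possible to
    ``target_product``. Deterministic first-best; raises when no invariant
    run can host a primer."""
    constraints = constraints or PrimerConstraints()
    conserved = _conserved_mask(aln)
    acc = aln.reference_id
    tcoord = _target_coordinates(aln, acc)
    tseq = aln.ungapped(acc)
    # invariant runs must be contiguous in alignment columns (a run broken
    # by an indel column is not co-linear across accessions); map each to
    # reference coordinates, where it is gap-free by construction
    runs = []
    for cs, ce in _runs(conserved):
        if ce - cs < constraints.min_len:
            continue
        s, e = int(tcoord[cs]), int(tcoord[ce - 1]) + 1
        runs.append((s, e))
    if not runs:
        raise ValueError("no invariant run long enough for a primer")
    flen = rlen = constraints.min_len
    best = None
    for i, (s1, e1) in enumerate(runs):
        for fstart in range(s1, e1 - flen + 1, 4):
            for s2, e2 in runs[i:]:
                # clamp the reverse 3' end toward the requested product size
                lo = max(s2 + rlen, fstart + max(constraints.min_product,
                                                 flen + rlen))
                hi = min(e2, fstart + constraints.max_product)
                if lo > hi:
                    continue
                rend = int(np.clip(fstart + target_product, lo, hi))
                product = rend - fstart
                fseq = tseq[fstart : fstart + flen]
                rseq = revcomp(tseq[rend - rlen : rend])
                if not all(
                    constraints.min_gc <= _gc(p) <= constraints.max_gc
                    and constraints.min_tm <= primer_tm(p) <= constraints.max_tm
                    for p in (fseq, rseq)
                ):
                    continue
                score = abs(product - target_product)
                if best is None or score < best[0]:
                    best = (
                        score,
                        PrimerPair(
                            forward=fseq,
                            reverse=rseq,
                            forward_start=fstart,
                            reverse_start=rend - rlen,
                            product_size=product,
                            role="control",
                            tm_forward=primer_tm(fseq),
                            tm_reverse=primer_tm(rseq),
                            gc_forward=_gc(fseq),
                            gc_reverse=_gc(rseq),
                        ),
                    )
            if best is not None and best[0] == 0:
                break
        if best is not None and best[0] == 0:
            break
    if best is None:
        raise ValueError("no control pair satisfies the constraints")
    return best[1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# in-silico PCR


def _binding_sites(seq: str, primer: str, max_internal_mm: int,
                   three_prime_strict: bool):
    """Positions where the primer binds the given strand (full-length
    alignment, <= max_internal_mm mismatches, zero mismatches in the
    3'-terminal 3 bases when strict). Returns list of (start, mismatches,
    three_prime_mm)."""
    n, m = len(seq), len(primer)
    if n < m:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    parr = np.frombuffer(primer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    mm = (windows != parr).sum(axis=1)
    tp = (windows[:, -3:] != parr[-3:]).sum(axis=1)
    internal = mm - tp
    ok = internal <= max_internal_mm
    if three_prime_strict:
        ok &= tp == 0
    else:
        ok &= mm <= max_internal_mm + 3
    return [(int(s), int(mm[s]), int(tp[s])) for s in np.flatnonzero(ok)]


def in_silico_pcr(
    record: PlastomeRecord | str,
    primer_pair: PrimerPair,
    max_product: int = 3000,
    max_internal_mm: int = 2,
    three_prime_strict: bool = True,
    circular: bool = True,
) -> list[Amplicon]:
    """Predict amplicons of a primer pair on a template genome.

    A primer binds where a full-length alignment has at most
    ``max_internal_mm`` internal mismatches and (when strict) none in the
    3'-terminal 3 bases — the allele-specific failure model. Convergent
    forward/reverse sites within ``max_product`` yield amplicons; zero
    amplicons is a valid result.
    """
    if isinstance(record, PlastomeRecord):
        seq, acc = record.sequence, record.accession
    else:
        seq, acc = record.upper(), "template"
    n = len(seq)
    template = seq + (seq[: max_product] if circular and n > max_product else "")
    fwd_sites = _binding_sites(template, primer_pair.forward,
                               max_internal_mm, three_prime_strict)
    rev_rc = revcomp(primer_pair.reverse)
    rev_sites = _binding_sites(template, rev_rc, max_internal_mm,
                               three_prime_strict)
    # reverse primer binds the minus strand where plus strand equals rev_rc
    amplicons = []
    seen = set()
    for fs, fm, ftp in fwd_sites:
        if fs >= n:
            continue  # only count origins once
        for rs, rm, rtp in rev_sites:
            end = rs + len(rev_rc)
            size = end - fs
            if size <= 0 or size > max_product:
                continue
            key = (fs % n, end % n)
            if key in seen:
                continue
            seen.add(key)
            amplicons.append(
                Amplicon(
                    template=acc,
                    start=fs % n,
                    end=end,
                    size=size,
                    mismatches=fm + rm,
                    three_prime_mismatches=ftp + rtp,
                )
            )
    return sorted(amplicons, key=lambda a: (a.start, a.size))
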