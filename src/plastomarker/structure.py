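"""Quadripartite architecture: IR detection, per-region composition and
junction comparison.

A plastome is linearized as LSC + IRb + SSC + IRa. Detection looks for the
maximal pair of inverted near-identical segments consistent with that layout;
assemblies normally emit byte-identical IR copies, so exact identity is the
default and a mismatch tolerance is opt-in.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneFeature, PlastomeRecord, RegionAnnotation, revcomp

log = logging.getLogger(__name__)

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


class NoIRFound(Exception):
    """No inverted repeat of the required length exists in the sequence."""


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa as [start, end) intervals on the linearized circle.

    ``end`` may exceed the genome length when a region wraps the origin;
    all four intervals are disjoint on the circle and cover it exactly.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    @property
    def lengths(self) -> dict[str, int]:
        return {
            name: iv[1] - iv[0]
            for name, iv in zip(
                ("LSC", "IRb", "SSC", "IRa"), (self.lsc, self.irb, self.ssc, self.ira)
            )
        }

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    def region_of(self, pos: int) -> str:
        """Structural region (LSC/SSC/IR) containing a position."""
        pos %= self.genome_length
        for name, (s, e) in (
            ("LSC", self.lsc),
            ("IR", self.irb),
            ("SSC", self.ssc),
            ("IR", self.ira),
        ):
            if s <= pos < e or (e > self.genome_length and pos < e - self.genome_length):
                return name
        return "LSC"  # unreachable for a valid partition

    def junction_positions(self) -> dict[str, int]:
        """Boundary positions (the first base of the downstream region)."""
        n = self.genome_length
        return {
            "JLB": self.irb[0] % n,
            "JSB": self.ssc[0] % n,
            "JSA": self.ira[0] % n,
            "JLA": self.lsc[0] % n,
        }

    def to_bed(self, accession: str) -> pd.DataFrame:
        rows = []
        for name, (s, e) in (
            ("LSC", self.lsc),
            ("IRb", self.irb),
            ("SSC", self.ssc),
            ("IRa", self.ira),
        ):
            rows.append({"chrom": accession, "start": s % self.genome_length,
                         "end": e if e <= self.genome_length else e - self.genome_length,
                         "name": name})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IR detection: seed-and-extend on k-mer matches against the reverse
# complement, merged on anti-diagonals into maximal identity blocks.


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer codes for every window (positions with N map to A;
    collisions are resolved by exact extension later)."""
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    vals = lut[arr]
    codes = np.zeros(len(arr) - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + vals[j : j + len(codes)]
    return codes


def _inverted_blocks(seq: str, k: int, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal exact inverted-match blocks (a, b, L) on the doubled sequence:
    seq2[a:a+L] == revcomp(seq2[b:b+L]), reported with a, b mod N, a <= b."""
    n = len(seq)
    seq2 = seq + seq
    arr = np.frombuffer(seq2.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq2).encode(), dtype=np.uint8)
    m = len(seq2)
    codes_f = _kmer_codes(arr, k)
    codes_r = _kmer_codes(rc, k)
    order_f = np.argsort(codes_f, kind="stable")
    order_r = np.argsort(codes_r, kind="stable")
    sf, sr = codes_f[order_f], codes_r[order_r]
    # seeds grouped by anti-diagonal c = i + j + k where j is the partner
    # start in seq2 coordinates (rc position p maps to j = m - p - k)
    diagonals: dict[int, list[int]] = defaultdict(list)
    ia = ib = 0
    while ia < len(sf) and ib < len(sr):
        if sf[ia] < sr[ib]:
            ia += 1
        elif sf[ia] > sr[ib]:
            ib += 1
        else:
            ja = ia
            while ja < len(sf) and sf[ja] == sf[ia]:
                ja += 1
            jb = ib
            while jb < len(sr) and sr[jb] == sr[ib]:
                jb += 1
            if (ja - ia) * (jb - ib) <= 4 * m:  # guard vs low-complexity blowup
                for i in order_f[ia:ja]:
                    for p in order_r[ib:jb]:
                        j = m - int(p) - k
                        diagonals[int(i) + j + k].append(int(i))
            ia, ib = ja, jb

    blocks: set[tuple[int, int, int]] = set()
    for c, starts in diagonals.items():
        starts = sorted(set(starts))
        done_until = -1
        for i in starts:
            if i < done_until:
                continue
            j = c - i - k  # partner start for this seed
            # extend: position t pairs with c - 1 - t on the complement sense
            lo = i
            while lo > 0 and c - lo < m and arr[lo - 1] == _COMP_CODE[arr[c - lo]]:
                lo -= 1
            hi = i + k  # exclusive
            while hi < m and c - 1 - hi >= 0 and arr[hi] == _COMP_CODE[arr[c - 1 - hi]]:
                hi += 1
            L = hi - lo
            done_until = hi
            if L < min_len:
                continue
            a, b = lo, c - hi  # partner interval [b, b+L)
            if b < a:
                a, b = b, a
            a_m, b_m = a % n, b % n
            if a_m > b_m:
                a_m, b_m = b_m, a_m
            if L <= n:
                blocks.add((a_m, b_m, L))
    return sorted(blocks)


_COMP_CODE = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_CODE[_x] = _y


def _extend_with_mismatches(seq: str, a: int, b: int, L: int, frac: float):
    """Greedy symmetric extension of an inverted block allowing a mismatch
    fraction up to ``frac``; returns (a, b, L, mismatches)."""
    n = len(seq)
    arr = np.frombuffer((seq + seq).encode(), dtype=np.uint8)
    mism = 0
    while True:
        na, nb, nl = a - 1, b, L + 1
        if na < 0 or b + nl > 2 * n or nl > n:
            break
        if arr[na] == _COMP_CODE[arr[b + nl - 1]]:
            a, L = na, nl
            continue
        if (mism + 1) / nl <= frac:
            a, L, mism = na, nl, mism + 1
            continue
        break
    return a, b, L, mism


def detect_partition(
    sequence: str,
    min_ir_len: int = 1000,
    max_mismatch_frac: float = 0.0,
    k: int = 25,
) -> QuadripartitePartition:
    """Detect the quadripartite layout of a circular plastome sequence.

    Returns the maximal pair of inverted repeats >= ``min_ir_len`` leaving two
    single-copy gaps; the longer gap is labelled LSC. Works across the
    linearization origin. Raises :class:`NoIRFound` when no qualifying pair
    exists. Ties on IR length are broken by maximizing the shorter
    single-copy region.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2 * min_ir_len:
        raise NoIRFound(f"sequence ({n} bp) shorter than two IR copies")
    blocks = _inverted_blocks(sequence, k=min(k, max(8, n // 50)), min_len=min_ir_len)
    if max_mismatch_frac > 0:
        blocks = [
            _extend_with_mismatches(sequence, a, b, L, max_mismatch_frac)[:3]
            for a, b, L in blocks
        ]
    candidates = []
    for a, b, L in blocks:
        # circular arcs between copy A=[a,a+L) and copy B=[b,b+L)
        g1 = (b - a - L) % n  # arc from end of A forward to start of B
        g2 = (a - b - L) % n  # arc from end of B forward to start of A
        if 2 * L + g1 + g2 != n or (g1 == 0 and g2 == 0):
            continue  # copies overlap on the circle
        candidates.append((L, min(g1, g2), a, b, g1, g2))
    if not candidates:
        raise NoIRFound(f"no inverted repeat pair >= {min_ir_len} bp")
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    L, _, a, b, g1, g2 = candidates[0]

    def iv(start: int, length: int) -> tuple[int, int]:
        start %= n
        return (start, start + length)

    if g1 >= g2:  # arc A->B is the LSC; order is LSC, B(=IRb), arc2, A(=IRa)
        part = QuadripartitePartition(
            lsc=iv(a + L, g1), irb=iv(b, L), ssc=iv(b + L, g2), ira=iv(a, L),
            genome_length=n,
        )
    else:
        part = QuadripartitePartition(
            lsc=iv(b + L, g2), irb=iv(a, L), ssc=iv(a + L, g1), ira=iv(b, L),
            genome_length=n,
        )
    if sum(part.lengths.values()) != n:
        raise AssertionError("partition does not cover the genome")
    return part


def canonical_rotation(record: PlastomeRecord, part: QuadripartitePartition):
    """Rotate a record so the LSC starts at position 0 (conventional
    linearization); returns (rotated_record, rotated_partition)."""
    n = record.length
    shift = part.lsc[0] % n
    if shift == 0:
        return record, part
    seq = record.sequence[shift:] + record.sequence[:shift]
    feats = []
    for gf in record.features:
        parts = []
        wraps = False
        for s, e in gf.parts:
            s2, e2 = (s - shift) % n, (e - shift) % n
            if e2 == 0:
                e2 = n
            if e2 < s2:  # part now wraps the origin: split
                parts.extend([(s2, n), (0, e2)])
                wraps = True
            else:
                parts.append((s2, e2))
        feats.append(
            GeneFeature(gf.name, gf.kind, gf.strand, parts,
                        intron_count=gf.intron_count, wraps_origin=wraps)
        )
    rec = PlastomeRecord(record.accession, record.species, seq, feats)

    def mv(iv):
        s = (iv[0] - shift) % n
        return (s, s + (iv[1] - iv[0]))

    part2 = QuadripartitePartition(
        lsc=mv(part.lsc), irb=mv(part.irb), ssc=mv(part.ssc), ira=mv(part.ira),
        genome_length=n,
    )
    return rec, part2


# ---------------------------------------------------------------------------
# composition and gene content


def region_gc(
    record: PlastomeRecord,
    part: QuadripartitePartition,
    annotation: RegionAnnotation | None = None,
) -> dict[str, float]:
    """GC fraction per structural region and overall, computed as
    (G+C)/(A+C+G+T); Ns are excluded from the denominator. When an
    annotation is supplied, per-feature-kind GC (CDS/tRNA/rRNA) is added."""

    def gc(seq: str) -> float:
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            return float("nan")
        return (seq.count("G") + seq.count("C")) / acgt

    out = {"total": gc(record.sequence)}
    for name, iv in (("LSC", part.lsc), ("IRb", part.irb), ("SSC", part.ssc),
                     ("IRa", part.ira)):
        out[name] = gc(record.subseq(*iv))
    out["IR"] = gc(record.subseq(*part.irb) + record.subseq(*part.ira))
    if annotation is not None:
        for kind in ("CDS", "tRNA", "rRNA"):
            seq = "".join(
                record.subseq(s, e)
                for gf in record.features
                if gf.kind == kind
                for s, e in gf.parts
            )
            out[kind] = gc(seq) if seq else float("nan")
    return out


def gene_content_summary(
    record: PlastomeRecord, part: QuadripartitePartition
) -> dict[str, object]:
    """Gene counts in the style of a plastome features table: unique genes by
    name, IR-duplicated genes, counts by kind, intron-containing genes."""
    by_name: dict[str, list[GeneFeature]] = defaultdict(list)
    for gf in record.features:
        by_name[gf.name].append(gf)

    def inside_ir(gf: GeneFeature) -> bool:
        n = record.length
        for s, e in gf.parts:
            if part.region_of(s % n) != "IR" or part.region_of((e - 1) % n) != "IR":
                return False
        return True

    duplicated = sorted(
        name
        for name, feats in by_name.items()
        if len(feats) > 1 and any(inside_ir(f) for f in feats)
    )
    kinds = defaultdict(set)
    for gf in record.features:
        kinds[gf.kind].add(gf.name)
    introns = sorted(
        {gf.name for gf in record.features if gf.intron_count > 0}
    )
    return {
        "unique_genes": len(by_name),
        "duplicated_in_ir": len(duplicated),
        "duplicated_gene_names": duplicated,
        "by_kind": {k: len(v) for k, v in sorted(kinds.items())},
        "intron_genes": introns,
    }


# ---------------------------------------------------------------------------
# junction report


def junction_report(records_with_partitions) -> pd.DataFrame:
    """For each accession and junction (JLB/JSB/JSA/JLA), report the nearest
    or overlapping gene, the bases of that gene on each side of the junction,
    and truncated same-name duplicates near the junction (pseudogene
    fragments). Input: iterable of (PlastomeRecord, QuadripartitePartition);
    records without a partition are skipped with a log note."""
    rows = []
    for record, part in records_with_partitions:
        if part is None:
            log.info("%s: no IR partition; skipped in junction report",
                     record.accession)
            continue
        n = record.length
        full_len = {name: max(f.length for f in fs) for name, fs in
                    _group_by_name(record.features).items()}
        for jname, q in part.junction_positions().items():
            gf, dist = _nearest_feature(record.features, q, n)
            if gf is None:
                continue
            s, e = gf.span
            if dist == 0:  # spanning: bases of the gene on each side
                if s <= q < e:
                    left, right = q - s, e - q
                else:  # junction falls in the wrapped tail of the span
                    left, right = (n - s) + q, (e - n) - q
            else:
                left, right = 0, gf.length
            frag = gf.length < full_len[gf.name]
            rows.append(
                {
                    "accession": record.accession,
                    "junction": jname,
                    "position": q,
                    "gene": gf.name,
                    "distance": dist,
                    "left_bases": int(left),
                    "right_bases": int(right),
                    "pseudogene_fragment": bool(frag),
                    "fragment_length": int(gf.length) if frag else 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "junction", "position", "gene", "distance",
            "left_bases", "right_bases", "pseudogene_fragment", "fragment_length",
        ],
    )


def _group_by_name(features):
    out = defaultdict(list)
    for f in features:
        out[f.name].append(f)
    return out


def _nearest_feature(features, q: int, n: int):
    """Feature overlapping position q, else the nearest one; returns
    (feature, circular distance)."""
    best, best_d = None, None
    for gf in features:
        s, e = gf.span
        if s <= q < e or (e > n and q < e - n):
            return gf, 0
        d = min((s - q) % n, (q - e) % n + 1)
        if best_d is None or d < best_d:
            best, best_d = gf, d
    return best, (best_d if best is not None else None)
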