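"""Repeat cataloguing: microsatellites (SSRs), dispersed repeats and tandem
repeats, with structural/functional region attribution.

SSR thresholds follow the common microsatellite-survey convention for
plastomes: minimum 7 copies for mononucleotide motifs, 4 for dinucleotide and
3 for tri- to hexanucleotide motifs. Dispersed repeats are maximal gapless
pairs >= 30 bp with Hamming distance <= 3 in forward (F), palindromic (P),
reverse (R) and complement (C) orientation. The tandem finder is a bespoke
period-scan; it does not emulate any external scoring scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import complement, revcomp
from .structure import QuadripartitePartition

log = logging.getLogger(__name__)

SSR_THRESHOLDS = {1: 7, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRRecord:
    motif: str  # canonical: lexicographically minimal rotation
    unit_len: int
    copies: int
    start: int
    end: int
    structural_region: str = "NA"
    functional_region: str = "NA"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class DispersedRepeat:
    kind: str  # F | P | R | C
    length: int
    pos1: int
    pos2: int
    mismatches: int


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    copies: float
    start: int
    end: int
    motif: str  # consensus unit

    @property
    def span_length(self) -> int:
        return self.end - self.start


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation of a repeat unit."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def find_ssrs(
    sequence: str, thresholds: dict[int, int] | None = None
) -> list[SSRRecord]:
    """Maximal perfect tandem runs of 1-6 bp units meeting per-unit-length
    copy thresholds. Runs are reported at their smallest period (a
    homopolymer is never reported as a dinucleotide repeat) and N breaks
    runs. Span covers complete copies only."""
    thresholds = thresholds or SSR_THRESHOLDS
    sequence = sequence.upper()
    n = len(sequence)
    calls: list[SSRRecord] = []
    claimed = np.zeros(n, dtype=bool)  # positions inside an accepted run
    for p in sorted(thresholds):
        min_copies = thresholds[p]
        i = 0
        while i + p <= n:
            unit = sequence[i : i + p]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            # extend run of identical units
            j = i + p
            while j + p <= n and sequence[j : j + p] == unit:
                j += p
            copies = (j - i) // p
            if copies >= min_copies:
                # maximality: cannot be left-extendable by a full unit
                if i >= p and sequence[i - p : i] == unit:
                    i += 1
                    continue
                span = (i, i + copies * p)
                if not claimed[span[0] : span[1]].any():
                    calls.append(
                        SSRRecord(
                            motif=canonical_motif(unit),
                            unit_len=p,
                            copies=copies,
                            start=span[0],
                            end=span[1],
                        )
                    )
                    claimed[span[0] : span[1]] = True
                    i = j
                else:
                    # suppressed by an earlier claim: a shifted run clear of
                    # the claim may still start inside this one
                    i += 1
            else:
                i += 1
    return sorted(calls, key=lambda r: (r.start, r.unit_len))


# ---------------------------------------------------------------------------
# dispersed repeats


_ORIENTATIONS = ("F", "P", "R", "C")


def _transform(sequence: str, kind: str) -> str:
    if kind == "F":
        return sequence
    if kind == "P":
        return revcomp(sequence)
    if kind == "R":
        return sequence[::-1]
    return complement(sequence)  # C


def _partner_interval(kind: str, p: int, L: int, n: int) -> int:
    """Map a match start in the transformed string back to a start in the
    original sequence."""
    if kind in ("F", "C"):
        return p
    return n - p - L  # reversed senses (P, R)


def _maximal_windows(mism_positions: list[int], lo: int, hi: int,
                     max_mism: int, min_len: int) -> list[tuple[int, int, int]]:
    """Maximal windows within [lo, hi) containing <= max_mism mismatches.

    ``mism_positions`` are the sorted mismatch positions inside [lo, hi).
    A window is maximal when extending it on either side would exceed the
    mismatch budget or leave the range; such windows are delimited by the
    (max_mism+1)-th mismatch on each side (or the range ends). Returns
    (start, end, mismatches_used) triples."""
    positions = [lo - 1] + sorted(mism_positions) + [hi]
    m = len(positions) - 2
    out = []
    for t in range(0, max(0, m - max_mism) + 1):
        last = min(t + max_mism + 1, m + 1)
        start = positions[t] + 1
        end = positions[last]
        used = last - t - 1
        if end - start >= min_len:
            out.append((start, end, used))
    return out


def find_dispersed_repeats(
    sequence: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    max_results: int = 500,
    seed_len: int | None = None,
) -> list[DispersedRepeat]:
    """Maximal repeated pairs >= ``min_len`` with <= ``max_mismatch``
    mismatches, classed by orientation: F (direct), P (reverse complement),
    R (reverse) and C (complement).

    Seeding uses exact ``seed_len``-mers; when None the seed length is the
    pigeonhole bound ``min_len // (max_mismatch + 1)`` for sequences up to
    ~20 kb (full sensitivity) and grows logarithmically for longer sequences
    to keep random seed matches bounded (near-identical repeats remain
    detectable). Pairs fully nested in a longer reported pair of the same
    orientation are suppressed; results are capped at ``max_results`` by
    descending length.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < min_len:
        return []
    guarantee = max(4, min_len // (max_mismatch + 1))
    if seed_len is None:
        k = guarantee
        while n * n / 4**k > 20000:
            k += 1
        seed_len = k
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    found: set[DispersedRepeat] = set()
    for kind in _ORIENTATIONS:
        tarr = np.frombuffer(_transform(sequence, kind).encode(), dtype=np.uint8)
        for s_start, t_start, s_end in _seed_matches(arr, tarr, seed_len):
            d = t_start - s_start
            lo = max(0, -d)
            hi = min(n, n - d)
            if hi - lo < min_len:
                continue
            # collect mismatch positions around the seed within budget
            wl, wr, mpos = _mismatch_window(
                arr, tarr, d, s_start, s_end, lo, hi, max_mismatch
            )
            for ws, we, wm in _maximal_windows(sorted(mpos), wl, wr,
                                               max_mismatch, min_len):
                _add_pair(found, kind, ws, we - ws, wm, d, n)
    calls = _suppress_nested(sorted(found, key=lambda r: (-r.length, r.pos1)))
    return calls[:max_results]


def _seed_matches(arr: np.ndarray, tarr: np.ndarray, k: int):
    """Yield (s_start, t_start, s_end) for maximal runs of exact k-mer
    matches between the two equal-length sequences (merged per diagonal)."""
    n = len(arr)
    if n < k:
        return
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i + 1  # N and others -> 0, never matches a valid code space
    va, vt = lut[arr], lut[tarr]
    ca = np.zeros(n - k + 1, dtype=np.int64)
    ct = np.zeros(n - k + 1, dtype=np.int64)
    valid_a = np.ones(n - k + 1, dtype=bool)
    valid_t = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        ca = ca * 5 + va[j : j + n - k + 1]
        ct = ct * 5 + vt[j : j + n - k + 1]
        valid_a &= va[j : j + n - k + 1] > 0
        valid_t &= vt[j : j + n - k + 1] > 0
    ia = np.flatnonzero(valid_a)
    it = np.flatnonzero(valid_t)
    ca, ct = ca[ia], ct[it]
    oa = np.argsort(ca, kind="stable")
    ot = np.argsort(ct, kind="stable")
    sa, st = ca[oa], ct[ot]
    # per-diagonal seed runs
    runs: dict[int, list[int]] = {}
    x = y = 0
    while x < len(sa) and y < len(st):
        if sa[x] < st[y]:
            x += 1
        elif sa[x] > st[y]:
            y += 1
        else:
            x2 = x
            while x2 < len(sa) and sa[x2] == sa[x]:
                x2 += 1
            y2 = y
            while y2 < len(st) and st[y2] == st[y]:
                y2 += 1
            if (x2 - x) * (y2 - y) <= 8 * n:
                for ii in oa[x:x2]:
                    si = int(ia[ii])
                    for jj in ot[y:y2]:
                        ti = int(it[jj])
                        runs.setdefault(ti - si, []).append(si)
            x, y = x2, y2
    for d, starts in runs.items():
        starts = sorted(set(starts))
        run_start = prev = starts[0]
        for s in starts[1:]:
            if s <= prev + k:
                prev = s
            else:
                yield run_start, run_start + d, prev + k
                run_start = prev = s
        yield run_start, run_start + d, prev + k


def _mismatch_window(arr, tarr, d, seed_s, seed_e, lo, hi, budget):
    """Scan outward from an exact seed collecting up to budget+1 mismatch
    positions on each side; returns (window_lo, window_hi, mismatch_set)."""
    mpos = set()
    i = seed_s - 1
    left_m = 0
    while i >= lo and left_m <= budget:
        if arr[i] != tarr[i + d]:
            left_m += 1
            if left_m > budget:
                break
            mpos.add(i)
        i -= 1
    wl = max(lo, i + 1)
    i = seed_e
    right_m = 0
    while i < hi and right_m <= budget:
        if arr[i] != tarr[i + d]:
            right_m += 1
            if right_m > budget:
                break
            mpos.add(i)
        i += 1
    wr = min(hi, i)
    return wl, wr, mpos


def _add_pair(found: set, kind: str, start: int, L: int, mism: int, d: int,
              n: int) -> None:
    p1 = start
    p2 = _partner_interval(kind, start + d, L, n)
    a, b = sorted((p1, p2))
    if a == b:  # the two occurrences must be distinct intervals
        return
    found.add(DispersedRepeat(kind=kind, length=L, pos1=a, pos2=b,
                              mismatches=mism))


def _suppress_nested(calls: list[DispersedRepeat]) -> list[DispersedRepeat]:
    """Drop pairs whose both occurrences are nested inside a longer reported
    pair of the same orientation."""
    kept: list[DispersedRepeat] = []
    for c in calls:
        nested = False
        for big in kept:
            if big.kind != c.kind or big.length < c.length:
                continue
            if (
                big.pos1 <= c.pos1 and c.pos1 + c.length <= big.pos1 + big.length
                and big.pos2 <= c.pos2
                and c.pos2 + c.length <= big.pos2 + big.length
            ):
                nested = True
                break
        if not nested:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# tandem repeats


def find_tandem_repeats(
    sequence: str,
    min_period: int = 7,
    max_period: int = 200,
    min_copies: float = 2.0,
    min_span: int = 22,
    max_mismatch_frac: float = 0.2,
) -> list[TandemRepeat]:
    """Approximate tandem arrays by period-wise self-comparison.

    For each period p, positions where S[i] == S[i+p] are matched; maximal
    stretches whose mismatch fraction stays <= ``max_mismatch_frac`` and that
    span >= max(min_span, min_copies * p) are reported with a majority-vote
    consensus unit. Arrays explained by a smaller reported period at the same
    locus are suppressed.
    """
    sequence = sequence.upper()
    n = len(sequence)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    calls: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        match = arr[: n - p] == arr[p:]
        seed_len = 8  # chance seeds are ~0.25^8 per position; filtered later
        claimed_until = -1
        for rs, re in _bool_run_intervals(match):
            if re - rs < seed_len or rs < claimed_until:
                continue
            i, j, mism = _extend_tandem(match, rs, re, p, max_mismatch_frac)
            span_end = j + p  # include the final (shifted-out) copy
            span = span_end - i
            if span >= max(min_span, min_copies * p) and span / p >= min_copies:
                motif = _consensus_unit(sequence[i:span_end], p)
                if _is_primitive_approx(motif):
                    calls.append(
                        TandemRepeat(period=p, copies=round(span / p, 2),
                                     start=i, end=span_end, motif=motif)
                    )
                    claimed_until = span_end
    return _suppress_tandem_multiples(sorted(calls, key=lambda t: (t.start,
                                                                   t.period)))


def _bool_run_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _extend_tandem(match: np.ndarray, rs: int, re: int, p: int, frac: float):
    """Extend a seed run of period-p self-matches outward while the overall
    mismatch fraction stays within ``frac`` (and mismatch gaps stay shorter
    than half a period). Returns (start, end, mismatches) on match indices."""
    cap = max(2, p // 2)
    i, j, mism = rs, re, 0
    # right: accept while the extension segment's own mismatch fraction
    # stays within budget (so random flanks terminate the array quickly)
    k, run, add = j, 0, 0
    best = j
    while k < len(match) and run < cap:
        if match[k]:
            run = 0
            if add / (k + 1 - j) <= frac:
                best = k + 1
        else:
            add += 1
            run += 1
        k += 1
    mism += sum(1 for t in range(j, best) if not match[t])
    j = best
    # left, symmetrically
    k, run, add = i - 1, 0, 0
    best = i
    while k >= 0 and run < cap:
        if match[k]:
            run = 0
            if add / (i - k) <= frac:
                best = k
        else:
            add += 1
            run += 1
        k -= 1
    mism += sum(1 for t in range(best, i) if not match[t])
    i = best
    return i, j, mism


def _consensus_unit(span_seq: str, p: int) -> str:
    cols = []
    for c in range(p):
        chars = span_seq[c::p]
        counts = {b: chars.count(b) for b in set(chars)}
        cols.append(max(counts, key=counts.get))
    return "".join(cols)


def _is_primitive_approx(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p // 2 + 1):
        if p % d == 0:
            reps = [motif[i : i + d] for i in range(0, p, d)]
            agree = sum(
                1
                for r in reps
                for a, b in zip(r, reps[0])
                if a == b
            )
            if agree >= 0.9 * p:
                return False
    return True


def _suppress_tandem_multiples(calls: list[TandemRepeat]) -> list[TandemRepeat]:
    kept: list[TandemRepeat] = []
    for c in calls:
        redundant = False
        for k in kept:
            if k.period >= c.period:
                continue
            overlap = min(k.end, c.end) - max(k.start, c.start)
            if overlap >= 0.9 * c.span_length:
                redundant = True
                break
        if not redundant:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# attribution


def attribute_repeats(
    calls,
    partition: QuadripartitePartition | None,
    annotation=None,
) -> pd.DataFrame:
    """Assign each repeat call to LSC/SSC/IR (by span midpoint) and to
    CDS/intron/IGS; returns one row per call with a ``straddles_junction``
    flag for calls crossing a region boundary."""
    rows = []
    for c in calls:
        if hasattr(c, "span"):
            s, e = c.span
        elif isinstance(c, TandemRepeat):
            s, e = c.start, c.end
        else:  # dispersed repeat: attribute the first occurrence
            s, e = c.pos1, c.pos1 + c.length
        mid = (s + e) // 2
        if partition is not None:
            sreg = partition.region_of(mid)
            straddle = partition.region_of(s) != partition.region_of(
                max(s, e - 1)
            )
        else:
            sreg, straddle = "NA", False
        if annotation is not None:
            freg = annotation.class_at(mid)
            locus = annotation.locus_at(mid)
        else:
            freg, locus = "NA", ""
        rows.append(
            {
                "type": type(c).__name__,
                "start": s,
                "end": e,
                "structural_region": sreg,
                "functional_region": freg,
                "locus": locus,
                "straddles_junction": bool(straddle),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["type", "start", "end", "structural_region",
                 "functional_region", "locus", "straddles_junction"],
    )
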