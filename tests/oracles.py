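"""Independent brute-force oracles used by the test suite.

These deliberately re-derive every quantity from first principles with
different algorithms from the package (quadratic scans, explicit pathway
enumeration, direct pair loops) so that agreement is informative.
"""

from __future__ import annotations

import itertools
import math

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


# ---------------------------------------------------------------------------
# SSRs: test every (start, period) pair


def _primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def ssr_oracle(seq: str, thresholds=None):
    thresholds = thresholds or {1: 7, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}
    n = len(seq)
    runs = []  # (period, start, copies)
    for p in sorted(thresholds):
        for s in range(n - p + 1):
            unit = seq[s : s + p]
            if "N" in unit or not _primitive(unit):
                continue
            if s >= p and seq[s - p : s] == unit:
                continue  # not left-maximal
            copies = 1
            while seq[s + copies * p : s + (copies + 1) * p] == unit:
                copies += 1
            if copies >= thresholds[p]:
                runs.append((p, s, copies, unit))
    # suppress overlaps in (period asc, start asc) priority
    claimed = [False] * n
    kept = []
    for p, s, copies, unit in sorted(runs):
        span = range(s, s + copies * p)
        if any(claimed[i] for i in span):
            continue
        for i in span:
            claimed[i] = True
        canonical = min(unit[i:] + unit[:i] for i in range(len(unit)))
        kept.append((canonical, p, copies, s, s + copies * p))
    return sorted(kept, key=lambda r: (r[3], r[1]))


# ---------------------------------------------------------------------------
# dispersed repeats: per-diagonal mismatch scan over all diagonals


def _transform(seq: str, kind: str) -> str:
    if kind == "F":
        return seq
    if kind == "P":
        return revcomp(seq)
    if kind == "R":
        return seq[::-1]
    return "".join(COMP[c] for c in seq)


def dispersed_oracle(seq: str, min_len=30, max_mismatch=3):
    """Full-diagonal scan (no seeding): for every orientation and every
    alignment offset, enumerate the maximal gapless windows with at most
    ``max_mismatch`` mismatches directly from the mismatch positions."""
    import numpy as np

    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    found = set()
    k = max_mismatch
    for kind in ("F", "P", "R", "C"):
        tarr = np.frombuffer(_transform(seq, kind).encode(), dtype=np.uint8)
        for d in range(-(n - 1), n):
            lo, hi = max(0, -d), min(n, n - d)
            if hi - lo < min_len:
                continue
            mm = arr[lo:hi] != tarr[lo + d : hi + d]
            # boundary positions: sentinel lo-1, mismatches, sentinel hi
            pos = np.concatenate(
                ([lo - 1], np.flatnonzero(mm) + lo, [hi])
            )
            m = len(pos) - 2
            # window t spans (pos[t], pos[min(t+k+1, m+1)]) exclusive
            t_max = max(0, m - k)
            t = np.arange(0, t_max + 1)
            last = np.minimum(t + k + 1, m + 1)
            starts = pos[t] + 1
            ends = pos[last]
            lengths = ends - starts
            for idx in np.flatnonzero(lengths >= min_len):
                s, e = int(starts[idx]), int(ends[idx])
                used = int(last[idx] - t[idx] - 1)
                L = e - s
                if kind in ("F", "C"):
                    p2 = s + d
                else:
                    p2 = n - (s + d) - L
                a, b = sorted((s, p2))
                if a == b:
                    continue
                found.add((kind, L, a, b, used))
    return _suppress_nested_tuples(found)


def _suppress_nested_tuples(found):
    ordered = sorted(found, key=lambda r: (-r[1], r[2]))
    kept = []
    for c in ordered:
        kind, L, p1, p2, m = c
        nested = False
        for kk, LL, q1, q2, _ in kept:
            if kk != kind or LL < L:
                continue
            if q1 <= p1 and p1 + L <= q1 + LL and q2 <= p2 and p2 + L <= q2 + LL:
                nested = True
                break
        if not nested:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Nei-Gojobori via explicit enumeration (Biopython translation)


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate(table=11))


def ng86_oracle(seq1: str, seq2: str):
    """(ka, ks) by direct enumeration; None where undefined."""
    bases = "ACGT"
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(ch not in bases for ch in c1 + c2):
            continue
        for c in (c1, c2):
            aa = _translate(c)
            syn = 0.0
            for pos in range(3):
                for b in bases:
                    if b == c[pos]:
                        continue
                    alt = c[:pos] + b + c[pos + 1 :]
                    if _translate(alt) == aa and aa != "*":
                        syn += 1 / 3
            s_sites += syn / 2
            n_sites += (3 - syn) / 2
        diff_pos = [k for k in range(3) if c1[k] != c2[k]]
        if not diff_pos:
            continue
        path_syn = []
        for order in itertools.permutations(diff_pos):
            cur, syn, through_stop = c1, 0, False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if _translate(nxt) == "*" and nxt != c2:
                    through_stop = True
                if _translate(nxt) == _translate(cur) and _translate(nxt) != "*":
                    syn += 1
                cur = nxt
            path_syn.append((through_stop, syn))
        usable = [s for t, s in path_syn if not t] or [s for _, s in path_syn]
        sd = sum(usable) / len(usable)
        s_diffs += sd
        n_diffs += len(diff_pos) - sd
    ps, pn = s_diffs / s_sites, n_diffs / n_sites
    if ps >= 0.75 or pn >= 0.75:
        return None
    ks = -0.75 * math.log(1 - 4 * ps / 3)
    ka = -0.75 * math.log(1 - 4 * pn / 3)
    return ka, ks


# ---------------------------------------------------------------------------
# nucleotide diversity by explicit pair/column loops


def pi_oracle(rows: list[str]) -> float:
    vals = []
    for a, b in itertools.combinations(rows, 2):
        usable = diffs = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                usable += 1
                diffs += x != y
        if usable:
            vals.append(diffs / usable)
    return sum(vals) / len(vals) if vals else float("nan")
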