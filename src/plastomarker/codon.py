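"""Codon usage (RSCU), amino-acid profiles and Nei–Gojobori (1986) Ka/Ks.

Everything uses the bacterial/plastid genetic code (NCBI translation table
11). The Ka/Ks estimator is the classic counting method: per-codon
synonymous site fractions averaged over both sequences, observed differences
averaged over all minimal mutational pathways (unweighted, pathways through
stop codons excluded), and a Jukes–Cantor correction applied to the
proportions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

log = logging.getLogger(__name__)

GENETIC_CODE_ID = 11
BASES = "TCAG"

# amino-acid physicochemical groups: a fixed hydropathy/charge assignment
# (hydrophobic side chains, polar uncharged = hydrophilic, charged acidic/
# basic, and the conformationally special G/P as neutral); partitions the 20
AA_GROUPS = {
    "hydrophobic": set("AVLIFMW"),
    "hydrophilic": set("STCYNQ"),
    "acidic": set("DE"),
    "basic": set("KRH"),
    "neutral": set("GP"),
}


@lru_cache(maxsize=None)
def _code(table_id: int = GENETIC_CODE_ID):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward = dict(table.forward_table)
    for stop in table.stop_codons:
        forward[stop] = "*"
    families: dict[str, list[str]] = {}
    for codon, aa in forward.items():
        families.setdefault(aa, []).append(codon)
    return forward, families


def translate_codon(codon: str, table_id: int = GENETIC_CODE_ID) -> str:
    forward, _ = _code(table_id)
    return forward.get(codon.upper(), "X")


@dataclass
class RSCUTable:
    codon_counts: dict[str, int]
    rscu: dict[str, float]
    aa_frequency: dict[str, float]
    group_fraction: dict[str, float]
    third_position_composition: dict[str, float]


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("-", "")
    if len(seq) % 3:
        log.warning("CDS length %d not divisible by 3; trimming", len(seq))
        seq = seq[: len(seq) - len(seq) % 3]
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def rscu(cds_sequences: list[str], genetic_code: int = GENETIC_CODE_ID) -> RSCUTable:
    """Relative synonymous codon usage over a set of CDS sequences.

    RSCU(c) = count(c) / (family total / degeneracy); stop codons form their
    own family. Internal stops are counted with a warning. Third-position
    base composition is reported alongside.
    """
    forward, families = _code(genetic_code)
    counts: dict[str, int] = {c: 0 for c in forward}
    third = {b: 0 for b in "ACGT"}
    internal_stops = 0
    for seq in cds_sequences:
        codons = _codons(seq)
        for i, c in enumerate(codons):
            if c not in forward:
                continue  # ambiguous codon
            counts[c] += 1
            third[c[2]] += 1
            if forward[c] == "*" and i < len(codons) - 1:
                internal_stops += 1
    if internal_stops:
        log.warning("%d internal stop codons counted", internal_stops)
    rscu_vals: dict[str, float] = {}
    aa_counts: dict[str, int] = {}
    for aa, fam in families.items():
        total = sum(counts[c] for c in fam)
        aa_counts[aa] = total
        for c in fam:
            rscu_vals[c] = counts[c] * len(fam) / total if total else float("nan")
    aa_total = sum(v for a, v in aa_counts.items() if a != "*")
    aa_freq = {
        a: (v / aa_total if aa_total else float("nan"))
        for a, v in sorted(aa_counts.items())
        if a != "*"
    }
    group_frac = {
        g: sum(aa_freq.get(a, 0.0) for a in members)
        for g, members in AA_GROUPS.items()
    }
    t3 = sum(third.values())
    third_comp = {b: (v / t3 if t3 else float("nan")) for b, v in third.items()}
    return RSCUTable(
        codon_counts=counts,
        rscu=rscu_vals,
        aa_frequency=aa_freq,
        group_fraction=group_frac,
        third_position_composition=third_comp,
    )


def amino_acid_profile(cds_sequences: list[str],
                       genetic_code: int = GENETIC_CODE_ID):
    """Translated amino-acid frequencies and physicochemical group
    fractions; raises on an empty input set."""
    if not cds_sequences:
        raise ValueError("amino_acid_profile needs at least one CDS")
    table = rscu(cds_sequences, genetic_code)
    return table.aa_frequency, table.group_fraction


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986


@dataclass
class KaKsResult:
    gene: str
    ka: float
    ks: float
    ratio: float  # NaN when undefined (Ks == 0)
    selection_class: str  # positive | neutral | purifying | undefined
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0


@lru_cache(maxsize=None)
def _syn_fraction(codon: str, table_id: int = GENETIC_CODE_ID) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon: each position
    contributes the fraction of its three possible changes that are
    synonymous; changes to stop codons count as nonsynonymous."""
    forward, _ = _code(table_id)
    aa = forward[codon]
    syn = 0.0
    for pos in range(3):
        fs = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if forward[alt] == aa and aa != "*":
                fs += 1
        syn += fs / 3
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str, table_id: int = GENETIC_CODE_ID):
    """(syn, nonsyn) differences between two codons averaged over all
    minimal mutational pathways; pathways passing through a stop codon are
    excluded (unless all do)."""
    forward, _ = _code(table_id)
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        cur = c1
        steps = []
        via_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            syn = forward[nxt] == forward[cur] and forward[nxt] != "*"
            steps.append(syn)
            if forward[nxt] == "*" and nxt != c2:
                via_stop = True
            cur = nxt
        pathways.append((via_stop, steps))
    usable = [s for stop, s in pathways if not stop] or [s for _, s in pathways]
    syn = sum(sum(steps) for steps in usable) / len(usable)
    return syn, len(positions) - syn


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1 - 4 * p / 3)


def kaks_ng86(
    seq1: str,
    seq2: str,
    gene: str = "",
    genetic_code: int = GENETIC_CODE_ID,
) -> KaKsResult:
    """Counting-method Ka/Ks for a codon-aligned CDS pair.

    Codons containing gaps, N or other ambiguity in either sequence are
    skipped. Raises ValueError when pS or pN reaches 3/4 (correction
    undefined); Ks == 0 leaves the ratio NaN and the class is assigned by
    :func:`classify_selection`.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq1) % 3:
        raise ValueError("aligned length must be a multiple of 3")
    forward, _ = _code(genetic_code)
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if c1 not in forward or c2 not in forward:
            continue
        s1, n1 = _syn_fraction(c1, genetic_code)
        s2, n2 = _syn_fraction(c2, genetic_code)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        sd, nd = _pathway_diffs(c1, c2, genetic_code)
        s_diffs += sd
        n_diffs += nd
    if s_sites == 0 or n_sites == 0:
        raise ValueError("no comparable codons")
    ps, pn = s_diffs / s_sites, n_diffs / n_sites
    ks, ka = _jukes_cantor(ps), _jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else float("nan")
    result = KaKsResult(
        gene=gene, ka=ka, ks=ks, ratio=ratio, selection_class="",
        syn_sites=s_sites, nonsyn_sites=n_sites,
        syn_diffs=s_diffs, nonsyn_diffs=n_diffs,
    )
    result.selection_class = classify_selection(result)
    return result


def classify_selection(kaks: KaKsResult, tol: float = 1e-9) -> str:
    """Selection class from the Ka/Ks ratio: >1 positive, ==1 neutral,
    <1 purifying; Ks == 0 with Ka > 0 is called positive (logged
    convention), 0/0 is undefined."""
    ka, ks = kaks.ka, kaks.ks
    if ks <= tol:
        if ka <= tol:
            return "undefined"
        log.debug("%s: Ks == 0 with Ka > 0; classed positive", kaks.gene)
        return "positive"
    ratio = ka / ks
    if ratio > 1 + tol:
        return "positive"
    if abs(ratio - 1) <= tol:
        return "neutral"
    return "purifying"


def mean_kaks(results: list[KaKsResult]) -> float:
    """Unweighted mean of the defined per-gene ratios (undefined excluded)."""
    vals = [r.ratio for r in results if not math.isnan(r.ratio)]
    return float(sum(vals) / len(vals)) if vals else float("nan")
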