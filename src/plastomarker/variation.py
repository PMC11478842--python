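"""Substitution, indel and nucleotide-diversity accounting on a multiple
plastome alignment.

All estimators use pairwise deletion: a site is usable for a sequence pair
when both rows carry an unambiguous base (A/C/G/T). π is the raw average
pairwise difference per usable site (no Jukes–Cantor correction), matching
the DnaSP convention for gap-rich organellar alignments.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GAP, AlignmentMatrix, RegionAnnotation, is_base
from .structure import QuadripartitePartition

log = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class SNPRecord:
    ref_pos: int
    ref_allele: str
    alt_allele: str
    accession: str
    ts_tv: str  # "Ts" | "Tv"
    structural_region: str = "NA"  # LSC | SSC | IR | NA
    functional_region: str = "NA"  # CDS | intron | IGS | NA
    locus: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class IndelRecord:
    ref_pos: int
    length: int
    kind: str  # "insertion" | "deletion" (relative to the reference)
    accession: str
    structural_region: str = "NA"
    locus: str = ""

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


def classify_substitution(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs
    transversion."""
    if ref == alt:
        raise ValueError("not a substitution")
    if (ref in PURINES) == (alt in PURINES):
        return "Ts"
    return "Tv"


def _region_lookups(
    partition: QuadripartitePartition | None,
    annotation: RegionAnnotation | None,
):
    def structural(pos: int) -> str:
        return partition.region_of(pos) if partition is not None else "NA"

    def functional(pos: int) -> tuple[str, str]:
        if annotation is None:
            return "NA", ""
        return annotation.class_at(pos), annotation.locus_at(pos)

    return structural, functional


def call_snps(
    aln: AlignmentMatrix,
    query_accession: str,
    partition: QuadripartitePartition | None = None,
    annotation: RegionAnnotation | None = None,
) -> list[SNPRecord]:
    """SNPs of a query against the alignment's reference row.

    Every column where reference and query both carry an unambiguous base and
    the bases differ yields one record; multi-nucleotide runs emit one record
    per column. Structural/functional region and locus are attached through
    the reference coordinate when a partition/annotation of the reference
    genome is given.
    """
    if query_accession == aln.reference_id:
        return []
    ref = aln.row(aln.reference_id)
    qry = aln.row(query_accession)
    both = is_base(ref) & is_base(qry)
    diff = both & (ref != qry)
    structural, functional = _region_lookups(partition, annotation)
    out = []
    for col in np.flatnonzero(diff):
        pos = int(aln.column_map[col])
        r, a = chr(ref[col]), chr(qry[col])
        freg, locus = functional(pos)
        out.append(
            SNPRecord(
                ref_pos=pos,
                ref_allele=r,
                alt_allele=a,
                accession=query_accession,
                ts_tv=classify_substitution(r, a),
                structural_region=structural(pos),
                functional_region=freg,
                locus=locus,
            )
        )
    return out


def call_indels(
    aln: AlignmentMatrix,
    query_accession: str,
    partition: QuadripartitePartition | None = None,
    annotation: RegionAnnotation | None = None,
) -> list[IndelRecord]:
    """Indel events of a query against the reference: each maximal run of gap
    characters present in exactly one of the two rows is one event; columns
    gapped in both rows are ignored. ``ref_pos`` is the nearest preceding
    reference coordinate (0 for leading events)."""
    if query_accession == aln.reference_id:
        return []
    ref = aln.row(aln.reference_id)
    qry = aln.row(query_accession)
    keep = ~((ref == GAP) & (qry == GAP))
    cols = np.flatnonzero(keep)
    r, q = ref[cols], qry[cols]
    structural, functional = _region_lookups(partition, annotation)
    # nearest non-gap reference coordinate at or before each kept column
    cm = aln.column_map[cols]
    prev_ref = np.maximum.accumulate(np.where(cm >= 0, cm, -1))
    prev_ref = np.maximum(prev_ref, 0)
    events = []
    state = None  # ("insertion"|"deletion", start_index)
    for i in range(len(cols) + 1):
        kind = None
        if i < len(cols):
            if r[i] == GAP and q[i] != GAP:
                kind = "insertion"
            elif q[i] == GAP and r[i] != GAP:
                kind = "deletion"
        if state is not None and (kind != state[0]):
            s = state[1]
            pos = int(prev_ref[s])
            _, locus = functional(pos)
            events.append(
                IndelRecord(
                    ref_pos=pos,
                    length=i - s,
                    kind=state[0],
                    accession=query_accession,
                    structural_region=structural(pos),
                    locus=locus,
                )
            )
            state = None
        if kind is not None and state is None:
            state = (kind, i)
    return events


# ---------------------------------------------------------------------------
# nucleotide diversity


def _pair_stats(matrix: np.ndarray, columns: np.ndarray | None = None):
    """Per-pair (differences, usable sites) over the given columns."""
    sub = matrix if columns is None else matrix[:, columns]
    base = is_base(sub)
    n = sub.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    diffs = np.empty(len(pairs), dtype=np.int64)
    usable = np.empty(len(pairs), dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        both = base[i] & base[j]
        usable[k] = int(both.sum())
        diffs[k] = int((both & (sub[i] != sub[j])).sum())
    return pairs, diffs, usable


def _pi_from_stats(diffs: np.ndarray, usable: np.ndarray) -> float:
    ok = usable > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(diffs[ok] / usable[ok]))


def window_pi(
    aln: AlignmentMatrix, window: int = 100, step: int = 100
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity over alignment columns.

    π per window is the average over all row pairs of differences per usable
    site; windows with no usable site for any pair carry NaN and are flagged
    in the ``defined`` column.
    """
    if aln.n_rows < 2:
        raise ValueError("window_pi needs at least two rows")
    rows = []
    for start in range(0, aln.n_cols, step):
        end = min(start + window, aln.n_cols)
        cols = np.arange(start, end)
        _, diffs, usable = _pair_stats(aln.matrix, cols)
        pi = _pi_from_stats(diffs, usable)
        rows.append(
            {
                "start": start,
                "end": end,
                "pi": pi,
                "usable_sites": int(usable.max(initial=0)),
                "defined": not np.isnan(pi),
            }
        )
        if end == aln.n_cols:
            break
    return pd.DataFrame(rows)


def locus_table(
    aln: AlignmentMatrix,
    annotation: RegionAnnotation,
    partition: QuadripartitePartition | None = None,
) -> pd.DataFrame:
    """Per-locus diversity table: π, indel events and indel diversity,
    mutation count (distinct polymorphic columns + indel events) and aligned
    length for every annotated locus of the reference genome."""
    base = is_base(aln.matrix)
    gap = aln.matrix == GAP
    n = aln.n_rows
    pair_idx = list(itertools.combinations(range(n), 2))
    rows = []
    for name, cls, positions in annotation.loci():
        cols = _columns_of_positions(aln, positions)
        if cols.size == 0:
            continue
        sub = aln.matrix[:, cols]
        sub_base = base[:, cols]
        sub_gap = gap[:, cols]
        diffs = usable = 0
        pair_pis = []
        indel_events_pairwise = 0
        for i, j in pair_idx:
            both = sub_base[i] & sub_base[j]
            u = int(both.sum())
            d = int((both & (sub[i] != sub[j])).sum())
            if u > 0:
                pair_pis.append(d / u)
            # gap runs present in exactly one of the two rows
            indel_events_pairwise += _count_gap_events(sub_gap[i], sub_gap[j])
        pi = float(np.mean(pair_pis)) if pair_pis else float("nan")
        # distinct polymorphic columns among unambiguous bases
        poly = 0
        for c in range(sub.shape[1]):
            col = sub[:, c][sub_base[:, c]]
            if col.size >= 2 and np.unique(col).size > 1:
                poly += 1
        n_pairs = len(pair_idx) or 1
        indel_div = indel_events_pairwise / n_pairs / sub.shape[1]
        mutations = poly + round(indel_events_pairwise / n_pairs)
        rows.append(
            {
                "locus": name,
                "class": cls,
                "pi": pi,
                "indel_diversity": indel_div,
                "mutations": int(mutations),
                "length": int(sub.shape[1]),
                "polymorphic_columns": int(poly),
            }
        )
    return pd.DataFrame(rows)


def _columns_of_positions(aln: AlignmentMatrix, positions: np.ndarray) -> np.ndarray:
    """Alignment columns whose reference coordinate is in ``positions``."""
    posset = np.zeros(int(aln.column_map.max()) + 2, dtype=bool)
    posset[positions[positions <= aln.column_map.max()]] = True
    cm = aln.column_map
    mask = (cm >= 0) & posset[np.clip(cm, 0, len(posset) - 1)]
    return np.flatnonzero(mask)


def _count_gap_events(gap_i: np.ndarray, gap_j: np.ndarray) -> int:
    """Number of maximal gap runs present in exactly one row of a pair."""
    one = gap_i ^ gap_j
    if not one.any():
        return 0
    padded = np.concatenate(([False], one, [False]))
    return int(np.count_nonzero(np.diff(padded.astype(np.int8)) == 1))


def locus_pi(
    aln: AlignmentMatrix,
    annotation: RegionAnnotation,
    partition: QuadripartitePartition | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-locus π plus unweighted per-class means (gene region, intron,
    IGS)."""
    table = locus_table(aln, annotation, partition)
    class_means = {
        cls: float(grp["pi"].mean())
        for cls, grp in table.dropna(subset=["pi"]).groupby("class")
    }
    return table, class_means


def rank_hotspots(locus_df: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k loci by π (descending); ties broken by mutation count then
    locus name. Input is a :func:`locus_table` DataFrame."""
    df = locus_df.dropna(subset=["pi"]).copy()
    df = df.sort_values(
        by=["pi", "mutations", "locus"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df.head(k)


def pairwise_p_distance(
    aln: AlignmentMatrix, accession_subset: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of p-distances (differences per usable site,
    pairwise deletion)."""
    ids = accession_subset or aln.ids
    idx = [aln.ids.index(a) for a in ids]
    sub = aln.matrix[idx]
    pairs, diffs, usable = _pair_stats(sub)
    mat = np.zeros((len(ids), len(ids)))
    for (i, j), d, u in zip(pairs, diffs, usable):
        p = d / u if u > 0 else float("nan")
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=ids, columns=ids)


def intraspecific_diversity(aln: AlignmentMatrix) -> dict[str, float]:
    """Mean pairwise p-distance among the accessions of each species with
    more than one accession."""
    dist = pairwise_p_distance(aln)
    out = {}
    species = sorted(set(aln.species_of.values()))
    for sp in species:
        accs = aln.accessions_of(sp)
        if len(accs) < 2:
            continue
        vals = [
            dist.loc[a, b] for a, b in itertools.combinations(accs, 2)
        ]
        out[sp] = float(np.mean(vals))
    return out


def substitution_summary(snp_lists: dict[str, list[SNPRecord]]) -> pd.DataFrame:
    """Substitution-type and region totals per accession (unordered base
    pairs A/G, C/T, A/C, C/G, G/T, A/T plus LSC/SSC/IR rows)."""
    pair_names = ["A/G", "C/T", "A/C", "C/G", "G/T", "A/T"]
    rows = {}
    for acc, snps in snp_lists.items():
        counts = dict.fromkeys(pair_names, 0)
        regions = {"LSC": 0, "SSC": 0, "IR": 0}
        ts = tv = 0
        for s in snps:
            key = "/".join(sorted((s.ref_allele, s.alt_allele)))
            if key in counts:
                counts[key] += 1
            if s.ts_tv == "Ts":
                ts += 1
            else:
                tv += 1
            if s.structural_region in regions:
                regions[s.structural_region] += 1
        rows[acc] = {
            **counts, "Total": len(snps), **regions, "Ts": ts, "Tv": tv,
        }
    return pd.DataFrame(rows).T


def indel_summary(indel_lists: dict[str, list[IndelRecord]]) -> pd.DataFrame:
    """Indel event counts, total bases and average length per structural
    region per accession."""
    rows = []
    for acc, indels in indel_lists.items():
        for region in ("LSC", "SSC", "IR", "NA"):
            sel = [d for d in indels if d.structural_region == region]
            if region == "NA" and not sel:
                continue
            total = sum(d.length for d in sel)
            rows.append(
                {
                    "accession": acc,
                    "region": region,
                    "indel_events": len(sel),
                    "indel_bases": total,
                    "mean_length": total / len(sel) if sel else 0.0,
                }
            )
    return pd.DataFrame(rows)
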