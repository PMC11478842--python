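"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open on the linearized circle throughout the
package; GenBank's 1-based inclusive locations are converted on read and
restored on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DNA = "ACGT"
_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

#: region-class codes used in RegionAnnotation arrays
CLS_CDS = 0  # exonic part of any gene (CDS, tRNA or rRNA; "gene region")
CLS_INTRON = 1
CLS_IGS = 2
CLASS_NAMES = {CLS_CDS: "CDS", CLS_INTRON: "intron", CLS_IGS: "IGS"}

GAP = ord("-")
_BASES = frozenset(b"ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N and gaps preserved)."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


@dataclass
class GeneFeature:
    """A located gene on a plastome.

    ``parts`` are ordered exon intervals; the gaps between consecutive parts
    of one feature are its introns. A feature wrapping the linearization
    origin is split into two parts and flagged with ``wraps_origin``.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA | pseudogene
    strand: str  # '+' | '-'
    parts: list[tuple[int, int]]
    intron_count: int = 0
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        self.parts = [(int(s), int(e)) for s, e in self.parts]
        for s, e in self.parts:
            if e <= s:
                raise ValueError(f"empty part [{s},{e}) in feature {self.name}")

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    @property
    def span(self) -> tuple[int, int]:
        """Outermost interval covered, introns included."""
        return (min(s for s, _ in self.parts), max(e for _, e in self.parts))


@dataclass
class PlastomeRecord:
    """One circular plastome: sequence, identity and feature annotation."""

    accession: str
    species: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be nonempty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("sequence must be nonempty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Sequence of [start, end) on the circle; end may exceed length."""
        n = self.length
        span = end - start
        if span > n or span < 0:
            raise ValueError("invalid interval on circle")
        start %= n
        if start + span <= n:
            return self.sequence[start : start + span]
        return self.sequence[start:] + self.sequence[: start + span - n]


@dataclass
class RegionAnnotation:
    """Per-position functional class (gene region / intron / IGS) plus a
    locus map assigning every position to a named locus.

    Locus names are gene symbols for gene regions, ``gene_intronK`` for
    introns, and ``upstream-downstream`` flanking-gene names for spacers.
    """

    classes: np.ndarray  # uint8 codes, len == genome length
    locus_index: np.ndarray  # int32 index into locus_names
    locus_names: list[str]
    locus_classes: list[int]

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        self.locus_index = np.asarray(self.locus_index, dtype=np.int32)

    def class_at(self, pos: int) -> str:
        return CLASS_NAMES[int(self.classes[pos])]

    def locus_at(self, pos: int) -> str:
        idx = int(self.locus_index[pos])
        return self.locus_names[idx] if idx >= 0 else ""

    def base_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.classes == code))
            for code, name in CLASS_NAMES.items()
        }

    def loci(self) -> list[tuple[str, str, np.ndarray]]:
        """Return (name, class, positions) for every named locus."""
        out = []
        for i, name in enumerate(self.locus_names):
            positions = np.flatnonzero(self.locus_index == i)
            if positions.size:
                out.append((name, CLASS_NAMES[self.locus_classes[i]], positions))
        return out


class AlignmentMatrix:
    """Gapped multi-accession alignment with species labels and a designated
    reference row used for coordinate mapping."""

    def __init__(
        self,
        ids: Sequence[str],
        rows: Sequence[str],
        species_of: dict[str, str],
        reference_id: str,
    ) -> None:
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate accession ids in alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        if reference_id not in ids:
            raise ValueError(f"reference {reference_id!r} not in alignment")
        missing = [a for a in ids if a not in species_of]
        if missing:
            raise ValueError(f"accessions missing from species map: {missing}")
        self.ids = ids
        self.matrix = np.frombuffer(
            "".join(r.upper() for r in rows).encode(), dtype=np.uint8
        ).reshape(len(ids), -1)
        self.species_of = {a: species_of[a] for a in ids}
        self.reference_id = reference_id
        ref = self.matrix[self.ids.index(reference_id)]
        non_gap = ref != GAP
        cmap = np.cumsum(non_gap) - 1
        cmap[~non_gap] = -1
        #: alignment column -> reference ungapped coordinate, or -1 at gaps
        self.column_map = cmap.astype(np.int64)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row(self, accession: str) -> np.ndarray:
        return self.matrix[self.ids.index(accession)]

    def row_str(self, accession: str) -> str:
        return self.row(accession).tobytes().decode()

    def ungapped(self, accession: str) -> str:
        return self.row_str(accession).replace("-", "")

    def accessions_of(self, species: str) -> list[str]:
        return [a for a in self.ids if self.species_of[a] == species]

    def columns_of_ref_interval(self, start: int, end: int) -> np.ndarray:
        """Alignment columns whose reference coordinate falls in [start, end),
        plus inserted (reference-gap) columns strictly inside the interval."""
        cm = self.column_map
        inside = (cm >= start) & (cm < end)
        # reference-gap columns between flanking in-interval reference columns
        filled = np.maximum.accumulate(np.where(cm >= 0, cm, -1))
        interior_gap = (cm == -1) & (filled >= start) & (filled < end - 1)
        return np.flatnonzero(inside | interior_gap)


def is_base(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of unambiguous bases (A/C/G/T) in a uint8 code array."""
    return (
        (codes == ord("A"))
        | (codes == ord("C"))
        | (codes == ord("G"))
        | (codes == ord("T"))
    )
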