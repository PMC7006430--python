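"""Nucleotide census of duplicated-sequence regions.

Takes classified self-alignment hits and turns them into the quantities of a
transcriptome-wide duplex census: merged genomic footprints per class
(inverted = putative dsRNA, tandem = control), nucleotide counts binned by
the length and identity of the hit each nucleotide belongs to, selection of
"long and nearly perfect" structures (> 300 bp, > 96% identity), and the
fraction of duplex nucleotides inside annotated repeats.

Splicing lives here too: a transcript is represented by its pre-mRNA sequence
(first exon through last exon, introns included) plus exon intervals, and the
mature mRNA is the exon concatenation with a coordinate map between the two.
All intervals are 0-based half-open.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .selfalign import AlignmentHit

__all__ = [
    "Transcript",
    "CoordinateMap",
    "DuplexRegion",
    "DuplexStructure",
    "CensusTable",
    "RepeatOverlap",
    "MAX_PRE_MRNA_LENGTH",
    "DEFAULT_LENGTH_BINS",
    "DEFAULT_IDENTITY_BINS",
    "splice_mrna",
    "merge_intervals",
    "merge_to_regions",
    "census",
    "select_structures",
    "repeat_overlap_fraction",
]

#: Pre-mRNAs longer than this are discarded at load time.
MAX_PRE_MRNA_LENGTH = 1_000_000

#: Bins are (lo, hi] with a strict lower edge, matching the strict > 40 bp /
#: > 70% acceptance filters. Length bins partition (40, inf) = [41, inf) bp;
#: identity bins partition (0, 100] percent. The top cells — > 300 bp and
#: > 96% — isolate the long, nearly perfect duplexes of interest.
DEFAULT_LENGTH_BINS: tuple[tuple[float, float], ...] = (
    (40, 100),
    (100, 300),
    (300, math.inf),
)
DEFAULT_IDENTITY_BINS: tuple[tuple[float, float], ...] = (
    (0, 70),
    (70, 80),
    (80, 90),
    (90, 96),
    (96, 100),
)


@dataclass(frozen=True)
class Transcript:
    """One gene's transcript: pre-mRNA sequence plus exon structure.

    ``exons`` are 0-based half-open intervals in pre-mRNA coordinates, sorted
    and non-overlapping. One transcript per gene (the longest variant).
    """

    gene_id: str
    chrom: str
    strand: str
    pre_mrna_sequence: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        L = len(self.pre_mrna_sequence)
        prev_end = 0
        for s, e in self.exons:
            if not (0 <= s < e <= L):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside sequence [0,{L})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted at ({s},{e})")
            prev_end = e

    @property
    def pre_mrna_length(self) -> int:
        return len(self.pre_mrna_sequence)


class CoordinateMap:
    """Bijection between exonic pre-mRNA positions and mRNA positions."""

    def __init__(self, exons: Sequence[tuple[int, int]]):
        self._exons = list(exons)
        self._starts = [s for s, _ in self._exons]
        offsets = []
        total = 0
        for s, e in self._exons:
            offsets.append(total)
            total += e - s
        self._offsets = offsets
        self._mrna_length = total

    @property
    def mrna_length(self) -> int:
        return self._mrna_length

    def pre_to_mrna(self, pos: int) -> int:
        """mRNA position of an exonic pre-mRNA position; KeyError if intronic."""
        i = bisect_right(self._starts, pos) - 1
        if i >= 0:
            s, e = self._exons[i]
            if s <= pos < e:
                return self._offsets[i] + (pos - s)
        raise KeyError(f"pre-mRNA position {pos} is not exonic")

    def mrna_to_pre(self, pos: int) -> int:
        if not (0 <= pos < self._mrna_length):
            raise KeyError(f"mRNA position {pos} out of range")
        i = bisect_right(self._offsets, pos) - 1
        s, _ = self._exons[i]
        return s + (pos - self._offsets[i])

    def is_exonic_interval(self, interval: tuple[int, int]) -> bool:
        """True if every base of the pre-mRNA interval lies within one exon run."""
        s, e = interval
        for xs, xe in self._exons:
            if xs <= s and e <= xe:
                return True
        return False


def splice_mrna(transcript: Transcript) -> tuple[str, CoordinateMap]:
    """Mature mRNA sequence (exon concatenation) and its coordinate map."""
    if not transcript.exons:
        raise ValueError(f"{transcript.gene_id}: transcript has no exons")
    mrna = "".join(transcript.pre_mrna_sequence[s:e] for s, e in transcript.exons)
    return mrna, CoordinateMap(transcript.exons)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge intervals; book-ended intervals ([a,b) and [b,c)) merge."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class DuplexRegion:
    """Merged footprint of one class of hits on one transcript.

    Every nucleotide of the footprint carries the (aligned length, identity)
    of the LONGEST hit covering it — ties broken by higher identity, then by
    leftmost hit start — so multi-hit nucleotides are counted once, in the
    bin of their dominant hit.
    """

    seq_id: str
    interval: tuple[int, int]
    class_label: str
    attr_length: np.ndarray  # per-base aligned length of the attributed hit
    attr_identity: np.ndarray  # per-base identity of the attributed hit

    @property
    def n_bases(self) -> int:
        return self.interval[1] - self.interval[0]


def merge_to_regions(hits: Sequence[AlignmentHit], class_label: str) -> list[DuplexRegion]:
    """Merge both arm intervals of every hit into per-transcript regions.

    Overlapping or book-ended arm intervals coalesce; each covered nucleotide
    is attributed to the longest covering hit (ties: higher identity, then
    leftmost hit start).
    """
    by_seq: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)

    regions: list[DuplexRegion] = []
    for seq_id in sorted(by_seq):
        seq_hits = by_seq[seq_id]
        arms = [h.q_interval for h in seq_hits] + [h.s_interval for h in seq_hits]
        merged = merge_intervals(arms)
        # Attribution priority: longest, then highest identity, then leftmost.
        ranked = sorted(
            seq_hits,
            key=lambda h: (-h.aln_length, -h.identity_pct, h.q_interval[0], h.s_interval[0]),
        )
        for rs, re_ in merged:
            n = re_ - rs
            attr_len = np.zeros(n, dtype=np.int64)
            attr_ident = np.zeros(n, dtype=np.float64)
            assigned = np.zeros(n, dtype=bool)
            for h in ranked:
                for s, e in (h.q_interval, h.s_interval):
                    s, e = max(s, rs), min(e, re_)
                    if s >= e:
                        continue
                    sl = slice(s - rs, e - rs)
                    free = ~assigned[sl]
                    np.putmask(attr_len[sl], free, h.aln_length)
                    np.putmask(attr_ident[sl], free, h.identity_pct)
                    assigned[sl] |= free
            if not assigned.all():  # pragma: no cover - merge covers by construction
                raise AssertionError("merged region contains unattributed nucleotides")
            regions.append(
                DuplexRegion(
                    seq_id=seq_id,
                    interval=(rs, re_),
                    class_label=class_label,
                    attr_length=attr_len,
                    attr_identity=attr_ident,
                )
            )
    return regions


def _validate_bins(bins: Sequence[tuple[float, float]], span: tuple[float, float], what: str) -> None:
    lo, hi = span
    if not bins:
        raise ValueError(f"{what}: no bins")
    if bins[0][0] != lo or bins[-1][1] != hi:
        raise ValueError(f"{what}: bins must partition ({lo}, {hi}]")
    for (a, b), (c, _d) in zip(bins, bins[1:]):
        if b != c or b <= a:
            raise ValueError(f"{what}: bins must be contiguous and increasing")


def _bin_index(values: np.ndarray, bins: Sequence[tuple[float, float]]) -> np.ndarray:
    """Index of the (lo, hi] bin of each value (strict lower edge)."""
    edges = np.array([b[0] for b in bins] + [bins[-1][1]], dtype=float)
    idx = np.searchsorted(edges, values, side="left") - 1
    if np.any(idx < 0) or np.any(idx >= len(bins)):
        raise ValueError("value outside bin range")
    return idx


@dataclass
class CensusTable:
    """Hit counts and merged nucleotide counts per class and bin cell.

    ``nt[class]`` and ``hits[class]`` are (n_length_bins x n_identity_bins)
    arrays; totals are the merged-footprint size and the number of distinct
    hits. Bin cell sums equal the totals by construction (every nucleotide is
    attributed to exactly one hit, every hit falls in exactly one cell).
    """

    organism: str
    molecule: str  # "mRNA" | "pre-mRNA"
    length_bins: tuple[tuple[float, float], ...]
    identity_bins: tuple[tuple[float, float], ...]
    nt: dict[str, np.ndarray] = field(default_factory=dict)
    hits: dict[str, np.ndarray] = field(default_factory=dict)

    def nt_total(self, class_label: str) -> int:
        return int(self.nt[class_label].sum())

    def hit_total(self, class_label: str) -> int:
        return int(self.hits[class_label].sum())

    def cell_labels(self) -> list[tuple[str, str]]:
        def fmt(b):
            hi = "inf" if math.isinf(b[1]) else f"{b[1]:g}"
            return f"({b[0]:g},{hi}]"

        return [
            (fmt(lb), fmt(ib)) for lb in self.length_bins for ib in self.identity_bins
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in sorted(self.nt):
            for i, lb in enumerate(self.length_bins):
                for j, ib in enumerate(self.identity_bins):
                    hi_l = "inf" if math.isinf(lb[1]) else f"{lb[1]:g}"
                    rows.append(
                        {
                            "organism": self.organism,
                            "molecule": self.molecule,
                            "class": cls,
                            "length_bin": f"({lb[0]:g},{hi_l}]",
                            "identity_bin": f"({ib[0]:g},{ib[1]:g}]",
                            "bp": int(self.nt[cls][i, j]),
                            "hit_count": int(self.hits[cls][i, j]),
                        }
                    )
        return pd.DataFrame(rows)


def census(
    ids_regions: Sequence[DuplexRegion],
    tds_regions: Sequence[DuplexRegion],
    length_bins: Sequence[tuple[float, float]] = DEFAULT_LENGTH_BINS,
    identity_bins: Sequence[tuple[float, float]] = DEFAULT_IDENTITY_BINS,
    *,
    ids_hits: Sequence[AlignmentHit] = (),
    tds_hits: Sequence[AlignmentHit] = (),
    organism: str = "synthetic",
    molecule: str = "pre-mRNA",
) -> CensusTable:
    """Per-bin nucleotide and hit counts for the two duplication classes.

    Each merged-footprint nucleotide is counted in the cell of its attributed
    hit's (aligned length, identity); each hit is counted once in its own
    cell. ``length_bins`` must partition (40, inf) and ``identity_bins`` must
    partition (0, 100], both as (lo, hi] with strict lower edges.
    """
    length_bins = tuple(tuple(b) for b in length_bins)
    identity_bins = tuple(tuple(b) for b in identity_bins)
    _validate_bins(length_bins, (40, math.inf), "length_bins")
    _validate_bins(identity_bins, (0, 100), "identity_bins")

    table = CensusTable(
        organism=organism,
        molecule=molecule,
        length_bins=length_bins,
        identity_bins=identity_bins,
    )
    shape = (len(length_bins), len(identity_bins))
    for cls, regions, cls_hits in (
        ("IDS", ids_regions, ids_hits),
        ("TDS", tds_regions, tds_hits),
    ):
        nt = np.zeros(shape, dtype=np.int64)
        for region in regions:
            li = _bin_index(region.attr_length.astype(float), length_bins)
            ii = _bin_index(region.attr_identity, identity_bins)
            np.add.at(nt, (li, ii), 1)
        hit_counts = np.zeros(shape, dtype=np.int64)
        for h in cls_hits:
            i = _bin_index(np.array([float(h.aln_length)]), length_bins)[0]
            j = _bin_index(np.array([h.identity_pct]), identity_bins)[0]
            hit_counts[i, j] += 1
        table.nt[cls] = nt
        table.hits[cls] = hit_counts
    return table


@dataclass(frozen=True)
class DuplexStructure:
    """A paired two-arm putative dsRNA (or tandem control) structure."""

    seq_id: str
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    identity_pct: float
    aln_length: int
    orientation: str  # "inverted" | "tandem"
    gap_bp: int

    @property
    def footprint(self) -> tuple[int, int]:
        return (min(self.arm1[0], self.arm2[0]), max(self.arm1[1], self.arm2[1]))

    @property
    def mean_arm_length(self) -> float:
        return ((self.arm1[1] - self.arm1[0]) + (self.arm2[1] - self.arm2[0])) / 2.0

    @classmethod
    def from_hit(cls, hit: AlignmentHit) -> "DuplexStructure":
        return cls(
            seq_id=hit.seq_id,
            arm1=hit.q_interval,
            arm2=hit.s_interval,
            identity_pct=hit.identity_pct,
            aln_length=hit.aln_length,
            orientation=hit.orientation,
            gap_bp=hit.gap_bp,
        )


def select_structures(
    hits: Sequence[AlignmentHit],
    min_length: int = 300,
    min_identity: float = 96.0,
) -> list[DuplexStructure]:
    """Long, nearly perfect structures with overlap deduplication.

    Keeps hits with aligned length strictly > ``min_length`` and identity
    strictly > ``min_identity``. Where candidate footprints overlap on the
    same transcript, only the highest-identity one is retained (ties: longer,
    then leftmost). Both arms lie within the same transcript by construction
    of the intra-transcript scan.
    """
    candidates = [
        h for h in hits if h.aln_length > min_length and h.identity_pct > min_identity
    ]
    candidates.sort(key=lambda h: (-h.identity_pct, -h.aln_length, h.q_interval[0]))
    kept: list[DuplexStructure] = []
    for h in candidates:
        fs, fe = h.q_interval[0], max(h.q_interval[1], h.s_interval[1])
        overlaps = any(
            st.seq_id == h.seq_id and fs < st.footprint[1] and st.footprint[0] < fe
            for st in kept
        )
        if not overlaps:
            kept.append(DuplexStructure.from_hit(h))
    kept.sort(key=lambda s: (s.seq_id, s.arm1, s.arm2))
    return kept


@dataclass(frozen=True)
class RepeatOverlap:
    """Duplex-footprint base count inside annotated repeats.

    ``available`` is False when no annotation was supplied at all (repeat
    content unknown); an annotation that is present but empty yields
    ``overlap_bp == 0`` with ``note`` flagging that no repeats are annotated.
    """

    overlap_bp: int | None
    total_bp: int
    available: bool
    note: str = ""

    @property
    def fraction(self) -> float | None:
        if not self.available or self.total_bp == 0:
            return None
        return self.overlap_bp / self.total_bp


def repeat_overlap_fraction(
    regions: Sequence[DuplexRegion],
    repeat_annotation: dict[str, Sequence[tuple[int, int]]] | None,
) -> RepeatOverlap:
    """Overlap of merged duplex footprints with a repeat annotation.

    ``repeat_annotation`` maps transcript id to repeat intervals (0-based
    half-open); ``None`` means no annotation is available and the operation
    reports exactly that rather than a spurious zero.
    """
    total = sum(r.n_bases for r in regions)
    if repeat_annotation is None:
        return RepeatOverlap(None, total, available=False, note="not available")
    merged_repeats = {sid: merge_intervals(ivs) for sid, ivs in repeat_annotation.items()}
    overlap = 0
    for region in regions:
        rs, re_ = region.interval
        for s, e in merged_repeats.get(region.seq_id, ()):
            overlap += max(0, min(e, re_) - max(s, rs))
    note = "" if any(merged_repeats.values()) else "no repeats annotated"
    return RepeatOverlap(overlap, total, available=True, note=note)
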