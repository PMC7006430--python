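"""Detection of duplicated sequences within a single transcript.

A transcript that contains two reversely oriented near-copies of the same
sequence (an inverted duplicated sequence, IDS) can fold back on itself and
form a long intramolecular RNA duplex — the kind of structure that cytoplasmic
dsRNA sensors such as MDA5 mistake for a viral replication intermediate.
Same-strand near-copies (tandem duplicated sequences, TDS) cannot base-pair
with each other and serve as the structural null control.

This module finds both kinds of duplication by aligning a sequence against
itself (and against its reverse complement) with a seed-and-extend local
aligner, then applies the operative filters: aligned length strictly greater
than 40 bp and percent identity strictly greater than 70. An import path for
standard 12-column tabular alignment output (BLAST ``-outfmt 6`` dialect)
allows any external aligner to feed the same downstream census.

Coordinates are 0-based half-open throughout; the tabular reader converts
from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

__all__ = [
    "AlignmentHit",
    "HitFilter",
    "revcomp",
    "self_align",
    "parse_tabular_hits",
    "classify_and_gap_filter",
    "write_tabular_hits",
]

# Scoring of the internal aligner. Acceptance of a hit is defined by the
# post-filter (length, identity), not by engine internals; these values give
# positive expected score down to ~70% identity (1*0.7 - 2*0.3 = 0.1).
MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = 7  # cost of a length-1 gap
GAP_EXTEND = 2  # incremental cost per additional gapped base
SEED_LENGTH = 11
XDROP = 20

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SAME = "same"
OPPOSITE = "opposite"


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One local self-alignment: two intervals on the same transcript.

    ``strand_relation`` is ``"same"`` for plus/plus hits (tandem duplication,
    TDS) and ``"opposite"`` for plus/minus hits (inverted duplication, IDS —
    a putative dsRNA stem). Both intervals are 0-based half-open on the
    forward strand of the transcript; canonical ordering puts the interval
    that starts first in ``q_interval``.
    """

    seq_id: str
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    strand_relation: str
    identity_pct: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.strand_relation not in (SAME, OPPOSITE):
            raise ValueError(f"strand_relation must be 'same' or 'opposite', got {self.strand_relation!r}")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not (0.0 < self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct must be in (0, 100], got {self.identity_pct}")
        for iv in (self.q_interval, self.s_interval):
            if iv[0] < 0 or iv[1] <= iv[0]:
                raise ValueError(f"invalid interval {iv}")
        if (self.q_interval[0], self.q_interval[1]) > (self.s_interval[0], self.s_interval[1]):
            raise ValueError("q_interval must start at or before s_interval (canonical ordering)")

    @property
    def orientation(self) -> str:
        """``"inverted"`` for opposite-strand hits, ``"tandem"`` for same-strand."""
        return "inverted" if self.strand_relation == OPPOSITE else "tandem"

    @property
    def gap_bp(self) -> int:
        """Distance between the arms, floored at 0 for overlapping (palindromic) arms."""
        return max(0, self.s_interval[0] - self.q_interval[1])

    @property
    def footprint(self) -> tuple[int, int]:
        """Union span of the two arms."""
        return (self.q_interval[0], max(self.q_interval[1], self.s_interval[1]))


@dataclass(frozen=True)
class HitFilter:
    """Post-alignment acceptance filter.

    Both thresholds are strict: a hit survives only if its aligned length is
    > ``min_length`` and its identity is > ``min_identity_pct``. ``max_gap``
    optionally restricts the distance between the two arms (the variant used
    to check that results are robust to the loop length between the arms).
    """

    min_length: int = 40
    min_identity_pct: float = 70.0
    max_gap: int | None = None

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not (0.0 < self.min_identity_pct <= 100.0):
            raise ValueError("min_identity_pct must be in (0, 100]")
        if self.max_gap is not None and self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")

    def passes(self, hit: AlignmentHit) -> bool:
        return hit.aln_length > self.min_length and hit.identity_pct > self.min_identity_pct


def _segment_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _segment_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity and column count of the best global alignment of two arms.

    Identity counts matching columns over all aligned columns, gap columns
    included — the convention of the tabular alignment format's %identity.
    """
    aln = _segment_aligner().align(a, b)[0]
    counts = aln.counts()
    n_cols = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / n_cols, n_cols


def _xdrop_extend(a: str, b: str) -> tuple[int, int, int]:
    """Gapped x-drop extension of ``a`` against ``b`` anchored at their starts.

    Returns ``(ai, bi, score)`` such that aligning ``a[:ai]`` to ``b[:bi]``
    achieves the best extension score. Affine gaps: a gap of length k costs
    ``GAP_OPEN + (k - 1) * GAP_EXTEND``. Rows whose cells all fall more than
    XDROP below the running best are abandoned, which keeps the band narrow.
    """
    la, lb = len(a), len(b)
    best = 0
    best_ai = best_aj = 0
    NEG = -(10**9)

    # H: best score ending at (i, j); E: gap in a (consuming b); F: gap in b.
    lo, hi = 0, 0  # inclusive window of j for the current row
    H = {0: 0}
    E = {0: NEG}
    F = {0: NEG}
    i = 0
    # Row 0: gaps consuming b only.
    j = 1
    while j <= lb:
        s = -(GAP_OPEN + (j - 1) * GAP_EXTEND)
        if s < best - XDROP:
            break
        H[j] = s
        E[j] = s
        F[j] = NEG
        hi = j
        j += 1

    while i < la:
        i += 1
        nH: dict[int, int] = {}
        nE: dict[int, int] = {}
        nF: dict[int, int] = {}
        new_lo, new_hi = None, 0
        ai = a[i - 1]
        for j in range(lo, min(hi + 1, lb) + 1):
            f_open = H.get(j, NEG) - GAP_OPEN
            f_ext = F.get(j, NEG) - GAP_EXTEND
            f = f_open if f_open >= f_ext else f_ext
            e_open = nH.get(j - 1, NEG) - GAP_OPEN
            e_ext = nE.get(j - 1, NEG) - GAP_EXTEND
            e = e_open if e_open >= e_ext else e_ext
            if j > 0:
                sub = MATCH_SCORE if ai == b[j - 1] else MISMATCH_SCORE
                m = H.get(j - 1, NEG) + sub
            else:
                m = NEG
            h = max(m, e, f)
            if h < best - XDROP:
                continue
            nH[j] = h
            nE[j] = e
            nF[j] = f
            if new_lo is None:
                new_lo = j
            new_hi = j
            if h > best:
                best = h
                best_ai, best_aj = i, j
        if new_lo is None:
            break
        H, E, F = nH, nE, nF
        lo, hi = new_lo, new_hi
    return best_ai, best_aj, best


def _find_raw_alignments(
    query: str,
    target: str,
    *,
    exclude_diagonal: bool,
    min_span: int,
) -> list[tuple[int, int, int, int]]:
    """Seed-and-extend: maximal-scoring local alignments of query vs target.

    Returns raw endpoint tuples ``(q0, q1, t0, t1)`` on the given strings.
    ``exclude_diagonal`` restricts seeds to t > q (same-strand self-comparison:
    removes the trivial identity diagonal and mirror duplicates at the source).
    """
    k = SEED_LENGTH
    lq = len(query)
    if lq < k:
        return []
    index: dict[str, list[int]] = {}
    for t in range(len(target) - k + 1):
        kmer = target[t : t + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(t)

    # Seeds grouped by diagonal so each duplicated region is extended once.
    seeds: list[tuple[int, int, int]] = []  # (diag, q, t)
    for q in range(lq - k + 1):
        kmer = query[q : q + k]
        if "N" in kmer:
            continue
        for t in index.get(kmer, ()):
            if exclude_diagonal and t <= q:
                continue
            seeds.append((t - q, q, t))
    seeds.sort()

    found: list[tuple[int, int, int, int]] = []

    def covered(q: int, t: int) -> bool:
        for q0, q1, t0, t1 in found:
            if q0 <= q and q + k <= q1 and t0 <= t and t + k <= t1:
                return True
        return False

    for _diag, q, t in seeds:
        if covered(q, t):
            continue
        # Forward from the seed end, backward from the seed start.
        f_ai, f_aj, _ = _xdrop_extend(query[q + k :], target[t + k :])
        b_ai, b_aj, _ = _xdrop_extend(query[:q][::-1], target[:t][::-1])
        q0, q1 = q - b_ai, q + k + f_ai
        t0, t1 = t - b_aj, t + k + f_aj
        if exclude_diagonal and (q0, q1) == (t0, t1):
            continue
        if min(q1 - q0, t1 - t0) < min_span:
            continue
        found.append((q0, q1, t0, t1))

    # An alignment found from a late seed may engulf one found earlier from a
    # noisier seed; keep only alignments not contained in a longer one.
    found.sort(key=lambda r: (r[1] - r[0]) + (r[3] - r[2]), reverse=True)
    kept: list[tuple[int, int, int, int]] = []
    for q0, q1, t0, t1 in found:
        contained = any(
            K[0] <= q0 and q1 <= K[1] and K[2] <= t0 and t1 <= K[3] for K in kept
        )
        if not contained:
            kept.append((q0, q1, t0, t1))
    return kept


def _canonical_hit(
    seq_id: str,
    iv_a: tuple[int, int],
    iv_b: tuple[int, int],
    strand: str,
    identity_pct: float,
    aln_length: int,
) -> AlignmentHit:
    # Canonical ordering: leftmost start first; ties broken by shortest interval.
    a, b = sorted([iv_a, iv_b], key=lambda iv: (iv[0], iv[1] - iv[0]))
    return AlignmentHit(
        seq_id=seq_id,
        q_interval=a,
        s_interval=b,
        strand_relation=strand,
        identity_pct=identity_pct,
        aln_length=aln_length,
    )


def _dedup(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse mirror duplicates: key is the unordered interval pair + strand."""
    seen: dict[tuple, AlignmentHit] = {}
    for hit in hits:
        key = (hit.seq_id, hit.strand_relation, hit.q_interval, hit.s_interval)
        prev = seen.get(key)
        if prev is None or hit.identity_pct > prev.identity_pct:
            seen[key] = hit
    return sorted(
        seen.values(),
        key=lambda h: (h.seq_id, h.q_interval, h.s_interval, h.strand_relation),
    )


def self_align(
    sequence: str,
    filter: HitFilter = HitFilter(),
    *,
    seq_id: str = "seq",
) -> list[AlignmentHit]:
    """All duplicated sequences within ``sequence``, both orientations.

    Same-strand duplications are found by comparing the sequence to itself
    (off-diagonal), opposite-strand ones by comparing it to its reverse
    complement. Extension is gap-aware; the reported identity of each hit is
    that of the best global alignment of the two arm segments. Hits are
    returned in canonical ordering with mirror duplicates collapsed and the
    length/identity filter applied (``max_gap`` is NOT applied here — see
    :func:`classify_and_gap_filter`).
    """
    seq = sequence.upper()
    n_bad = sum(1 for c in seq if c not in "ACGT")
    if len(seq) == 0 or n_bad > 0.5 * len(seq):
        raise ValueError(
            f"sequence {seq_id!r}: {n_bad}/{len(seq)} non-ACGT characters; "
            "more than 50% ambiguous — refusing to scan"
        )
    if len(seq) < filter.min_length:
        raise ValueError(
            f"sequence {seq_id!r} shorter ({len(seq)}) than min_length {filter.min_length}"
        )

    hits: list[AlignmentHit] = []
    L = len(seq)
    # min_span: arm shorter than this cannot yield aln_length > min_length
    # even with gaps opening within the x-drop budget.
    min_span = max(SEED_LENGTH, filter.min_length - XDROP)

    for strand, target in ((SAME, seq), (OPPOSITE, revcomp(seq))):
        raw = _find_raw_alignments(
            seq, target, exclude_diagonal=(strand == SAME), min_span=min_span
        )
        for q0, q1, t0, t1 in raw:
            identity, n_cols = _segment_identity(seq[q0:q1], target[t0:t1])
            if strand == OPPOSITE:
                iv_b = (L - t1, L - t0)
            else:
                iv_b = (t0, t1)
            hit = _canonical_hit(seq_id, (q0, q1), iv_b, strand, identity, n_cols)
            if strand == SAME and hit.q_interval == hit.s_interval:
                continue  # residual self-identity
            if filter.passes(hit):
                hits.append(hit)
    return _dedup(hits)


def parse_tabular_hits(path, filter: HitFilter = HitFilter()) -> list[AlignmentHit]:
    """Read self-alignment hits from 12-column tabular alignment output.

    Expected columns: query, subject, %identity, aligned length, mismatches,
    gap opens, qstart, qend, sstart, send, e-value, bitscore — with 1-based
    inclusive coordinates and opposite strand encoded by sstart > send
    (the ``-outfmt 6`` dialect). Applies the same filtering, trivial-hit
    removal, canonical ordering and mirror collapse as :func:`self_align`.

    Raises ``ValueError`` naming the offending line for malformed rows and
    for qstart > qend (the format keeps query coordinates ascending).
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}")
            try:
                qid = fields[0]
                identity = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})") from None
            if qstart > qend:
                raise ValueError(f"{path}:{lineno}: qstart > qend ({qstart} > {qend})")
            if qstart < 1 or sstart < 1 or send < 1:
                raise ValueError(f"{path}:{lineno}: coordinates must be 1-based positive")
            q_iv = (qstart - 1, qend)
            if sstart <= send:
                strand = SAME
                s_iv = (sstart - 1, send)
            else:
                strand = OPPOSITE
                s_iv = (send - 1, sstart)
            if strand == SAME and q_iv == s_iv:
                continue  # trivial self-hit
            hit = _canonical_hit(qid, q_iv, s_iv, strand, identity, length)
            if filter.passes(hit):
                hits.append(hit)
    return _dedup(hits)


def write_tabular_hits(hits: Sequence[AlignmentHit], path) -> None:
    """Write hits in the 12-column tabular dialect read by :func:`parse_tabular_hits`.

    Mismatch/gap columns are not tracked per hit and are emitted as the
    mismatch count implied by identity over aligned columns, with 0 gap opens;
    e-value and bitscore are placeholders (0, 0).
    """
    with open(path, "w") as fh:
        for h in hits:
            mismatches = round(h.aln_length * (1.0 - h.identity_pct / 100.0))
            if h.strand_relation == SAME:
                sstart, send = h.s_interval[0] + 1, h.s_interval[1]
            else:
                sstart, send = h.s_interval[1], h.s_interval[0] + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.seq_id,
                        h.seq_id,
                        f"{h.identity_pct:.3f}",
                        h.aln_length,
                        mismatches,
                        0,
                        h.q_interval[0] + 1,
                        h.q_interval[1],
                        sstart,
                        send,
                        0,
                        0,
                    )
                )
                + "\n"
            )


def classify_and_gap_filter(
    hits: Iterable[AlignmentHit], filter: HitFilter = HitFilter()
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Partition hits into (IDS, TDS) and apply the optional inter-arm gap cap.

    The gap is the distance from the end of the first arm to the start of the
    second, floored at 0 for overlapping (palindromic) arms; hits whose gap
    exceeds ``filter.max_gap`` are dropped from both classes.
    """
    ids_hits: list[AlignmentHit] = []
    tds_hits: list[AlignmentHit] = []
    for hit in hits:
        if filter.max_gap is not None and hit.gap_bp > filter.max_gap:
            continue
        (ids_hits if hit.strand_relation == OPPOSITE else tds_hits).append(hit)
    return ids_hits, tds_hits
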