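"""Independent oracles shared by the test suite.

Everything here recomputes expected values by a route independent of the
implementation under test: exact big-integer binomial sums, Hamming identity
over raw sequence windows, brute-force per-base interval arithmetic, and
Biopython's dynamic-programming aligner as an external alignment engine.
"""

from __future__ import annotations

import math

from Bio import Align

from dsrnacensus import AlignmentHit, revcomp
from dsrnacensus.synthetic import hamming_identity


def log10_binom_tail_exact(k: int, n: int) -> float:
    """log10 P(X <= k), X ~ Binomial(n, 1/2), by exact integer summation."""
    total = sum(math.comb(n, i) for i in range(k + 1))
    return math.log10(total) - n * math.log10(2.0)


def window_identity(seq: str, hit: AlignmentHit) -> float | None:
    """Exact percent identity of the sequence over a hit's reported windows.

    Independent of the aligner's own scoring: for equal-length (ungapped)
    windows it is a direct Hamming identity of the two arm substrings, with
    the second arm reverse-complemented for opposite-strand hits. Returns
    None for unequal windows (gapped alignment), where Hamming is undefined.
    """
    a = seq[hit.q_interval[0] : hit.q_interval[1]]
    b = seq[hit.s_interval[0] : hit.s_interval[1]]
    if hit.strand_relation == "opposite":
        b = revcomp(b)
    if len(a) != len(b):
        return None
    return hamming_identity(a, b)


def local_dp_aligner() -> Align.PairwiseAligner:
    """Exhaustive local DP aligner with the scan's scoring scheme."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def global_arm_identity(arm_a: str, arm_b: str) -> float:
    """DP-oracle identity of an arm pair (matching columns over all columns)."""
    aligner = local_dp_aligner()
    aligner.mode = "global"
    aln = aligner.align(arm_a, arm_b)[0]
    c = aln.counts()
    return 100.0 * c.identities / (c.identities + c.mismatches + c.gaps)


def matches_planted(hit: AlignmentHit, planted, min_overlap_frac: float = 0.8) -> bool:
    """True when a hit's arms each cover >= 80% of the planted arms, with the
    orientation the truth record predicts."""
    want = "opposite" if planted.orientation == "inverted" else "same"
    if hit.strand_relation != want:
        return False
    for hiv, piv in ((hit.q_interval, planted.arm1), (hit.s_interval, planted.arm2)):
        overlap = min(hiv[1], piv[1]) - max(hiv[0], piv[0])
        if overlap < min_overlap_frac * (piv[1] - piv[0]):
            return False
    return True


def brute_force_union(intervals) -> set[int]:
    """Per-base set union of intervals — the merge/census conservation oracle."""
    covered: set[int] = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return covered
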