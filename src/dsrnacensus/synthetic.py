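"""Synthetic transcriptomes with planted duplications and read pileups.

Every downstream stage — the self-alignment scan, the nucleotide census, the
depletion test and the editing quantification — is exercised against data
with known ground truth generated here. The generator emulates the three
ingredients the analysis consumes from real data:

1. gene models: alternating exons and introns of configurable lengths over a
   uniform-random background sequence;
2. repeat insertions: pairs of diverged copies of a repeat family placed in
   inverted or tandem orientation inside a gene (the mechanism by which
   mobile-element proliferation creates endogenous dsRNA stems), each pair
   recorded as a :class:`PlantedDuplex` truth record;
3. read pileups: per-adenosine coverage drawn Poisson, A-to-G mismatches
   drawn binomial at a configured per-site editing rate.

The mutation model is substitution-only (no indels), so the true arm-pair
identity of every planted duplex is an exact Hamming identity and the
identity ground truth is unambiguous. Everything is deterministic for a
fixed seed: one root seed per run, per-gene substreams derived by stable
(CRC-32) hashing of the gene id so results do not depend on generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .census import Transcript
from .editing import EditingProfile
from .selfalign import revcomp

__all__ = [
    "RepeatFamily",
    "PlantedDuplex",
    "SimConfig",
    "generate_repeat_copy",
    "generate_transcriptome",
    "simulate_pileup",
    "expected_pairwise_identity",
    "hamming_identity",
    "write_fasta",
    "write_exon_bed",
    "write_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

BOTH_EXONIC = "both-arms-exonic"
INTRONIC = "at-least-one-arm-intronic"

IntSampler = Callable[[np.random.Generator], int]


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat element consensus and its per-copy divergence.

    Each inserted copy substitutes every consensus base independently with
    probability ``divergence`` (uniformly to one of the three other bases),
    mimicking the accumulated divergence of mobile-element copies.
    """

    consensus: str
    name: str = "repeat"
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not self.consensus or any(c not in "ACGT" for c in self.consensus):
            raise ValueError("consensus must be a non-empty string over {A,C,G,T}")
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")


@dataclass(frozen=True)
class PlantedDuplex:
    """Ground-truth record of one inserted pair of repeat copies.

    Arm intervals are 0-based half-open in final pre-mRNA coordinates.
    ``true_identity`` is the exact (Hamming) percent identity between the two
    arms in duplex orientation.
    """

    gene: str
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    orientation: str  # "inverted" | "tandem"
    true_identity: float
    compartment: str  # BOTH_EXONIC | INTRONIC

    def __post_init__(self) -> None:
        if self.orientation not in ("inverted", "tandem"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not (0.0 < self.true_identity <= 100.0):
            raise ValueError("true_identity must be in (0, 100]")
        if self.compartment not in (BOTH_EXONIC, INTRONIC):
            raise ValueError(f"bad compartment {self.compartment!r}")
        if self.arm1[1] > self.arm2[0] and self.arm2[1] > self.arm1[0]:
            raise ValueError("arms overlap")


def _const(value: int) -> IntSampler:
    return lambda rng: value


def _uniform_int(lo: int, hi: int) -> IntSampler:
    return lambda rng: int(rng.integers(lo, hi + 1))


def as_sampler(value: int | tuple[int, int] | IntSampler) -> IntSampler:
    """Coerce an int (constant), (lo, hi) tuple (uniform) or callable."""
    if callable(value):
        return value
    if isinstance(value, int):
        if value <= 0:
            raise ValueError("length/count values must be positive")
        return _const(value)
    lo, hi = value
    if lo <= 0 or hi < lo:
        raise ValueError(f"bad sampler range ({lo}, {hi})")
    return _uniform_int(lo, hi)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic transcriptome.

    Length scales are a desk-scale caricature of vertebrate gene anatomy:
    a handful of exons of a few hundred bp separated by introns several
    times longer, with on average one planted repeat pair per gene. Repeat
    lengths of 60-500 bp bracket the short/long structure boundary (300 bp)
    and divergence up to 0.04 per copy spans arm-pair identities from ~92%
    to 100% (families may override per-insertion divergence).
    """

    n_genes: int = 100
    n_exons: int | tuple[int, int] | IntSampler = (2, 6)
    exon_length: int | tuple[int, int] | IntSampler = (150, 400)
    intron_length: int | tuple[int, int] | IntSampler = (200, 1500)
    insertion_rate: float = 1.0  # planted pairs per gene (Poisson mean)
    insertions_per_gene: int | None = None  # exact count; overrides the rate
    p_inverted: float = 0.5
    divergence: float = 0.02
    repeat_length: int | tuple[int, int] | IntSampler = (60, 500)
    families: tuple[RepeatFamily, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0.0 <= self.p_inverted <= 1.0):
            raise ValueError("p_inverted must be in [0, 1]")
        if not (0.0 <= self.divergence <= 0.5):
            raise ValueError("divergence must be in [0, 0.5]")
        if self.insertion_rate < 0:
            raise ValueError("insertion_rate must be >= 0")


def _gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene substream: root seed + stable CRC-32 hash of the gene id."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(gene_id.encode())])
    )


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_repeat_copy(family: RepeatFamily, rng: np.random.Generator) -> str:
    """One diverged copy: each base substituted independently with
    probability ``family.divergence``, uniformly to a different base."""
    arr = np.frombuffer(family.consensus.encode(), dtype=np.uint8).copy()
    idx = np.searchsorted(_BASES, arr)  # consensus validated to ACGT
    mutate = rng.random(len(arr)) < family.divergence
    if mutate.any():
        shift = rng.integers(1, 4, size=int(mutate.sum()))
        idx[mutate] = (idx[mutate] + shift) % 4
    return _BASES[idx].tobytes().decode()


def hamming_identity(a: str, b: str) -> float:
    """Exact percent identity of two equal-length ungapped arms."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def expected_pairwise_identity(divergence: float) -> float:
    """Expected percent identity of two independent copies at divergence d.

    A column matches when neither copy mutated, (1-d)^2, or both mutated to
    the same of the three alternative bases, d^2/3.
    """
    d = divergence
    return 100.0 * ((1 - d) ** 2 + d * d / 3.0)


def _draw_insertion_points(
    segments: Sequence[tuple[str, int, int]],
    n_points: int,
    used: set[int],
    rng: np.random.Generator,
) -> list[tuple[int, str]]:
    """Distinct interior inter-base positions, each tagged with its feature type.

    A point p in the interior of a segment (strictly between its first and
    last base) receives the inserted copy between base p-1 and base p, so the
    copy lands wholly inside that exon or intron and never splits a
    previously planted arm (arms occupy zero width in pre-insertion
    coordinates at their own distinct points).
    """
    candidates = [
        (s + 1, e, kind) for kind, s, e in segments if e - s >= 2
    ]  # interior points of each segment: [s+1, e-1]
    total = sum(hi - lo for lo, hi, _ in candidates)
    if total <= len(used):
        raise ValueError("gene too short to fit the requested insertions")
    points: list[tuple[int, str]] = []
    for _ in range(n_points):
        for _attempt in range(200):
            r = int(rng.integers(0, total))
            for lo, hi, kind in candidates:
                span = hi - lo
                if r < span:
                    p = lo + r
                    break
                r -= span
            if p not in used:
                used.add(p)
                points.append((p, kind))
                break
        else:
            raise ValueError("could not place insertion: gene interior exhausted")
    return points


def generate_transcriptome(
    config: SimConfig,
) -> tuple[list[Transcript], list[PlantedDuplex]]:
    """Generate gene models with planted duplications and their truth records.

    Deterministic for a fixed ``config.rng_seed``. Raises ``ValueError`` when
    an insertion cannot fit in a generated gene.
    """
    n_exons = as_sampler(config.n_exons)
    exon_len = as_sampler(config.exon_length)
    intron_len = as_sampler(config.intron_length)
    repeat_len = as_sampler(config.repeat_length)

    transcripts: list[Transcript] = []
    planted: list[PlantedDuplex] = []

    for gi in range(config.n_genes):
        gene_id = f"gene{gi:05d}"
        rng = _gene_rng(config.rng_seed, gene_id)

        # Alternating exon/intron segments in base (pre-insertion) coordinates.
        k = max(1, n_exons(rng))
        segments: list[tuple[str, int, int]] = []
        pos = 0
        for xi in range(k):
            L = exon_len(rng)
            segments.append(("exon", pos, pos + L))
            pos += L
            if xi < k - 1:
                L = intron_len(rng)
                segments.append(("intron", pos, pos + L))
                pos += L
        base_len = pos
        base_seq = random_sequence(base_len, rng)

        if config.insertions_per_gene is not None:
            n_pairs = config.insertions_per_gene
        else:
            n_pairs = int(rng.poisson(config.insertion_rate))

        used_points: set[int] = set()
        insertions: list[tuple[int, str]] = []  # (base point, copy sequence)
        gene_truth: list[dict] = []
        for _ in range(n_pairs):
            if config.families:
                family = config.families[int(rng.integers(0, len(config.families)))]
            else:
                family = RepeatFamily(
                    consensus=random_sequence(repeat_len(rng), rng),
                    name="denovo",
                    divergence=config.divergence,
                )
            copy1 = generate_repeat_copy(family, rng)
            copy2 = generate_repeat_copy(family, rng)
            inverted = bool(rng.random() < config.p_inverted)
            arm2_seq = revcomp(copy2) if inverted else copy2
            identity = hamming_identity(copy1, copy2)
            (p1, k1), (p2, k2) = _draw_insertion_points(
                segments, 2, used_points, rng
            )
            if p2 < p1:  # arm1 is the leftmost arm
                (p1, k1), (p2, k2) = (p2, k2), (p1, k1)
                first_seq, second_seq = arm2_seq, copy1
            else:
                first_seq, second_seq = copy1, arm2_seq
            insertions.append((p1, first_seq))
            insertions.append((p2, second_seq))
            gene_truth.append(
                {
                    "p1": p1,
                    "p2": p2,
                    "len1": len(first_seq),
                    "len2": len(second_seq),
                    "orientation": "inverted" if inverted else "tandem",
                    "identity": identity,
                    "compartment": BOTH_EXONIC
                    if (k1 == "exon" and k2 == "exon")
                    else INTRONIC,
                }
            )

        insertions.sort()
        ins_points = [p for p, _ in insertions]
        ins_lengths = [len(s) for _, s in insertions]
        cum = np.concatenate([[0], np.cumsum(ins_lengths)])

        def shift(base_pos: int) -> int:
            """Total inserted length at points <= base_pos."""
            i = np.searchsorted(ins_points, base_pos, side="right")
            return int(cum[i])

        # Materialize the final sequence.
        parts: list[str] = []
        prev = 0
        for p, s in insertions:
            parts.append(base_seq[prev:p])
            parts.append(s)
            prev = p
        parts.append(base_seq[prev:])
        final_seq = "".join(parts)

        # Exon intervals: an insertion strictly inside an exon extends it.
        exons = []
        for kind, s, e in segments:
            if kind == "exon":
                exons.append((s + shift(s), e + shift(e - 1)))

        transcripts.append(
            Transcript(
                gene_id=gene_id,
                chrom=gene_id,
                strand="+",
                pre_mrna_sequence=final_seq,
                exons=tuple(exons),
            )
        )
        for t in gene_truth:
            a1 = t["p1"] + shift(t["p1"] - 1)  # insertions at earlier points only
            a2 = t["p2"] + shift(t["p2"] - 1)
            planted.append(
                PlantedDuplex(
                    gene=gene_id,
                    arm1=(a1, a1 + t["len1"]),
                    arm2=(a2, a2 + t["len2"]),
                    orientation=t["orientation"],
                    true_identity=t["identity"],
                    compartment=t["compartment"],
                )
            )
    return transcripts, planted


def simulate_pileup(
    region: tuple[int, int],
    sequence: str,
    mean_coverage: float,
    editing_rate: float,
    rng: np.random.Generator,
    *,
    contig: str = "seq",
) -> EditingProfile:
    """Pileup over the adenosines of ``sequence`` within ``region``.

    Coverage per adenosine is Poisson(``mean_coverage``); the G-count is
    Binomial(coverage, ``editing_rate``). Zero mean coverage yields an
    entirely uncovered (unexpressed) region.
    """
    if not (0.0 <= editing_rate <= 1.0):
        raise ValueError("editing_rate must be in [0, 1]")
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be >= 0")
    s, e = region
    positions = np.array(
        [i for i in range(s, min(e, len(sequence))) if sequence[i] == "A"],
        dtype=np.int64,
    )
    cov = rng.poisson(mean_coverage, size=len(positions)).astype(np.int64)
    g = rng.binomial(cov, editing_rate) if len(positions) else np.array([], dtype=np.int64)
    return EditingProfile(contig, positions, cov.astype(np.int64) - g, np.asarray(g, dtype=np.int64))


# ---------------------------------------------------------------------------
# Text-format writers (coordinate conventions declared in headers)


def write_fasta(transcripts: Sequence[Transcript], path, *, spliced: bool = False) -> None:
    from .census import splice_mrna

    with open(path, "w") as fh:
        for tr in transcripts:
            seq = splice_mrna(tr)[0] if spliced else tr.pre_mrna_sequence
            fh.write(f">{tr.gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_exon_bed(transcripts: Sequence[Transcript], path) -> None:
    with open(path, "w") as fh:
        fh.write("# exon intervals, 0-based half-open, pre-mRNA coordinates\n")
        for tr in transcripts:
            for s, e in tr.exons:
                fh.write(f"{tr.gene_id}\t{s}\t{e}\texon\n")


def write_truth_table(planted: Sequence[PlantedDuplex], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# planted duplexes, 0-based half-open pre-mRNA coordinates\n"
            "gene\tarm1_start\tarm1_end\tarm2_start\tarm2_end\t"
            "orientation\ttrue_identity\tcompartment\n"
        )
        for p in planted:
            fh.write(
                f"{p.gene}\t{p.arm1[0]}\t{p.arm1[1]}\t{p.arm2[0]}\t{p.arm2[1]}\t"
                f"{p.orientation}\t{p.true_identity:.4f}\t{p.compartment}\n"
            )
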