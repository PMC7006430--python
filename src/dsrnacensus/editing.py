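"""Expression and A-to-I editing of duplex arms, from read pileups.

Inosine is read as guanosine by reverse transcriptase, so ADAR editing of a
duplex arm shows up as A-to-G mismatches over genomic adenosines. The input
boundary of this module is a pileup table: for each genomic adenosine inside
a duplex region, the number of reads supporting the reference A and the
number supporting G. Read alignment, duplicate-read removal, hyper-edited
read recovery and the random assignment of reads ambiguous between the two
nearly identical arms all happen upstream of this boundary (the upstream
assignment of arm-ambiguous reads must use a seeded RNG for reproducibility).

Definitions used throughout:

* coverage of an adenosine: A-count + G-count after 5-bp end trimming;
* editing level of an adenosine: G / (A + G);
* coverage of an arm: mean coverage over its adenosines (zero-coverage
  adenosines are averaged in as zeros);
* editing index of an arm: sum of G over the arm divided by the summed
  coverage — the coverage-weighted mean editing level;
* FPKM of an arm: mean coverage x 1e9 / (total mapped reads x effective
  read length), with effective length = read length - 2 x trim;
* average inosines per transcript of a structure: editing index x number of
  adenosines, averaged over the two arms;
* residual identity: genomic arm-pair identity minus 100 x average inosines
  / mean arm length — the identity left after editing unwinds base pairs.

Adenosines are counted on the annotated transcript strand: a minus-strand
gene's genomic T positions are adenosines of the transcript, with T-to-C
mismatches entering as A-to-G. Pileups are expected in that orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .census import DuplexStructure

__all__ = [
    "EditingProfile",
    "LibraryStats",
    "ArmSummary",
    "StructureEditingSummary",
    "read_pileup",
    "write_pileup",
    "arm_coverage_and_index",
    "fpkm_to_coverage",
    "coverage_to_fpkm",
    "summarize_structure",
    "residual_identity",
    "expression_filter",
]

UNWOUND_THRESHOLD = 96.0  # residual identity below this: structure "unwound"


@dataclass
class EditingProfile:
    """Per-adenosine A/G read counts over one contig (transcript).

    ``positions`` are 0-based and strictly increasing; only adenosines of the
    transcript appear. Coverage of a site is ``a_counts + g_counts``; its
    editing level is ``g / (a + g)`` where coverage is positive.
    """

    contig: str
    positions: np.ndarray
    a_counts: np.ndarray
    g_counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.a_counts = np.asarray(self.a_counts, dtype=np.int64)
        self.g_counts = np.asarray(self.g_counts, dtype=np.int64)
        if not (len(self.positions) == len(self.a_counts) == len(self.g_counts)):
            raise ValueError("positions/a_counts/g_counts length mismatch")
        if np.any(self.a_counts < 0) or np.any(self.g_counts < 0):
            raise ValueError("negative counts")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def coverage(self) -> np.ndarray:
        return self.a_counts + self.g_counts

    def slice(self, interval: tuple[int, int]) -> "EditingProfile":
        s, e = interval
        mask = (self.positions >= s) & (self.positions < e)
        return EditingProfile(
            self.contig, self.positions[mask], self.a_counts[mask], self.g_counts[mask]
        )


def read_pileup(path) -> dict[str, EditingProfile]:
    """Read a pileup TSV (contig, 0-based pos, ref base, A-count, G-count)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["contig", "pos", "ref", "a_count", "g_count"],
        dtype={"contig": str},
    )
    profiles = {}
    for contig, sub in df.groupby("contig", sort=True):
        sub = sub.sort_values("pos")
        profiles[str(contig)] = EditingProfile(
            str(contig),
            sub["pos"].to_numpy(),
            sub["a_count"].to_numpy(),
            sub["g_count"].to_numpy(),
        )
    return profiles


def write_pileup(profiles: Iterable[EditingProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("# pileup: contig, 0-based position, ref base, A-count, G-count\n")
        for prof in profiles:
            for pos, a, g in zip(prof.positions, prof.a_counts, prof.g_counts):
                fh.write(f"{prof.contig}\t{pos}\tA\t{a}\t{g}\n")


@dataclass(frozen=True)
class LibraryStats:
    """Sequencing-library figures needed to convert coverage to FPKM."""

    total_mapped_reads: int
    read_length: int
    trim_bp: int = 5

    def __post_init__(self) -> None:
        if self.effective_length < 1:
            raise ValueError(
                f"effective read length {self.effective_length} < 1 "
                f"(read_length {self.read_length}, trim {self.trim_bp} per end)"
            )
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")

    @property
    def effective_length(self) -> int:
        return self.read_length - 2 * self.trim_bp


def fpkm_to_coverage(fpkm: float, lib: LibraryStats) -> float:
    """Mean per-base coverage corresponding to an FPKM value.

    coverage = FPKM x total mapped reads x effective read length / 1e9.
    """
    return fpkm * lib.total_mapped_reads * lib.effective_length / 1e9


def coverage_to_fpkm(coverage: float, lib: LibraryStats) -> float:
    """Inverse of :func:`fpkm_to_coverage`."""
    return coverage * 1e9 / (lib.total_mapped_reads * lib.effective_length)


def arm_coverage_and_index(
    profile: EditingProfile, arm: tuple[int, int]
) -> tuple[float, float, int]:
    """(mean coverage, editing index, adenosine count) of one arm.

    The mean averages coverage over ALL adenosines of the arm, zero-coverage
    ones included as zeros. The editing index is total G over total coverage;
    with no covered adenosine (or no adenosines at all) it is undefined and
    returned as NaN.
    """
    sub = profile.slice(arm)
    n = len(sub.positions)
    if n == 0:
        return (math.nan, math.nan, 0)
    cov = sub.coverage
    mean_cov = float(cov.sum()) / n
    total_cov = int(cov.sum())
    if total_cov == 0:
        return (0.0, math.nan, n)
    index = float(sub.g_counts.sum()) / total_cov
    return (mean_cov, index, n)


@dataclass(frozen=True)
class ArmSummary:
    interval: tuple[int, int]
    mean_coverage: float
    fpkm: float
    editing_index: float
    n_adenosines: int

    @property
    def inosines(self) -> float:
        """Expected inosines per transcript in this arm: index x adenosines."""
        if self.n_adenosines == 0 or math.isnan(self.editing_index):
            return math.nan
        return self.editing_index * self.n_adenosines


@dataclass(frozen=True)
class StructureEditingSummary:
    """Expression and editing of one duplex structure's two arms."""

    structure: DuplexStructure
    arm1: ArmSummary
    arm2: ArmSummary
    avg_inosines: float
    residual_identity_pct: float

    @property
    def unwound_below_threshold(self) -> bool:
        """True when editing brings a >96%-identity structure below 96%."""
        return (
            self.structure.identity_pct > UNWOUND_THRESHOLD
            and self.residual_identity_pct < UNWOUND_THRESHOLD
        )


def _avg_inosines(arm1: ArmSummary, arm2: ArmSummary, mode: str) -> float:
    if mode == "per_arm":
        return (arm1.inosines + arm2.inosines) / 2.0
    if mode == "pooled":
        total_g1 = arm1.editing_index * arm1.mean_coverage * arm1.n_adenosines
        total_g2 = arm2.editing_index * arm2.mean_coverage * arm2.n_adenosines
        total_cov = (
            arm1.mean_coverage * arm1.n_adenosines + arm2.mean_coverage * arm2.n_adenosines
        )
        if total_cov == 0:
            return math.nan
        pooled_index = (total_g1 + total_g2) / total_cov
        return pooled_index * (arm1.n_adenosines + arm2.n_adenosines) / 2.0
    raise ValueError(f"unknown inosine averaging mode {mode!r}")


def residual_identity(structure: DuplexStructure, avg_inosines: float) -> float:
    """Identity remaining after editing: original minus the edited fraction.

    residual = identity - 100 x avg_inosines / mean(arm lengths), floored at
    0. With NaN inosines (unexpressed structure) the original identity is
    returned unchanged: no editing evidence, no identity loss.
    """
    if math.isnan(avg_inosines):
        return structure.identity_pct
    loss = 100.0 * avg_inosines / structure.mean_arm_length
    return max(0.0, structure.identity_pct - loss)


def summarize_structure(
    structure: DuplexStructure,
    profile: EditingProfile,
    lib: LibraryStats,
    *,
    inosine_mode: str = "per_arm",
) -> StructureEditingSummary:
    """Coverage, FPKM, editing index, inosines and residual identity per arm.

    ``inosine_mode`` selects how the per-structure inosine number averages
    the two arms: ``"per_arm"`` (default) averages each arm's index x
    adenosine count; ``"pooled"`` uses a single pooled index over both arms.
    """
    arms = []
    for iv in (structure.arm1, structure.arm2):
        mean_cov, index, n_a = arm_coverage_and_index(profile, iv)
        fpkm = (
            math.nan if math.isnan(mean_cov) else coverage_to_fpkm(mean_cov, lib)
        )
        arms.append(
            ArmSummary(
                interval=iv,
                mean_coverage=mean_cov,
                fpkm=fpkm,
                editing_index=index,
                n_adenosines=n_a,
            )
        )
    arm1, arm2 = arms
    avg_ino = _avg_inosines(arm1, arm2, inosine_mode)
    resid = residual_identity(structure, avg_ino)
    return StructureEditingSummary(
        structure=structure,
        arm1=arm1,
        arm2=arm2,
        avg_inosines=avg_ino,
        residual_identity_pct=resid,
    )


def expression_filter(
    summaries: Sequence[StructureEditingSummary],
    fpkm_cutoff: float,
) -> list[StructureEditingSummary]:
    """Structures whose BOTH arms exceed the FPKM cutoff (strict >).

    An arm with undefined FPKM (no adenosines) cannot demonstrate expression
    and fails the filter.
    """
    out = []
    for s in summaries:
        f1, f2 = s.arm1.fpkm, s.arm2.fpkm
        if not math.isnan(f1) and not math.isnan(f2) and f1 > fpkm_cutoff and f2 > fpkm_cutoff:
            out.append(s)
    return out


def summaries_to_frame(summaries: Sequence[StructureEditingSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "seq_id": s.structure.seq_id,
                "arm1_start": s.structure.arm1[0],
                "arm1_end": s.structure.arm1[1],
                "arm2_start": s.structure.arm2[0],
                "arm2_end": s.structure.arm2[1],
                "orientation": s.structure.orientation,
                "identity_pct": s.structure.identity_pct,
                "arm1_coverage": s.arm1.mean_coverage,
                "arm2_coverage": s.arm2.mean_coverage,
                "arm1_fpkm": s.arm1.fpkm,
                "arm2_fpkm": s.arm2.fpkm,
                "arm1_index": s.arm1.editing_index,
                "arm2_index": s.arm2.editing_index,
                "avg_inosines": s.avg_inosines,
                "residual_identity_pct": s.residual_identity_pct,
                "unwound_below_96": s.unwound_below_threshold,
            }
        )
    return pd.DataFrame(rows)
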