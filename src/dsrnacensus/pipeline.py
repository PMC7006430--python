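"""Pipeline orchestration: configuration, file I/O and staged execution.

One run chains the stages simulate -> scan -> census -> stats -> editing on
either a synthetic transcriptome (generated here, with truth records) or
user-supplied inputs (pre-mRNA FASTA + exon BED, optional external alignment
hits, repeat annotation and pileups). Every output is plain text, declares
its coordinate convention in a header comment, and is reproducible: the run
manifest records inputs, a parameter hash, the seed and a checksum of every
output, and re-running an identical configuration reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import editing as editing_mod
from . import selfalign, stats, synthetic
from .census import (
    MAX_PRE_MRNA_LENGTH,
    Transcript,
    census as compute_census,
    merge_to_regions,
    repeat_overlap_fraction,
    select_structures,
    splice_mrna,
)

logger = logging.getLogger("dsrnacensus")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_transcripts"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunConfig:
    """Declarative configuration for one pipeline run.

    Precedence when built through the CLI: command-line flags > config file >
    defaults; the effective values are logged at startup. With no ``fasta``
    the synthetic generator provides the transcriptome (and pileups for the
    editing stage) from the ``sim_*`` parameters.
    """

    # inputs (all optional; synthetic generation fills the gaps)
    fasta: str | None = None
    exon_bed: str | None = None
    repeat_bed: str | None = None
    pileup: str | None = None
    hits_tsv: str | None = None
    # filters and thresholds
    min_length: int = 40
    min_identity: float = 70.0
    max_gap: int | None = None
    structure_min_length: int = 300
    structure_min_identity: float = 96.0
    fpkm_cutoff: float = 0.01
    # library statistics for FPKM conversion
    total_reads: int = 1_343_000_000
    read_length: int = 76
    trim_bp: int = 5
    # synthetic-run parameters
    sim_n_genes: int = 40
    sim_insertion_rate: float = 1.0
    sim_p_inverted: float = 0.5
    sim_divergence: float = 0.02
    sim_mean_coverage: float = 50.0
    sim_editing_rate: float = 0.05
    # run control
    out_dir: str = "dsrna_out"
    rng_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("fasta", "exon_bed", "repeat_bed", "pileup", "hits_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"[config] missing input file for '{name}': {p}")
        if self.fasta is None and self.exon_bed is not None:
            raise PipelineError("[config] exon_bed given without fasta")

    def hit_filter(self) -> selfalign.HitFilter:
        return selfalign.HitFilter(
            min_length=self.min_length,
            min_identity_pct=self.min_identity,
            max_gap=self.max_gap,
        )

    def library(self) -> editing_mod.LibraryStats:
        return editing_mod.LibraryStats(
            total_mapped_reads=self.total_reads,
            read_length=self.read_length,
            trim_bp=self.trim_bp,
        )


def _read_exon_bed(path) -> dict[str, list[tuple[int, int]]]:
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            exons.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return {k: sorted(v) for k, v in exons.items()}


def _read_repeat_bed(path) -> dict[str, list[tuple[int, int]]]:
    return _read_exon_bed(path)


def load_transcripts(
    fasta_path, exon_bed_path=None, *, max_length: int = MAX_PRE_MRNA_LENGTH
) -> list[Transcript]:
    """Load pre-mRNA transcripts, discarding those longer than ``max_length``.

    Without an exon BED each record is treated as a single-exon (intronless)
    transcript.
    """
    exon_map = _read_exon_bed(exon_bed_path) if exon_bed_path else {}
    out = []
    n_dropped = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) > max_length:
            n_dropped += 1
            continue
        exons = exon_map.get(rec.id, [(0, len(seq))])
        out.append(
            Transcript(
                gene_id=rec.id, chrom=rec.id, strand="+", pre_mrna_sequence=seq, exons=tuple(exons)
            )
        )
    if n_dropped:
        logger.info("dropped %d transcripts longer than %d bp", n_dropped, max_length)
    return out


def _write_regions_bed(regions, path, class_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# merged {class_label} regions, 0-based half-open\n")
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.interval[0]}\t{r.interval[1]}\t{class_label}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scan_molecule(transcripts, hit_filter, molecule: str):
    """Self-align every transcript; returns (ids_hits, tds_hits)."""
    all_hits = []
    for tr in transcripts:
        if molecule == "mRNA":
            seq = splice_mrna(tr)[0]
        else:
            seq = tr.pre_mrna_sequence
        if len(seq) < max(hit_filter.min_length, selfalign.SEED_LENGTH):
            continue
        all_hits.extend(selfalign.self_align(seq, hit_filter, seq_id=tr.gene_id))
    return selfalign.classify_and_gap_filter(all_hits, hit_filter)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to the run dir).

    Any stage failure raises :class:`PipelineError` tagged with the stage
    name; outputs of the failed stage are removed.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hit_filter = config.hit_filter()
    logger.info(
        "filters: length > %d, identity > %.1f%%, max_gap=%s; structures: > %d bp, > %.1f%%",
        hit_filter.min_length,
        hit_filter.min_identity_pct,
        hit_filter.max_gap,
        config.structure_min_length,
        config.structure_min_identity,
    )

    manifest: dict = {
        "inputs": {
            k: getattr(config, k)
            for k in ("fasta", "exon_bed", "repeat_bed", "pileup", "hits_tsv")
        },
        "seed": config.rng_seed,
        "parameter_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                logger.info("stage %s: start", name)
                self._before = set(outputs)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for key in set(outputs) - self._before:
                        outputs[key].unlink(missing_ok=True)
                        del outputs[key]
                    raise PipelineError(f"[{name}] {exc}") from exc
                logger.info("stage %s: done", name)
                return False

        return _Stage()

    planted = None
    with stage("simulate"):
        if config.fasta is None:
            sim = synthetic.SimConfig(
                n_genes=config.sim_n_genes,
                insertion_rate=config.sim_insertion_rate,
                p_inverted=config.sim_p_inverted,
                divergence=config.sim_divergence,
                rng_seed=config.rng_seed,
            )
            transcripts, planted = synthetic.generate_transcriptome(sim)
            outputs["fasta"] = out_dir / "synthetic_pre_mrna.fa"
            synthetic.write_fasta(transcripts, outputs["fasta"])
            outputs["exon_bed"] = out_dir / "synthetic_exons.bed"
            synthetic.write_exon_bed(transcripts, outputs["exon_bed"])
            outputs["truth"] = out_dir / "synthetic_truth.tsv"
            synthetic.write_truth_table(planted, outputs["truth"])
        else:
            transcripts = load_transcripts(config.fasta, config.exon_bed)

    with stage("scan"):
        if config.hits_tsv is not None:
            hits = selfalign.parse_tabular_hits(config.hits_tsv, hit_filter)
            ids_pre, tds_pre = selfalign.classify_and_gap_filter(hits, hit_filter)
        else:
            ids_pre, tds_pre = _scan_molecule(transcripts, hit_filter, "pre-mRNA")
        ids_m, tds_m = _scan_molecule(transcripts, hit_filter, "mRNA")
        outputs["hits_pre_mrna"] = out_dir / "hits_pre_mrna.tsv"
        selfalign.write_tabular_hits(ids_pre + tds_pre, outputs["hits_pre_mrna"])
        outputs["hits_mrna"] = out_dir / "hits_mrna.tsv"
        selfalign.write_tabular_hits(ids_m + tds_m, outputs["hits_mrna"])

    with stage("census"):
        tables = []
        structures = []
        for molecule, (ids_hits, tds_hits) in (
            ("pre-mRNA", (ids_pre, tds_pre)),
            ("mRNA", (ids_m, tds_m)),
        ):
            ids_regions = merge_to_regions(ids_hits, "IDS")
            tds_regions = merge_to_regions(tds_hits, "TDS")
            table = compute_census(
                ids_regions,
                tds_regions,
                ids_hits=ids_hits,
                tds_hits=tds_hits,
                molecule=molecule,
            )
            tables.append(table)
            if molecule == "pre-mRNA":
                structures = select_structures(
                    ids_hits,
                    min_length=config.structure_min_length,
                    min_identity=config.structure_min_identity,
                )
                _write_regions_bed(ids_regions, out_dir / "regions_ids.bed", "IDS")
                _write_regions_bed(tds_regions, out_dir / "regions_tds.bed", "TDS")
                outputs["regions_ids"] = out_dir / "regions_ids.bed"
                outputs["regions_tds"] = out_dir / "regions_tds.bed"
                if config.repeat_bed is not None:
                    rep = repeat_overlap_fraction(
                        ids_regions, _read_repeat_bed(config.repeat_bed)
                    )
                    manifest["repeat_overlap"] = {
                        "overlap_bp": rep.overlap_bp,
                        "total_bp": rep.total_bp,
                        "fraction": rep.fraction,
                    }
        import pandas as pd

        census_df = pd.concat([t.to_frame() for t in tables], ignore_index=True)
        outputs["census"] = out_dir / "census.tsv"
        with open(outputs["census"], "w") as fh:
            fh.write("# nucleotide and hit census per class and bin\n")
            census_df.to_csv(fh, sep="\t", index=False)
        outputs["structures"] = out_dir / "structures.tsv"
        with open(outputs["structures"], "w") as fh:
            fh.write("# long nearly perfect structures, 0-based half-open\n")
            fh.write("seq_id\tarm1_start\tarm1_end\tarm2_start\tarm2_end\torientation\tidentity_pct\taln_length\tgap_bp\n")
            for s in structures:
                fh.write(
                    f"{s.seq_id}\t{s.arm1[0]}\t{s.arm1[1]}\t{s.arm2[0]}\t{s.arm2[1]}\t"
                    f"{s.orientation}\t{s.identity_pct:.3f}\t{s.aln_length}\t{s.gap_bp}\n"
                )

    with stage("stats"):
        report = stats.depletion_report(tables)
        outputs["depletion"] = out_dir / "depletion.tsv"
        with open(outputs["depletion"], "w") as fh:
            fh.write("# IDS-depletion single-proportion tests (one-sided exact)\n")
            report.to_csv(fh, sep="\t", index=False)

    with stage("editing"):
        lib = config.library()
        if config.pileup is not None:
            profiles = editing_mod.read_pileup(config.pileup)
        elif planted is not None and structures:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, 0x9E3779B9])
            )
            seq_by_id = {t.gene_id: t.pre_mrna_sequence for t in transcripts}
            parts: dict[str, list] = {}
            for s in structures:
                seq = seq_by_id[s.seq_id]
                for arm in (s.arm1, s.arm2):
                    parts.setdefault(s.seq_id, []).append(
                        synthetic.simulate_pileup(
                            arm,
                            seq,
                            config.sim_mean_coverage,
                            config.sim_editing_rate,
                            rng,
                            contig=s.seq_id,
                        )
                    )
            profiles = {}
            for seq_id, profs in parts.items():
                pos = np.concatenate([p.positions for p in profs])
                a = np.concatenate([p.a_counts for p in profs])
                g = np.concatenate([p.g_counts for p in profs])
                order = np.argsort(pos)
                profiles[seq_id] = editing_mod.EditingProfile(
                    seq_id, pos[order], a[order], g[order]
                )
            outputs["pileup"] = out_dir / "synthetic_pileup.tsv"
            editing_mod.write_pileup(profiles.values(), outputs["pileup"])
        else:
            profiles = {}
        summaries = []
        for s in structures:
            if s.seq_id in profiles:
                summaries.append(editing_mod.summarize_structure(s, profiles[s.seq_id], lib))
        expressed = editing_mod.expression_filter(summaries, config.fpkm_cutoff)
        manifest["n_structures"] = len(structures)
        manifest["n_structures_expressed"] = len(expressed)
        outputs["editing"] = out_dir / "editing_summary.tsv"
        with open(outputs["editing"], "w") as fh:
            fh.write("# per-structure expression and editing, 0-based half-open\n")
            editing_mod.summaries_to_frame(summaries).to_csv(fh, sep="\t", index=False)

    for key, path in outputs.items():
        manifest["outputs"][key] = {"path": str(path), "sha256": _sha256(path)}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %d outputs, manifest at %s", len(outputs), manifest_path)
    return manifest
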