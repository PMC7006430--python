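"""Splicing, interval merge/attribution, binning, structures, repeats."""

import numpy as np
import pytest

from dsrnacensus import (
    AlignmentHit,
    HitFilter,
    SimConfig,
    Transcript,
    census,
    classify_and_gap_filter,
    generate_transcriptome,
    merge_intervals,
    merge_to_regions,
    repeat_overlap_fraction,
    select_structures,
    self_align,
    splice_mrna,
)
from dsrnacensus.synthetic import BOTH_EXONIC, random_sequence

from _oracles import brute_force_union


def _hit(q, s, strand="opposite", ident=95.0, length=None, seq_id="x"):
    return AlignmentHit(seq_id, q, s, strand, ident, length or (q[1] - q[0]))


class TestSplicing:
    def test_two_exon_concatenation_and_map(self, rng):
        seq = random_sequence(400, rng)
        tr = Transcript("g", "g", "+", seq, ((0, 100), (200, 300)))
        mrna, cmap = splice_mrna(tr)
        assert len(mrna) == 200
        assert mrna == seq[:100] + seq[200:300]
        assert cmap.pre_to_mrna(200) == 100
        assert cmap.mrna_to_pre(100) == 200
        with pytest.raises(KeyError):
            cmap.pre_to_mrna(150)  # intronic

    def test_single_exon_identity(self, rng):
        seq = random_sequence(300, rng)
        tr = Transcript("g", "g", "+", seq, ((0, 300),))
        mrna, cmap = splice_mrna(tr)
        assert mrna == seq
        assert all(cmap.pre_to_mrna(i) == i for i in range(0, 300, 37))

    def test_empty_exon_list_rejected(self, rng):
        tr = Transcript("g", "g", "+", random_sequence(100, rng), ())
        with pytest.raises(ValueError, match="no exons"):
            splice_mrna(tr)

    def test_intronic_arm_lost_on_splicing(self):
        """A duplex with an intronic arm is seen in pre-mRNA, not mRNA."""
        cfg = SimConfig(
            n_genes=8, insertions_per_gene=1, divergence=0.0, rng_seed=23,
            repeat_length=(80, 200),
        )
        transcripts, planted = generate_transcriptome(cfg)
        by_gene = {t.gene_id: t for t in transcripts}
        intronic = [p for p in planted if p.compartment != BOTH_EXONIC]
        assert intronic, "cohort must contain intron-compartment duplexes"
        for p in intronic:
            tr = by_gene[p.gene]
            pre_hits = self_align(tr.pre_mrna_sequence, seq_id=p.gene)
            assert any(h.strand_relation in ("same", "opposite") for h in pre_hits)
            mrna, _ = splice_mrna(tr)
            assert self_align(mrna, seq_id=p.gene) == []


class TestMerge:
    def test_overlapping_arms_merge(self):
        regions = merge_to_regions([_hit((100, 200), (150, 250))], "IDS")
        assert len(regions) == 1
        assert regions[0].interval == (100, 250)
        assert regions[0].n_bases == 150

    def test_book_ended_intervals_merge(self):
        assert merge_intervals([(100, 200), (200, 300)]) == [(100, 300)]

    def test_merge_matches_per_base_oracle(self, rng):
        """Merged footprint equals the brute-force per-base union."""
        for _ in range(25):
            ivs = []
            for _ in range(rng.integers(1, 8)):
                s = int(rng.integers(0, 500))
                ivs.append((s, s + int(rng.integers(1, 120))))
            merged = merge_intervals(ivs)
            covered = brute_force_union(ivs)
            assert sum(e - s for s, e in merged) == len(covered)
            for s, e in merged:
                assert set(range(s, e)) <= covered
            # disjoint and non-adjacent after merging
            for (s1, e1), (s2, _) in zip(merged, merged[1:]):
                assert e1 < s2

    def test_attribution_prefers_longer_hit(self):
        short = _hit((100, 160), (400, 460), ident=98.0)
        long_ = _hit((140, 440), (600, 900), ident=85.0)
        regions = merge_to_regions([short, long_], "IDS")
        by_base = {}
        for r in regions:
            for off in range(r.n_bases):
                by_base[r.interval[0] + off] = (
                    int(r.attr_length[off]),
                    float(r.attr_identity[off]),
                )
        assert by_base[150] == (300, 85.0)  # covered by both, longer wins
        assert by_base[120] == (60, 98.0)  # only the short hit covers it

    def test_attribution_tie_breaks_on_identity(self):
        a = _hit((100, 200), (400, 500), ident=90.0)
        b = _hit((150, 250), (600, 700), ident=99.0)
        regions = merge_to_regions([a, b], "IDS")
        by_base = {}
        for r in regions:
            for off in range(r.n_bases):
                by_base[r.interval[0] + off] = float(r.attr_identity[off])
        assert by_base[175] == 99.0

    def test_conservation_against_arm_union(self, small_cohort):
        """Per class, merged nucleotide total equals the union of arm intervals."""
        _, transcripts, _ = small_cohort
        all_hits = []
        for tr in transcripts:
            all_hits.extend(self_align(tr.pre_mrna_sequence, seq_id=tr.gene_id))
        ids_hits, tds_hits = classify_and_gap_filter(all_hits, HitFilter())
        for cls, hits in (("IDS", ids_hits), ("TDS", tds_hits)):
            regions = merge_to_regions(hits, cls)
            total = sum(r.n_bases for r in regions)
            oracle = 0
            for sid in {h.seq_id for h in hits}:
                arms = [h.q_interval for h in hits if h.seq_id == sid]
                arms += [h.s_interval for h in hits if h.seq_id == sid]
                oracle += len(brute_force_union(arms))
            assert total == oracle


class TestCensus:
    def test_single_hit_falls_in_top_cell(self):
        h = _hit((0, 350), (500, 850), ident=97.0, length=350)
        table = census(merge_to_regions([h], "IDS"), [], ids_hits=[h])
        nt = table.nt["IDS"]
        assert nt[2, 4] == 700  # (>300 bp, >96%) cell holds all nucleotides
        assert nt.sum() == 700
        assert table.hits["IDS"][2, 4] == 1

    def test_empty_inputs_zero_table(self):
        table = census([], [])
        assert table.nt["IDS"].sum() == 0
        assert table.nt["TDS"].sum() == 0

    def test_bin_sums_equal_totals(self, small_cohort):
        _, transcripts, _ = small_cohort
        all_hits = []
        for tr in transcripts:
            all_hits.extend(self_align(tr.pre_mrna_sequence, seq_id=tr.gene_id))
        ids_hits, tds_hits = classify_and_gap_filter(all_hits, HitFilter())
        ids_regions = merge_to_regions(ids_hits, "IDS")
        tds_regions = merge_to_regions(tds_hits, "TDS")
        table = census(ids_regions, tds_regions, ids_hits=ids_hits, tds_hits=tds_hits)
        assert table.nt_total("IDS") == sum(r.n_bases for r in ids_regions)
        assert table.nt_total("TDS") == sum(r.n_bases for r in tds_regions)
        assert table.hit_total("IDS") == len(ids_hits)
        assert table.hit_total("TDS") == len(tds_hits)

    def test_balanced_exact_planting_gives_equal_totals(self):
        """Equal-sized planted IDS and TDS cohorts produce equal footprints."""
        arms = [((i * 1000, i * 1000 + 120), (i * 1000 + 400, i * 1000 + 520)) for i in range(100)]
        ids_hits = [_hit(a, b, "opposite", ident=100.0, seq_id=f"g{i}") for i, (a, b) in enumerate(arms)]
        tds_hits = [_hit(a, b, "same", ident=100.0, seq_id=f"g{i}") for i, (a, b) in enumerate(arms)]
        table = census(
            merge_to_regions(ids_hits, "IDS"),
            merge_to_regions(tds_hits, "TDS"),
            ids_hits=ids_hits,
            tds_hits=tds_hits,
        )
        assert table.nt_total("IDS") == table.nt_total("TDS") == 100 * 240

    def test_tightening_filter_never_increases_cells(self, small_cohort):
        _, transcripts, _ = small_cohort
        all_hits = []
        for tr in transcripts:
            all_hits.extend(self_align(tr.pre_mrna_sequence, seq_id=tr.gene_id))

        def table_for(filt):
            kept = [h for h in all_hits if filt.passes(h)]
            ids_hits, tds_hits = classify_and_gap_filter(kept, filt)
            return census(
                merge_to_regions(ids_hits, "IDS"),
                merge_to_regions(tds_hits, "TDS"),
                ids_hits=ids_hits,
                tds_hits=tds_hits,
            )

        loose = table_for(HitFilter(min_length=40, min_identity_pct=70.0))
        tight = table_for(HitFilter(min_length=100, min_identity_pct=90.0))
        for cls in ("IDS", "TDS"):
            assert np.all(tight.nt[cls] <= loose.nt[cls])
            assert np.all(tight.hits[cls] <= loose.hits[cls])

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            census([], [], length_bins=[(50, 100), (100, float("inf"))])
        with pytest.raises(ValueError, match="contiguous"):
            census([], [], identity_bins=[(0, 70), (80, 100)])


class TestStructures:
    def test_boundary_length_excluded(self):
        h = _hit((0, 300), (400, 700), ident=99.0, length=300)
        assert select_structures([h]) == []
        h2 = _hit((0, 301), (400, 701), ident=99.0, length=301)
        assert len(select_structures([h2])) == 1

    def test_boundary_identity_excluded(self):
        base = dict(q=(0, 400), s=(500, 900))
        assert select_structures([_hit(base["q"], base["s"], ident=96.0, length=400)]) == []
        kept = select_structures([_hit(base["q"], base["s"], ident=96.1, length=400)])
        assert len(kept) == 1

    def test_overlapping_candidates_keep_highest_identity(self):
        lo = _hit((0, 400), (500, 900), ident=97.0, length=400)
        hi = _hit((100, 500), (600, 1000), ident=99.0, length=400)
        kept = select_structures([lo, hi])
        assert len(kept) == 1
        assert kept[0].identity_pct == 99.0

    def test_disjoint_structures_all_kept(self):
        a = _hit((0, 400), (500, 900), ident=97.0, length=400, seq_id="g1")
        b = _hit((0, 400), (500, 900), ident=98.0, length=400, seq_id="g2")
        assert len(select_structures([a, b])) == 2


class TestRepeatOverlap:
    def _regions(self, *hits):
        return merge_to_regions(list(hits), "IDS")

    def test_partial_overlap_counts(self):
        regions = self._regions(_hit((0, 60), (450, 510), seq_id="g"))
        res = repeat_overlap_fraction(regions, {"g": [(50, 150)]})
        assert (res.overlap_bp, res.total_bp) == (10, 120)

    def test_empty_annotation_flagged(self):
        regions = self._regions(_hit((0, 60), (450, 510), seq_id="g"))
        res = repeat_overlap_fraction(regions, {})
        assert res.available and res.overlap_bp == 0
        assert "no repeats" in res.note

    def test_missing_annotation_not_available(self):
        regions = self._regions(_hit((0, 60), (450, 510), seq_id="g"))
        res = repeat_overlap_fraction(regions, None)
        assert not res.available
        assert res.fraction is None
        assert res.note == "not available"

    def test_truth_bed_gives_full_overlap(self, small_cohort):
        """With the planted arms as annotation, planted footprint overlap is 1."""
        _, transcripts, planted = small_cohort
        all_hits = []
        for tr in transcripts:
            all_hits.extend(self_align(tr.pre_mrna_sequence, seq_id=tr.gene_id))
        # keep hits matching planted arms only, widen annotation by arm spans
        annotation: dict[str, list] = {}
        for p in planted:
            annotation.setdefault(p.gene, []).extend([p.arm1, p.arm2])
        matched = [
            h
            for h in all_hits
            if any(
                p.gene == h.seq_id
                and h.q_interval[0] >= p.arm1[0] - 2
                and h.s_interval[1] <= p.arm2[1] + 2
                for p in planted
            )
        ]
        regions = merge_to_regions(matched, "IDS")
        res = repeat_overlap_fraction(regions, annotation)
        assert res.total_bp > 0
        assert res.overlap_bp / res.total_bp > 0.98
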