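"""Filter cascade stages, recall evaluation and candidate ranking."""

import numpy as np
import pytest

from conftest import oracle_any_overlap, oracle_union_covered_fraction
from teloscan.candidate_pipeline import (
    AnnotationSet,
    CoverageTrack,
    ExternalScores,
    GenomicInterval,
    PolyAThresholds,
    TranscriptRecord,
    annotate_structure_and_haca,
    coding_filter,
    compute_recall,
    coverage_stats,
    dedup_cds,
    length_filter,
    min_coverage_filter,
    overlap_filter,
    polyA_classify,
    redundancy_filter,
    scan_and_flag_templates,
    score_candidates,
)
from teloscan.datasets import CELEGANS_TR_CANDIDATES, celegans_candidate_records
from teloscan.seqcore import NucleotideSequence, TemplateScanParams


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


def tx(tid, chrom, start, end, strand=".", cov=None):
    rec = TranscriptRecord(interval=iv(chrom, start, end, strand), id=tid)
    if cov is not None:
        rec.coverage_total = cov * rec.length
    return rec


def random_intervals(rng, n, chrom="c", span=1000, max_len=60):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span - 1))
        e = s + int(rng.integers(1, max_len))
        out.append(iv(chrom, s, e))
    return out


class TestDedupCds:
    def test_identical_records_collapse(self):
        a = iv("c", 0, 10, "+")
        assert dedup_cds([a, a]) == [a]

    def test_disjoint_unchanged(self):
        items = [iv("c", 0, 10), iv("c", 20, 30)]
        assert dedup_cds(items) == items

    def test_planted_duplicates_count(self):
        rng = np.random.default_rng(0)
        unique = random_intervals(rng, 300)
        unique = sorted(set(unique))
        dup = unique + [unique[i] for i in rng.integers(0, len(unique), 100)]
        assert dedup_cds(dup) == unique


class TestOverlapFilter:
    def test_one_bp_overlap_removed(self):
        anno = AnnotationSet(cds=[iv("c", 100, 200)])
        items = [tx("t", "c", 199, 300)]
        assert overlap_filter(items, anno) == []

    def test_annotation_free_region_retained(self):
        anno = AnnotationSet(cds=[iv("c", 100, 200)], ncrna=[(iv("c", 500, 600), "tRNA")])
        items = [tx("t", "c", 300, 400)]
        assert overlap_filter(items, anno) == items

    def test_ncrna_overlap_also_removes(self):
        anno = AnnotationSet(ncrna=[(iv("c", 500, 600), "snoRNA")])
        assert overlap_filter([tx("t", "c", 590, 700)], anno) == []

    def test_strand_agnostic_by_default(self):
        anno = AnnotationSet(cds=[iv("c", 100, 200, "+")])
        assert overlap_filter([tx("t", "c", 150, 250, "-")], anno) == []
        assert overlap_filter([tx("t", "c", 150, 250, "-")], anno, stranded=True) == [
            tx("t", "c", 150, 250, "-")
        ]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(13)
        anno_ivs = random_intervals(rng, 150)
        anno = AnnotationSet(cds=anno_ivs[:100], ncrna=[(x, "other") for x in anno_ivs[100:]])
        items = [tx(f"t{i}", "c", x.start, x.end) for i, x in enumerate(random_intervals(rng, 200))]
        got = {t.id for t in overlap_filter(items, anno)}
        expect = {t.id for t in items if not oracle_any_overlap(t.interval, anno_ivs)}
        assert got == expect


class TestCoverage:
    def test_uniform_track(self):
        track = CoverageTrack({"c": np.full(200, 2.0)})
        assert coverage_stats(iv("c", 50, 150), track) == (200.0, 2.0, 2.0)

    def test_zero_track(self):
        track = CoverageTrack({"c": np.zeros(100)})
        assert coverage_stats(iv("c", 0, 100), track) == (0.0, 0.0, 0.0)

    def test_missing_chromosome(self):
        track = CoverageTrack({"c": np.zeros(100)})
        with pytest.raises(KeyError):
            coverage_stats(iv("other", 0, 10), track)

    def test_random_track_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        depths = rng.integers(0, 50, size=500).astype(float)
        track = CoverageTrack({"c": depths})
        for _ in range(50):
            s = int(rng.integers(0, 499))
            e = s + int(rng.integers(1, 500 - s))
            window = [depths[i] for i in range(s, e)]
            st = coverage_stats(iv("c", s, e), track)
            assert st.sum == sum(window)
            assert st.mean == pytest.approx(sum(window) / len(window))
            assert st.min == min(window)

    @pytest.mark.parametrize(
        "mean,survives", [(9.9, False), (10.0, True), (25.0, True)]
    )
    def test_min_coverage_boundary(self, mean, survives):
        items = [tx("t", "c", 0, 100, cov=mean)]
        assert (min_coverage_filter(items) == items) is survives

    def test_zero_threshold_is_identity(self):
        items = [tx("t", "c", 0, 100, cov=0.0)]
        assert min_coverage_filter(items, threshold=0.0) == items


class TestRedundancy:
    def test_nested_pair(self):
        outer, inner = tx("a", "c", 0, 100, "+"), tx("b", "c", 10, 50, "+")
        assert redundancy_filter([inner, outer]) == [outer]

    def test_identical_pair_keeps_smallest_id(self):
        a, b = tx("a", "c", 0, 100, "+"), tx("b", "c", 0, 100, "+")
        assert redundancy_filter([b, a]) == [a]

    def test_containment_is_strand_specific(self):
        outer, inner = tx("a", "c", 0, 100, "+"), tx("b", "c", 10, 50, "-")
        assert set(t.id for t in redundancy_filter([outer, inner])) == {"a", "b"}

    def test_disjoint_unchanged(self):
        items = [tx("a", "c", 0, 10, "+"), tx("b", "c", 20, 30, "+")]
        assert redundancy_filter(items) == items

    def test_matches_quadratic_containment_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            items = [
                tx(f"t{i:03d}", "c", x.start, x.end, "+")
                for i, x in enumerate(random_intervals(rng, 60, span=300, max_len=80))
            ]
            got = {t.id for t in redundancy_filter(items)}
            # oracle: iteratively remove anything contained in a kept item,
            # processing largest-first (ties by id)
            order = sorted(items, key=lambda t: (t.interval.start, -t.interval.end, t.id))
            kept = []
            for t in order:
                contained = any(
                    k.interval.contains(t.interval) for k in kept
                )
                if not contained:
                    kept.append(t)
            assert got == {t.id for t in kept}


class TestCodingFilter:
    def test_either_tool_removes(self):
        scores = ExternalScores(coding_scores={"t": (0.9, 0.1)})
        assert coding_filter([tx("t", "c", 0, 10)], scores) == []

    def test_boundary_is_noncoding(self):
        scores = ExternalScores(coding_scores={"t": (0.5, 0.5)})
        items = [tx("t", "c", 0, 10)]
        assert coding_filter(items, scores) == items

    def test_zero_scores_retained(self):
        scores = ExternalScores(coding_scores={"t": (0.0, 0.0)})
        items = [tx("t", "c", 0, 10)]
        assert coding_filter(items, scores) == items

    def test_unscored_retained_with_flag(self):
        items = [tx("t", "c", 0, 10)]
        out = coding_filter(items, ExternalScores())
        assert out == items and "unscored_coding" in out[0].flags


class TestLengthFilter:
    @pytest.mark.parametrize("length,survives", [(1000, True), (1001, False)])
    def test_boundary(self, length, survives):
        items = [tx("t", "c", 0, length)]
        assert (length_filter(items) == items) is survives

    def test_published_candidate_lengths_all_pass(self):
        items = [tx(r["id"], "c", 0, r["length"]) for r in CELEGANS_TR_CANDIDATES]
        assert length_filter(items) == items

    def test_empty_input(self):
        assert length_filter([]) == []


class TestTemplateStage:
    params = TemplateScanParams()

    def test_single_template_retained_unflagged(self):
        seqs = {"t": NucleotideSequence("t", "G" * 30 + "TAAGCCTAAG" + "G" * 30)}
        (out,) = scan_and_flag_templates([tx("t", "c", 0, 70)], self.params, seqs)
        assert "multi_template" not in out.flags
        assert len(out.valid_template_sites) == 1

    def test_two_sites_flagged_multi(self):
        seqs = {
            "t": NucleotideSequence(
                "t", "G" * 10 + "TAAGCCTAAG" + "G" * 20 + "CCTAAGCC" + "G" * 10
            )
        }
        (out,) = scan_and_flag_templates([tx("t", "c", 0, 58)], self.params, seqs)
        assert "multi_template" in out.flags

    def test_template_free_removed(self):
        seqs = {"t": NucleotideSequence("t", "G" * 50)}
        assert scan_and_flag_templates([tx("t", "c", 0, 50)], self.params, seqs) == []

    def test_missing_sequence_names_id(self):
        with pytest.raises(KeyError, match="t1"):
            scan_and_flag_templates([tx("t1", "c", 0, 50)], self.params, {})


class TestPolyAClassify:
    @pytest.mark.parametrize(
        "total,polya,expected",
        [
            (100, 0, "absent"),
            (100, 100, "similar"),
            (100, 50, "half"),
            (100, 9.99, "absent"),
            (100, 70, "similar"),
            (100, 151, "abundant"),
        ],
    )
    def test_bins(self, total, polya, expected):
        assert polyA_classify(total, polya) == expected

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError):
            polyA_classify(10, -1)

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            PolyAThresholds(absent_below=0.9, half_below=0.5)


class TestStructureHaca:
    def test_furthest_3p_hit_selected(self):
        item = tx("t", "c", 0, 327)
        scores = ExternalScores(haca_predictions={"t": [(100, 106, 0.9), (250, 256, 0.6)]})
        annotate_structure_and_haca([item], scores)
        assert item.haca == (250, 256, 0.6)

    def test_no_hits(self):
        item = tx("t", "c", 0, 100)
        annotate_structure_and_haca([item], ExternalScores())
        assert not item.has_haca

    def test_one_bp_structure_overlap_counts(self):
        item = tx("t", "c", 100, 200)
        scores = ExternalScores(structure_loci=[iv("c", 199, 250)])
        annotate_structure_and_haca([item], scores)
        assert item.has_structure_locus


class TestScoring:
    def test_published_features_rank_confirmed_tr_first(self):
        report = score_candidates(celegans_candidate_records())
        table = report.table
        assert report.top_candidate == "TR_C2"
        assert table.loc["TR_C2", "Score"] == 6
        # unique top: everything else scores strictly lower
        assert (table.drop("TR_C2")["Score"] < 6).all()
        for crit in (
            "single_template",
            "template_near_5p",
            "length_in_range",
            "polyA_absent",
            "structure_locus",
            "haca",
        ):
            assert bool(table.loc["TR_C2", crit])

    def test_rendered_coordinates_match_printed_table(self):
        table = score_candidates(celegans_candidate_records()).table
        for row in CELEGANS_TR_CANDIDATES:
            assert table.loc[row["id"], "Start"] == row["start"]
            assert table.loc[row["id"], "End"] == row["end"]
            assert table.loc[row["id"], "Length"] == row["length"]
            assert table.loc[row["id"], "Motif"] == row["motif"]
            assert table.loc[row["id"], "Pos"] == row["pos"]

    def test_input_order_does_not_change_ranks(self):
        records = celegans_candidate_records()
        base = score_candidates(records).table["Rank"]
        rng = np.random.default_rng(4)
        for _ in range(5):
            perm = list(rng.permutation(len(records)))
            shuffled = [records[i] for i in perm]
            assert score_candidates(shuffled).table["Rank"].equals(base)

    def test_candidate_with_no_soft_evidence_scores_minimum(self):
        rec = tx("t", "c", 0, 1000)
        rec.template_sites = [
            s
            for s in scan_and_flag_templates(
                [rec],
                TemplateScanParams(),
                {"t": NucleotideSequence("t", "G" * 500 + "TAAGCCTAAG" + "G" * 490)},
            )[0].template_sites
        ]
        rec.polyA_class = "similar"
        table = score_candidates([rec]).table
        # only the single-template criterion holds
        assert table.loc["t", "Score"] == 1


class TestRecall:
    def test_perfect_predictions(self):
        genes = [(iv("c", 0, 100), "tRNA"), (iv("c", 200, 260), "miRNA")]
        preds = [g for g, _ in genes]
        table = compute_recall(genes, preds, 0.9)
        assert (table["recall_pct"] == 100.0).all()

    def test_half_coverage_boundary(self):
        genes = [(iv("c", 0, 100), "tRNA")]
        preds = [iv("c", 0, 50)]
        assert compute_recall(genes, preds, 0.9).loc["Total", "n_recalled"] == 0
        assert compute_recall(genes, preds, 0.5).loc["Total", "n_recalled"] == 1

    def test_union_semantics_of_abutting_predictions(self):
        genes = [(iv("c", 0, 100), "tRNA")]
        both = [iv("c", 0, 50), iv("c", 50, 100)]
        assert compute_recall(genes, both, 0.9).loc["Total", "n_recalled"] == 1
        # overlapping halves must not double-count
        overlapping = [iv("c", 0, 50), iv("c", 10, 60)]
        assert compute_recall(genes, overlapping, 0.9).loc["Total", "n_recalled"] == 0

    def test_matches_union_coverage_oracle(self):
        rng = np.random.default_rng(31)
        families = ["tRNA", "miRNA", "snoRNA"]
        for _ in range(30):
            genes = [
                (x, families[int(rng.integers(3))]) for x in random_intervals(rng, 40)
            ]
            preds = random_intervals(rng, 60)
            min_frac = float(rng.choice([0.5, 0.9]))
            table = compute_recall(genes, preds, min_frac)
            expect_total = sum(
                oracle_union_covered_fraction(g, preds) >= min_frac for g, _ in genes
            )
            assert table.loc["Total", "n_recalled"] == expect_total
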