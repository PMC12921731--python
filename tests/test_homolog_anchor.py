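"""Intron extraction, per-intron template scan, TR windows, consensus
motifs and the presence/absence feature matrix."""

import numpy as np
import pytest

from teloscan.homolog_anchor import (
    GeneModel,
    IntronRecord,
    TRWindow,
    annotate_intron_haca,
    build_feature_matrix,
    consensus_motif,
    extract_intron,
    extract_tr_window,
    intron_template_scan,
    select_orthologous_intron,
)
from teloscan.seqcore import (
    NucleotideSequence,
    TemplateScanParams,
    reverse_complement,
)


def model(exons, strand="+", species="sp", chrom="c"):
    return GeneModel(species=species, gene_id="g", chrom=chrom, strand=strand, exons=tuple(exons))


def make_genome(seq, chrom="c"):
    return {chrom: NucleotideSequence(chrom, seq)}


class TestExtractIntron:
    def test_plus_strand_arithmetic(self):
        rec = extract_intron(model([(100, 200), (260, 300)]), 0)
        assert (rec.start, rec.end, rec.length) == (200, 260, 60)

    def test_abutting_exons_mark_intron_absent(self):
        rec = extract_intron(model([(100, 200), (200, 300)]), 0)
        assert not rec.present and rec.length == 0

    def test_out_of_range_ordinal(self):
        with pytest.raises(IndexError):
            extract_intron(model([(0, 10), (20, 30)]), 1)

    def test_minus_strand_mirrors_plus(self):
        # mirror exon layout around position 1000
        plus = model([(100, 200), (260, 300), (350, 400)], "+")
        minus = model(
            [(1000 - e, 1000 - s) for s, e in reversed(plus.exons)], "-"
        )
        for ordinal in (0, 1):
            p = extract_intron(plus, ordinal)
            m = extract_intron(minus, ordinal)
            assert (m.start, m.end) == (1000 - p.end, 1000 - p.start)
            assert m.length == p.length

    def test_ordinal_follows_transcription_order_on_minus(self):
        m = model([(0, 10), (50, 60), (100, 110)], "-")
        first = extract_intron(m, 0)  # between the two rightmost exons
        assert (first.start, first.end) == (60, 100)


class TestSelectOrthologousIntron:
    def test_matches_flank_lengths(self):
        m = model([(0, 100), (150, 170), (200, 400), (430, 460)])
        # reference flanks: 20 nt upstream exon, 200 nt downstream exon
        assert select_orthologous_intron(m, (20, 200)) == 1

    def test_intronless_gene_rejected(self):
        with pytest.raises(ValueError):
            select_orthologous_intron(model([(0, 100)]), (10, 10))


class TestIntronTemplateScan:
    params = TemplateScanParams()

    def test_short_intron_reports_no_template(self):
        seq = "G" * 100 + "T" * 52 + "G" * 100
        m = model([(50, 100), (152, 200)])
        rec = intron_template_scan(extract_intron(m, 0), make_genome(seq))
        assert rec.template_site is None

    def test_planted_offset_recovered_exactly(self):
        intron = "G" * 85 + "TAAGCCTAAG" + "G" * 335
        seq = "A" * 50 + intron + "A" * 50
        m = model([(0, 50), (50 + len(intron), 80 + len(intron))])
        rec = intron_template_scan(extract_intron(m, 0), make_genome(seq))
        assert rec.offset5 == 85
        assert rec.template_site.motif == "TAAGCCTAAG"

    def test_offset_identity(self, bundle):
        for sp in sorted(bundle.gene_models):
            rec = extract_intron(bundle.gene_models[sp], 1)
            if not rec.present:
                continue
            rec = intron_template_scan(rec, bundle.genomes[sp])
            if rec.template_site is not None:
                assert rec.offset5 + len(rec.template_site.motif) + rec.offset3 == rec.length

    def test_longest_then_five_prime_most_site_selected(self):
        intron = (
            "G" * 20 + "CTAAGCCT" + "G" * 20 + "TAAGCCTAAG" + "G" * 20 + "CCTAAGCC" + "G" * 20
        )
        m = model([(0, 10), (10 + len(intron), 30 + len(intron))])
        rec = intron_template_scan(extract_intron(m, 0), make_genome("A" * 10 + intron + "A" * 20))
        assert rec.template_site.motif == "TAAGCCTAAG"  # longest wins

    def test_strand_symmetry_of_planted_template(self):
        intron = "G" * 40 + "TAAGCCTAAG" + "C" * 60
        plus_seq = "A" * 30 + intron + "A" * 30
        minus_seq = reverse_complement(plus_seq)
        n = len(plus_seq)
        plus_model = model([(0, 30), (30 + len(intron), n)], "+")
        minus_model = model([(0, 30), (30 + len(intron), n)], "-")
        plus_rec = intron_template_scan(extract_intron(plus_model, 0), make_genome(plus_seq))
        minus_rec = intron_template_scan(extract_intron(minus_model, 0), make_genome(minus_seq))
        assert plus_rec.template_site.motif == minus_rec.template_site.motif
        assert plus_rec.offset5 == minus_rec.offset5
        assert plus_rec.offset3 == minus_rec.offset3


class TestTRWindow:
    def intron_with_template(self, pad5=100, pad3=400):
        intron = "G" * pad5 + "TAAGCCTAAG" + "G" * pad3
        genome = make_genome("A" * 50 + intron + "A" * 50)
        m = model([(0, 50), (50 + len(intron), 100 + len(intron))])
        return intron_template_scan(extract_intron(m, 0), genome), genome

    def test_unclipped_window_length(self):
        rec, genome = self.intron_with_template()
        w = extract_tr_window(rec, genome)
        assert w.sequence.length == 70 + 10 + 350
        assert not (w.truncated_5p or w.truncated_3p)
        assert w.template_offset == 70

    def test_upstream_clipping_sets_flag(self):
        rec, genome = self.intron_with_template(pad5=30)
        w = extract_tr_window(rec, genome)
        assert w.truncated_5p and w.template_offset == 30

    def test_window_contains_motif_at_offset(self):
        rec, genome = self.intron_with_template(pad5=30, pad3=100)
        w = extract_tr_window(rec, genome)
        assert (
            w.sequence.residues[w.template_offset : w.template_offset + 10]
            == "TAAGCCTAAG"
        )

    def test_premrna_extension_mode(self):
        rec, genome = self.intron_with_template(pad5=30)
        w = extract_tr_window(rec, genome, clip_to_intron=False)
        assert not w.truncated_5p and w.template_offset == 70
        # the extra 40 nt come from the upstream exon ('A' fill)
        assert w.sequence.residues.startswith("A" * 40)

    def test_template_free_intron_rejected(self):
        m = model([(0, 10), (100, 120)])
        rec = extract_intron(m, 0)
        with pytest.raises(ValueError):
            extract_tr_window(rec, make_genome("G" * 200))


class TestConsensusMotif:
    def oracle(self, motifs, allowed_exceptions):
        """Brute-force phase alignment: lay every motif on every rotation
        explicitly and score the stack by summed squared support."""
        repeat = reverse_complement("TTAGGC")
        best = None
        for rot in range(6):
            rotation = repeat[rot:] + repeat[:rot]
            lanes = {}
            for sp, m in motifs.items():
                # place at the smallest offset where the rotation repeats match
                for off in range(6):
                    if (rotation * 6)[off : off + len(m)] == m:
                        lanes[sp] = off
                        break
            cols = {}
            for sp, off in lanes.items():
                for c in range(off, off + len(motifs[sp])):
                    cols[c] = cols.get(c, 0) + 1
            obj = sum(v * v for v in cols.values())
            if best is None or obj > best[0]:
                best = (obj, rotation, lanes, cols)
        _, rotation, lanes, cols = best
        n = len(motifs)

        def longest_run(selected):
            runs, cur = [], []
            for c in sorted(selected):
                if cur and c != cur[-1] + 1:
                    runs.append(cur)
                    cur = []
                cur.append(c)
            if cur:
                runs.append(cur)
            return max(runs, key=len) if runs else []

        cons = longest_run([c for c, v in cols.items() if v > n / 2])
        core = longest_run([c for c, v in cols.items() if v >= n - allowed_exceptions])
        return (
            "".join(rotation[c % 6] for c in cons),
            "".join(rotation[c % 6] for c in core),
        )

    def test_specified_example_matches_oracle(self):
        motifs = {"a": "CTAAGCCT", "b": "CCTAAGCC", "c": "TAAGCCTAAG"}
        got = consensus_motif(motifs, allowed_exceptions=0)
        expect_cons, expect_core = self.oracle(motifs, 0)
        assert got.consensus == expect_cons == "CTAAGCCT"
        assert got.core == expect_core == "TAAGCC"

    def test_identical_motifs(self):
        got = consensus_motif({"a": "TAAGCCTAAG", "b": "TAAGCCTAAG"}, allowed_exceptions=0)
        assert got.consensus == "TAAGCCTAAG"
        assert got.core == "TAAGCCTAAG"
        assert all(v == 2 for v in got.support.values())

    def test_random_motif_sets_match_oracle(self):
        rng = np.random.default_rng(8)
        repeat = reverse_complement("TTAGGC")
        for _ in range(30):
            motifs = {}
            for i in range(int(rng.integers(2, 8))):
                length = int(rng.integers(8, 16))
                phase = int(rng.integers(0, 6))
                motifs[f"s{i}"] = (repeat * 5)[phase : phase + length]
            got = consensus_motif(motifs, allowed_exceptions=0)
            expect_cons, expect_core = self.oracle(motifs, 0)
            assert got.consensus == expect_cons
            assert got.core == expect_core

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            consensus_motif({"a": "TAAGCCTAAG"})

    def test_non_member_motif_rejected(self):
        with pytest.raises(ValueError):
            consensus_motif({"a": "TAAGCCTAAG", "b": "TAAGGCTAAG"})

    def test_scenario_consensus_contains_shared_core(self, bundle):
        from teloscan.homolog_anchor import extract_intron, intron_template_scan

        motifs = {}
        for sp in sorted(bundle.gene_models):
            rec = extract_intron(bundle.gene_models[sp], 1)
            if rec.present:
                rec = intron_template_scan(rec, bundle.genomes[sp])
                if rec.template_site is not None:
                    motifs[sp] = rec.template_site.motif
        got = consensus_motif(motifs)
        assert "TAAGCC" in got.consensus or got.consensus in "TAAGCCTAAGCCTAAG"
        assert got.core  # non-empty near-universal core


class TestFeatureMatrix:
    def test_absent_intron_row(self):
        recs = [
            IntronRecord("a", 1, "c", "+", 0, 0),
            IntronRecord("b", 1, "c", "+", 10, 110),
        ]
        m = build_feature_matrix(recs)
        assert not m.loc["a", "intron_present"]
        assert m.loc["a", "intron_length"] is not None  # pd.NA
        assert m.loc["b", "intron_length"] == 100

    def test_duplicate_species_rejected(self):
        recs = [IntronRecord("a", 1, "c", "+", 0, 10)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_matrix(recs)

    def test_template_implies_intron_present(self, bundle):
        recs = []
        for sp in sorted(bundle.gene_models):
            rec = extract_intron(bundle.gene_models[sp], 1)
            if rec.present:
                rec = intron_template_scan(rec, bundle.genomes[sp])
            recs.append(rec)
        m = build_feature_matrix(recs)
        assert (~m["template_present"] | m["intron_present"]).all()

    def test_scenario_matrix_matches_manifest(self, bundle):
        recs = []
        for sp in sorted(bundle.gene_models):
            rec = extract_intron(bundle.gene_models[sp], 1)
            if rec.present:
                rec = intron_template_scan(rec, bundle.genomes[sp])
            rec = annotate_intron_haca(rec, bundle.intron_haca.get(sp, []))
            recs.append(rec)
        m = build_feature_matrix(recs)
        truth = bundle.manifest.species
        assert int(m["template_present"].sum()) == bundle.scenario.n_template_bearing
        for sp in m.index:
            assert m.loc[sp, "template_present"] == truth[sp]["template_present"]
            assert m.loc[sp, "haca_present"] == truth[sp]["haca_present"]


class TestHacaSelection:
    def test_furthest_3p_selected(self):
        rec = IntronRecord("a", 1, "c", "+", 0, 400)
        out = annotate_intron_haca(rec, [(100, 106, 0.9), (300, 306, 0.5)])
        assert out.haca == (300, 306, 0.5)

    def test_empty_prediction_list(self):
        rec = IntronRecord("a", 1, "c", "+", 0, 400)
        assert annotate_intron_haca(rec, []).haca is None
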