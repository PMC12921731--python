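"""Deterministic, seeded generator of every input the pipeline consumes.

The generator emulates the statistical structure a TR-discovery screen
assumes: a multi-exon host gene whose second intron carries a planted
TR-like element (telomere-template region at a configurable offset and an
H/ACA-like terminus), assembled-transcript decoys engineered to fall at
each stage of the filter cascade, two coverage tracks in which only the
intronic transcript is missing from the Poly(A) library, a set of
homologous species with diverged intron flanks but conserved template
cores, and a fragmented, partly gap-rich genome alignment. Every planted
feature is recorded in a ground-truth manifest so that tests can verify
each transcript's fate and each alignment block's fate exactly.

Background sequence is i.i.d. uniform over A/C/G/T by default; spurious
telomere-template runs arising by chance are detected on both strands and
re-rolled so manifests are stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from . import candidate_pipeline as cp
from .candidate_pipeline import (
    AnnotationSet,
    CoverageTrack,
    ExternalScores,
    GenomicInterval,
    TranscriptRecord,
)
from .homolog_anchor import GeneModel, TRWindow
from .maf_ops import MafBlock, MafSequenceLine, write_maf
from .seqcore import (
    NucleotideSequence,
    TelomereUnit,
    TemplateScanParams,
    find_template_sites,
    is_telomeric_substring,
    reverse_complement,
    write_fasta,
)

__all__ = [
    "HostGeneSpec",
    "PlantedTRSpec",
    "DecoyCounts",
    "CoverageSpec",
    "DivergenceSpec",
    "MafSpec",
    "SyntheticScenario",
    "GroundTruthManifest",
    "ScenarioBundle",
    "generate_scenario",
    "mutate_homologs",
    "scenario_from_dict",
]

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class HostGeneSpec:
    """Exon/intron layout of the host gene (intron 2 hosts the TR)."""

    exon_lengths: Tuple[int, ...] = (150, 200, 180, 160)
    intron_lengths: Tuple[int, ...] = (120, 430, 90)

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one fewer intron than exons")


@dataclass(frozen=True)
class PlantedTRSpec:
    """The TR-like element planted in intron 2 of the reference species.

    ``offset5`` places the template region 80–90 nt from the intron 5'
    end, and the default intron length leaves ~335 nt downstream — the
    typical geometry of intron-hosted TRs. The transcript starts
    ``transcript_pad5`` nt upstream of the template, putting the template
    near the transcript 5' end.
    """

    motif: str = "TAAGCCTAAG"
    offset5: int = 85
    transcript_pad5: int = 28
    transcript_length: int = 327
    haca_h_box: str = "AGACTA"  # ANANNA pattern
    haca_aca_box: str = "ACA"

    def __post_init__(self) -> None:
        if not is_telomeric_substring(self.motif):
            raise ValueError(f"planted motif {self.motif!r} is not telomeric")


@dataclass(frozen=True)
class DecoyCounts:
    """How many decoy transcripts to plant for each intended fate."""

    weak_candidates: int = 4  # survive to ranking but score low
    low_coverage: int = 2
    nested: int = 2
    cds_overlap: int = 2
    ncrna_overlap: int = 2
    coding: int = 2
    overlength: int = 2
    no_template: int = 3  # one carries a near-miss (single-edit) motif
    multi_template: int = 2
    telomere_array: int = 1  # repeat array longer than max_template_len

    @property
    def total(self) -> int:
        return sum(asdict(self).values())


@dataclass(frozen=True)
class CoverageSpec:
    """Depths per feature for the two libraries (noiseless steps by default)."""

    exon_depth: float = 30.0
    tr_depth_total: float = 25.0
    tr_depth_polyA: float = 0.0
    decoy_depth: float = 15.0
    low_depth: float = 5.0
    polyA_scale: float = 1.0
    noise: str = "none"  # or "poisson"

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


@dataclass(frozen=True)
class DivergenceSpec:
    """Per-site substitution rate applied to homolog intron flanks."""

    rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("rate must lie in [0, 1)")


@dataclass(frozen=True)
class MafSpec:
    """Shape of the generated alignment: a mergeable chain, one gap-rich
    block and one isolated block over a species subset."""

    n_maf_species: int = 6
    chain_widths: Tuple[int, ...] = (100, 120, 80)
    inter_block_gaps: Tuple[int, ...] = (2, 4)
    gap_rich_width: int = 40
    max_random_gaps: int = 8

    def __post_init__(self) -> None:
        if len(self.inter_block_gaps) != len(self.chain_widths) - 1:
            raise ValueError("need one fewer inter-block gap than chain blocks")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of a synthetic study; defaults are the package's
    standard conditions (33 species, 21 of them template-bearing)."""

    n_species: int = 33
    n_template_bearing: int = 21  # includes the reference species
    reference_chrom_length: int = 70000
    flank_length: int = 200
    gc: float = 0.5
    host_gene: HostGeneSpec = field(default_factory=HostGeneSpec)
    tr: PlantedTRSpec = field(default_factory=PlantedTRSpec)
    decoys: DecoyCounts = field(default_factory=DecoyCounts)
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    divergence: DivergenceSpec = field(default_factory=DivergenceSpec)
    maf: MafSpec = field(default_factory=MafSpec)
    include_intron_absent_species: bool = True
    homolog_motifs: Tuple[str, ...] = (
        "TAAGCCTAAG",
        "CTAAGCCT",
        "CCTAAGCC",
        "TAAGCCTAAGC",
        "CTAAGCCTAA",
        "CCTAAGCCT",
        "CTAAGCCTAAGCCTA",
    )
    haca_free_bearing_species: int = 2  # template-bearing species without H/ACA

    def __post_init__(self) -> None:
        if not 2 <= self.n_template_bearing <= self.n_species:
            raise ValueError("n_template_bearing must lie in [2, n_species]")
        il = self.host_gene.intron_lengths[1]
        tr = self.tr
        if tr.offset5 + len(tr.motif) >= il:
            raise ValueError("planted TR does not fit in intron 2")
        if tr.offset5 - tr.transcript_pad5 < 0:
            raise ValueError("transcript would start before the intron")
        if tr.offset5 - tr.transcript_pad5 + tr.transcript_length > il:
            raise ValueError("planted TR transcript longer than intron 2")
        for m in self.homolog_motifs:
            if not is_telomeric_substring(m):
                raise ValueError(f"homolog motif {m!r} is not telomeric")


def scenario_from_dict(d: Mapping) -> SyntheticScenario:
    """Build a scenario from a (YAML-loaded) dict of overrides."""
    nested = {
        "host_gene": HostGeneSpec,
        "tr": PlantedTRSpec,
        "decoys": DecoyCounts,
        "coverage": CoverageSpec,
        "divergence": DivergenceSpec,
        "maf": MafSpec,
    }
    kwargs = {}
    for key, val in d.items():
        if key in nested:
            val = {
                k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
            }
            kwargs[key] = nested[key](**val)
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return SyntheticScenario(**kwargs)


# ---------------------------------------------------------------------------
# Manifest and bundle


@dataclass
class GroundTruthManifest:
    """Ground truth of everything the generator planted."""

    seed: int
    planted_tr_id: str
    transcript_fates: Dict[str, str]
    species: Dict[str, Dict]  # per-species template/intron/H/ACA ground truth
    maf_fates: Dict[str, str]
    expected_final_maf_blocks: int

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ScenarioBundle:
    """Everything one scenario generated, in memory."""

    scenario: SyntheticScenario
    seed: int
    genomes: Dict[str, Dict[str, NucleotideSequence]]  # species -> chrom -> seq
    gene_models: Dict[str, GeneModel]
    transcripts: List[TranscriptRecord]
    annotation: AnnotationSet
    external: ExternalScores
    track_total: CoverageTrack
    track_polyA: CoverageTrack
    intron_haca: Dict[str, List[Tuple[int, int, float]]]  # species -> hits
    maf_blocks: List[MafBlock]
    manifest: GroundTruthManifest

    @property
    def reference_species(self) -> str:
        return "species_01"

    @property
    def reference_genome(self) -> Dict[str, NucleotideSequence]:
        return self.genomes[self.reference_species]

    def genome_map(self) -> Dict[str, NucleotideSequence]:
        """Flat ``assembly.chromosome`` map, as MAF operations expect."""
        return {
            f"{sp}.{chrom}": seq
            for sp, chroms in self.genomes.items()
            for chrom, seq in chroms.items()
        }

    def write(self, outdir: Union[str, Path]) -> None:
        out = Path(outdir)
        (out / "genomes").mkdir(parents=True, exist_ok=True)
        (out / "gene_models").mkdir(exist_ok=True)
        for sp in sorted(self.genomes):
            write_fasta(
                [self.genomes[sp][c] for c in sorted(self.genomes[sp])],
                out / "genomes" / f"{sp}.fa",
            )
        for sp in sorted(self.gene_models):
            _write_gene_model_gff3(self.gene_models[sp], out / "gene_models" / f"{sp}.gff3")
        _write_annotation_gtf(self.annotation, out / "annotation.gtf")
        with open(out / "transcripts.bed", "w") as fh:
            for t in self.transcripts:
                iv = t.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.id}\t0\t{iv.strand}\n")
        _write_bedgraph(self.track_total, out / "coverage_total.bedgraph")
        _write_bedgraph(self.track_polyA, out / "coverage_polya.bedgraph")
        with open(out / "coding_scores.tsv", "w") as fh:
            fh.write("transcript_id\tscore_a\tscore_b\n")
            for tid in sorted(self.external.coding_scores):
                a, b = self.external.coding_scores[tid]
                fh.write(f"{tid}\t{a:.3f}\t{b:.3f}\n")
        with open(out / "structure_loci.bed", "w") as fh:
            for iv in self.external.structure_loci:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tstructure_locus\t0\t{iv.strand}\n")
        with open(out / "haca_predictions.tsv", "w") as fh:
            fh.write("sequence_id\tstart\tend\tconfidence\n")
            for tid in sorted(self.external.haca_predictions):
                for s, e, c in self.external.haca_predictions[tid]:
                    fh.write(f"{tid}\t{s}\t{e}\t{c:.2f}\n")
            for sp in sorted(self.intron_haca):
                for s, e, c in self.intron_haca[sp]:
                    fh.write(f"{sp}.intron2\t{s}\t{e}\t{c:.2f}\n")
        write_maf(self.maf_blocks, out / "alignment.maf")
        self.manifest.to_yaml(out / "manifest.yaml")


# ---------------------------------------------------------------------------
# Helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _species_name(i: int) -> str:
    return f"species_{i:02d}"


def _mutate(rng: np.random.Generator, seq: str, rate: float, protect: Sequence[Tuple[int, int]] = ()) -> str:
    """Per-site substitutions at ``rate`` outside the protected intervals."""
    protected = np.zeros(len(seq), dtype=bool)
    for s, e in protect:
        protected[s:e] = True
    hit = (rng.random(len(seq)) < rate) & ~protected
    chars = list(seq)
    for i in np.flatnonzero(hit):
        choices = [b for b in BASES if b != chars[i]]
        chars[i] = choices[rng.integers(3)]
    return "".join(chars)


def mutate_homologs(
    window: TRWindow, rate: float, protect: Tuple[int, int], seed: int
) -> TRWindow:
    """Diverge a TR window by per-site substitution, core protected.

    ``protect`` is a (start, end) interval in window coordinates that is
    left untouched; it should cover the template region so the returned
    window still validates. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    mutated = _mutate(rng, window.sequence.residues, rate, [protect])
    return TRWindow(
        species=window.species,
        sequence=NucleotideSequence(window.sequence.identifier, mutated),
        template_offset=window.template_offset,
        motif=window.motif,
        truncated_5p=window.truncated_5p,
        truncated_3p=window.truncated_3p,
    )


def _scrub_spurious_sites(
    rng: np.random.Generator,
    residues: List[str],
    allowed: Sequence[Tuple[int, int]],
    params: TemplateScanParams,
    max_rounds: int = 50,
) -> None:
    """Re-roll chance telomere-template runs outside the planted regions.

    Scans both strands; any maximal run not contained in an allowed
    interval has its non-planted positions replaced with fresh random
    bases until the sequence is clean (mutates ``residues`` in place).
    Planted positions themselves are never rewritten.
    """
    protected = np.zeros(len(residues), dtype=bool)
    for s, e in allowed:
        protected[s:e] = True

    def spurious_spans() -> List[Tuple[int, int]]:
        n = len(residues)
        seq_fwd = NucleotideSequence("fwd", "".join(residues))
        seq_rev = NucleotideSequence("rev", reverse_complement(seq_fwd.residues))
        spans = []
        for site in find_template_sites(seq_fwd, params):
            spans.append((site.start, site.end))
        for site in find_template_sites(seq_rev, params):
            spans.append((n - site.end, n - site.start))
        return [
            (s, e)
            for s, e in spans
            if not any(a_s <= s and e <= a_e for a_s, a_e in allowed)
        ]

    for _ in range(max_rounds):
        bad = spurious_spans()
        if not bad:
            return
        for s, e in bad:
            for i in range(s, e):
                if not protected[i]:
                    residues[i] = BASES[rng.integers(4)]
    raise RuntimeError("could not scrub spurious template runs; widen allowed regions")


def _place(residues: List[str], pos: int, insert: str) -> None:
    residues[pos : pos + len(insert)] = list(insert)


def _motif_phase(motif: str, repeat: str) -> int:
    k = len(repeat)
    pos = (repeat * (len(motif) // k + 2)).find(motif)
    if pos < 0:
        raise ValueError(f"{motif!r} is not a substring of the repeated template")
    return pos % k


def _plant_breaking(
    rng: np.random.Generator, chars: List[str], pos: int, motif: str, repeat: str
) -> None:
    """Plant a telomeric motif and break the cyclic continuation at both
    boundaries, so the planted maximal run is exactly the planted span."""
    chars[pos : pos + len(motif)] = list(motif)
    k = len(repeat)
    p = _motif_phase(motif, repeat)
    left_cont = repeat[(p - 1) % k]
    right_cont = repeat[(p + len(motif)) % k]
    if pos > 0:
        choices = [b for b in BASES if b != left_cont]
        chars[pos - 1] = choices[rng.integers(3)]
    if pos + len(motif) < len(chars):
        choices = [b for b in BASES if b != right_cont]
        chars[pos + len(motif)] = choices[rng.integers(3)]


# ---------------------------------------------------------------------------
# Generation


def generate_scenario(
    scenario: SyntheticScenario = SyntheticScenario(), seed: int = 42
) -> ScenarioBundle:
    """Generate every pipeline input for one synthetic study.

    Byte-identical outputs for identical (scenario, seed); raises on
    infeasible configurations before building anything.
    """
    rng = np.random.default_rng(seed)
    params = TemplateScanParams()
    repeat = TelomereUnit().template_repeat  # GCCTAA
    hg, tr, cov = scenario.host_gene, scenario.tr, scenario.coverage

    genomes: Dict[str, Dict[str, NucleotideSequence]] = {}
    gene_models: Dict[str, GeneModel] = {}
    species_truth: Dict[str, Dict] = {}
    intron_haca: Dict[str, List[Tuple[int, int, float]]] = {}

    # --- per-species gene regions -----------------------------------------
    ref_intron2 = None
    for i in range(1, scenario.n_species + 1):
        sp = _species_name(i)
        bearing = i <= scenario.n_template_bearing
        intron_absent = (
            scenario.include_intron_absent_species and i == scenario.n_species
        )
        strand = "-" if i % 2 == 1 else "+"  # reference (i=1) sits on '-'

        if i == 1:
            offset5 = tr.offset5
            motif = tr.motif
            flank5 = _random_dna(rng, offset5, scenario.gc)
            flank3 = _random_dna(
                rng, hg.intron_lengths[1] - offset5 - len(motif), scenario.gc
            )
            chars = list(flank5 + motif + flank3)
            _plant_breaking(rng, chars, offset5, motif, repeat)
            intron2 = "".join(chars)
            ref_intron2 = intron2
        elif bearing:
            assert ref_intron2 is not None
            offset5 = int(rng.integers(80, 91))
            motif = scenario.homolog_motifs[rng.integers(len(scenario.homolog_motifs))]
            flank5 = _mutate(
                rng, ref_intron2[: tr.offset5], scenario.divergence.rate
            )[:offset5]
            if len(flank5) < offset5:
                flank5 = flank5 + _random_dna(rng, offset5 - len(flank5), scenario.gc)
            flank3 = _mutate(
                rng,
                ref_intron2[tr.offset5 + len(tr.motif) :],
                scenario.divergence.rate,
            )
            chars = list(flank5 + motif + flank3)
            _plant_breaking(rng, chars, offset5, motif, repeat)
            intron2 = "".join(chars)
        elif intron_absent:
            offset5, motif, intron2 = None, None, ""
        else:
            offset5, motif = None, None
            intron2 = _random_dna(rng, 60, scenario.gc)

        # H/ACA-like terminus: plant the literal boxes near the intron 3'
        # end for bearing species (except the configured drop-outs).
        has_haca = bearing and (
            i <= scenario.n_template_bearing - scenario.haca_free_bearing_species
            or i == 1
        )
        if bearing and has_haca:
            h_pos = len(intron2) - 60
            aca_pos = len(intron2) - 15
            chars = list(intron2)
            _place(chars, h_pos, tr.haca_h_box)
            _place(chars, aca_pos, tr.haca_aca_box)
            intron2 = "".join(chars)
            intron_haca[sp] = [(h_pos, aca_pos + len(tr.haca_aca_box), 0.83)]
        elif not bearing and i == scenario.n_template_bearing + 1 and intron2:
            # one intron with an H/ACA-like prediction but no template
            intron_haca[sp] = [(10, 40, 0.55)]

        intron_seqs = [
            _random_dna(rng, hg.intron_lengths[0], scenario.gc),
            intron2,
            _random_dna(rng, hg.intron_lengths[2], scenario.gc),
        ]
        exon_seqs = [_random_dna(rng, L, scenario.gc) for L in hg.exon_lengths]
        premrna = exon_seqs[0]
        for ex, intr in zip(exon_seqs[1:], intron_seqs):
            premrna += intr + ex

        if i == 1:
            chrom, chrom_len = "chrI", scenario.reference_chrom_length
            region_start = 2000
            residues = list(_random_dna(rng, chrom_len, scenario.gc))
        else:
            chrom = "chr1"
            chrom_len = 2 * scenario.flank_length + len(premrna)
            region_start = scenario.flank_length
            residues = list(_random_dna(rng, chrom_len, scenario.gc))

        inserted = premrna if strand == "+" else reverse_complement(premrna)
        _place(residues, region_start, inserted)
        region_end = region_start + len(premrna)

        # Exon genomic coordinates from transcription-order layout.
        tx_bounds = []
        cursor = 0
        for j, L in enumerate(hg.exon_lengths):
            tx_bounds.append((cursor, cursor + L))
            cursor += L
            if j < len(intron_seqs):
                cursor += len(intron_seqs[j])
        if strand == "+":
            exons = tuple(
                (region_start + s, region_start + e) for s, e in tx_bounds
            )
        else:
            exons = tuple(
                sorted((region_end - e, region_end - s) for s, e in tx_bounds)
            )
        model = GeneModel(
            species=sp, gene_id=f"{sp}_host", chrom=chrom, strand=strand, exons=exons
        )

        # Template genomic interval (for the scrub's allow-list and truth).
        def tx_to_genomic(t0: int, t1: int) -> Tuple[int, int]:
            if strand == "+":
                return region_start + t0, region_start + t1
            return region_end - t1, region_end - t0

        intron2_tx_start = hg.exon_lengths[0] + len(intron_seqs[0]) + hg.exon_lengths[1]
        allowed: List[Tuple[int, int]] = []
        truth: Dict = {
            "strand": strand,
            "chrom": chrom,
            "intron2_length": len(intron2),
            "template_present": bool(bearing),
            "haca_present": sp in intron_haca,
        }
        if bearing:
            t0 = intron2_tx_start + offset5
            t1 = t0 + len(motif)
            g0, g1 = tx_to_genomic(t0, t1)
            allowed.append((g0, g1))
            truth.update(
                {
                    "motif": motif,
                    "offset5": offset5,
                    "template_genomic_start": g0,
                    "template_genomic_end": g1,
                }
            )
        g_i2 = tx_to_genomic(intron2_tx_start, intron2_tx_start + len(intron2))
        truth["intron2_genomic"] = [int(g_i2[0]), int(g_i2[1])]
        species_truth[sp] = truth

        genomes[sp] = {"__residues__": residues}  # placeholder; finalized below
        gene_models[sp] = model
        genomes[sp]["__allowed__"] = allowed  # type: ignore[assignment]
        genomes[sp]["__chrom__"] = chrom  # type: ignore[assignment]

    # --- reference-species transcript decoys ------------------------------
    ref_sp = _species_name(1)
    ref_res: List[str] = genomes[ref_sp]["__residues__"]  # type: ignore[assignment]
    ref_allowed: List[Tuple[int, int]] = genomes[ref_sp]["__allowed__"]  # type: ignore[assignment]
    ref_model = gene_models[ref_sp]
    hg_region_start = ref_model.exons[0][0]
    hg_region_end = ref_model.exons[-1][1]
    ref_truth = species_truth[ref_sp]

    # TR transcript (transcribed coordinates within intron 2).
    i2_g0, i2_g1 = ref_truth["intron2_genomic"]
    tr_tx_start = tr.offset5 - tr.transcript_pad5
    # reference strand is '-': transcript transcribed span -> genomic span
    tr_g_end = i2_g1 - tr_tx_start
    tr_g_start = tr_g_end - tr.transcript_length
    tr_id = "tr_transcript"

    transcripts: List[TranscriptRecord] = []
    fates: Dict[str, str] = {}
    coding_scores: Dict[str, Tuple[float, float]] = {}
    haca_predictions: Dict[str, List[Tuple[int, int, float]]] = {}
    structure_loci: List[GenomicInterval] = []

    def add_transcript(tid: str, start: int, end: int, strand: str, fate: str,
                       scores: Tuple[float, float] = (0.1, 0.15)) -> TranscriptRecord:
        rec = TranscriptRecord(
            interval=GenomicInterval("chrI", start, end, strand), id=tid
        )
        transcripts.append(rec)
        fates[tid] = fate
        coding_scores[tid] = scores
        return rec

    add_transcript(tr_id, tr_g_start, tr_g_end, "-", cp.FATE_RANKED, (0.05, 0.1))
    haca_predictions[tr_id] = [(150, 156, 0.61), (300, 310, 0.83)]
    # Structure locus around the template, in genomic coordinates.
    t_g0, t_g1 = ref_truth["template_genomic_start"], ref_truth["template_genomic_end"]
    structure_loci.append(GenomicInterval("chrI", t_g0 - 40, t_g1 + 40, "."))
    # Two structure loci far from any transcript.
    structure_loci.append(GenomicInterval("chrI", 45000, 45120, "."))
    structure_loci.append(GenomicInterval("chrI", 45500, 45610, "."))

    # Partial host-mRNA assembly: spans the last two exons (overlaps CDS).
    mRNA_start = ref_model.exons[-2][0]
    mRNA_end = ref_model.exons[-1][1]
    add_transcript("host_mrna_fragment", mRNA_start, mRNA_end, "-", cp.STAGE_OVERLAP)

    # Decoys, each in its own slot downstream of the gene region.
    slot = 4000
    slot_step = 1500
    dc = scenario.decoys
    unit_rc = TelomereUnit().template_repeat  # GCCTAA

    def next_slot() -> int:
        nonlocal slot
        s = slot
        slot += slot_step
        return s

    def plant_tx_sequence(start: int, length: int, strand: str,
                          motifs_at: Sequence[Tuple[int, str]]) -> None:
        """Write a transcribed-orientation sequence with planted motifs."""
        seq = list(_random_dna(rng, length, scenario.gc))
        for pos, m in motifs_at:
            if is_telomeric_substring(m):
                _plant_breaking(rng, seq, pos, m, repeat)
            else:  # near-miss decoy motifs are planted verbatim
                _place(seq, pos, m)
        insert = "".join(seq)
        if strand == "-":
            insert = reverse_complement(insert)
        _place(ref_res, start, insert)
        for pos, m in motifs_at:
            if strand == "+":
                ref_allowed.append((start + pos, start + pos + len(m)))
            else:
                ref_allowed.append((start + length - pos - len(m), start + length - pos))

    weak_intervals: List[Tuple[int, int, str]] = []
    for j in range(dc.weak_candidates):
        s = next_slot()
        strand = "+" if j % 2 == 0 else "-"
        plant_tx_sequence(s, 300, strand, [(249, "CTAAGCCT")])
        add_transcript(f"weak_{j:02d}", s, s + 300, strand, cp.FATE_RANKED)
        weak_intervals.append((s, s + 300, strand))
    for j in range(dc.low_coverage):
        s = next_slot()
        plant_tx_sequence(s, 300, "+", [(50, "TAAGCCTAAG")])
        add_transcript(f"lowcov_{j:02d}", s, s + 300, "+", cp.STAGE_COVERAGE)
    for j in range(dc.nested):
        ws, we, wstrand = weak_intervals[j % len(weak_intervals)]
        add_transcript(f"nested_{j:02d}", ws + 50, ws + 200, wstrand, cp.STAGE_REDUNDANCY)
    for j in range(dc.cds_overlap):
        anchor = hg_region_start if j % 2 == 0 else hg_region_end
        s = anchor - 50 if j % 2 == 0 else anchor - 250
        add_transcript(f"cdsov_{j:02d}", s, s + 300, "+", cp.STAGE_OVERLAP)
    ncrna_gene = GenomicInterval("chrI", 42000, 42120, "+")
    for j in range(dc.ncrna_overlap):
        s = 42000 - 100 + j * 150
        add_transcript(f"ncov_{j:02d}", s, s + 200, "+", cp.STAGE_OVERLAP)
    for j in range(dc.coding):
        s = next_slot()
        plant_tx_sequence(s, 300, "+", [(50, "TAAGCCTAAG")])
        scores = (0.9, 0.3) if j % 2 == 0 else (0.4, 0.8)
        add_transcript(f"coding_{j:02d}", s, s + 300, "+", cp.STAGE_CODING, scores)
    for j in range(dc.overlength):
        s = next_slot()
        plant_tx_sequence(s, 1200, "+", [(100, "TAAGCCTAAG")])
        add_transcript(f"long_{j:02d}", s, s + 1200, "+", cp.STAGE_LENGTH)
    for j in range(dc.no_template):
        s = next_slot()
        if j == 0:
            # near-miss: single central edit breaks the cyclic language
            plant_tx_sequence(s, 300, "+", [(50, "TAAGACTAAG")])
        else:
            plant_tx_sequence(s, 300, "+", [])
        add_transcript(f"notmpl_{j:02d}", s, s + 300, "+", cp.STAGE_TEMPLATE)
    for j in range(dc.multi_template):
        s = next_slot()
        plant_tx_sequence(s, 400, "+", [(40, "TAAGCCTAAG"), (150, "CCTAAGCC")])
        add_transcript(f"multi_{j:02d}", s, s + 400, "+", cp.FLAG_MULTI_TEMPLATE)
    for j in range(dc.telomere_array):
        s = next_slot()
        plant_tx_sequence(s, 300, "+", [(60, unit_rc * 7)])
        add_transcript(f"telarray_{j:02d}", s, s + 300, "+", cp.STAGE_TEMPLATE)

    # --- scrub chance template runs, then freeze genomes ------------------
    for sp in sorted(genomes):
        res: List[str] = genomes[sp]["__residues__"]  # type: ignore[assignment]
        allowed: List[Tuple[int, int]] = genomes[sp]["__allowed__"]  # type: ignore[assignment]
        chrom: str = genomes[sp]["__chrom__"]  # type: ignore[assignment]
        _scrub_spurious_sites(rng, res, allowed, params)
        genomes[sp] = {chrom: NucleotideSequence(chrom, "".join(res))}

    # --- annotation (reference species) ------------------------------------
    cds = []
    for s, e in ref_model.exons:
        cds.append(GenomicInterval("chrI", s, e, ref_model.strand))
        cds.append(GenomicInterval("chrI", s, e, ref_model.strand))  # duplicate record
    annotation = AnnotationSet(cds=cds, ncrna=[(ncrna_gene, "snoRNA")])

    # --- coverage tracks ---------------------------------------------------
    n_ref = scenario.reference_chrom_length
    total = np.zeros(n_ref)
    polya = np.zeros(n_ref)
    for t in transcripts:  # decoys first; gene paint below overrides overlaps
        depth = cov.low_depth if t.id.startswith("lowcov") else cov.decoy_depth
        total[t.interval.start : t.interval.end] = depth
        if t.id.startswith("weak"):
            polya[t.interval.start : t.interval.end] = cov.decoy_depth
    for s, e in ref_model.exons:
        total[s:e] = cov.exon_depth
        polya[s:e] = cov.exon_depth
    total[tr_g_start:tr_g_end] = cov.tr_depth_total
    polya[tr_g_start:tr_g_end] = cov.tr_depth_polyA
    if cov.noise == "poisson":
        total = rng.poisson(total).astype(float)
        polya = rng.poisson(polya).astype(float)
    track_total = CoverageTrack({"chrI": total})
    track_polyA = CoverageTrack({"chrI": polya})

    external = ExternalScores(
        coding_scores=coding_scores,
        structure_loci=structure_loci,
        haca_predictions=haca_predictions,
    )

    # --- MAF ---------------------------------------------------------------
    maf_blocks, maf_fates, expected_final = _generate_maf(
        rng, scenario, genomes
    )

    manifest = GroundTruthManifest(
        seed=seed,
        planted_tr_id=tr_id,
        transcript_fates=fates,
        species=species_truth,
        maf_fates=maf_fates,
        expected_final_maf_blocks=expected_final,
    )
    return ScenarioBundle(
        scenario=scenario,
        seed=seed,
        genomes=genomes,
        gene_models=gene_models,
        transcripts=transcripts,
        annotation=annotation,
        external=external,
        track_total=track_total,
        track_polyA=track_polyA,
        intron_haca=intron_haca,
        maf_blocks=maf_blocks,
        manifest=manifest,
    )


def _generate_maf(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    genomes: Dict[str, Dict[str, NucleotideSequence]],
) -> Tuple[List[MafBlock], Dict[str, str], int]:
    """A mergeable chain, one gap-rich block and one isolated block.

    Texts are genuine genome substrings with random gap columns, so that
    merged blocks can be checked for residue conservation against the
    genomes.
    """
    maf = scenario.maf
    species = [_species_name(i) for i in range(1, maf.n_maf_species + 1)]
    chroms = {sp: next(iter(genomes[sp])) for sp in species}
    lengths = {sp: genomes[sp][chroms[sp]].length for sp in species}
    cursors = {sp: 100 for sp in species}
    cursors[species[0]] = 50000  # reference cursor in a feature-free region

    def make_line(sp: str, width: int, n_gaps: int, strand: str = "+") -> MafSequenceLine:
        size = width - n_gaps
        start = cursors[sp]
        seq = genomes[sp][chroms[sp]]
        if strand == "+":
            segment = seq.residues[start : start + size]
        else:
            rev_start = lengths[sp] - start - size
            segment = reverse_complement(seq.residues[rev_start : rev_start + size])
        gap_cols = sorted(rng.choice(width, size=n_gaps, replace=False))
        text = []
        seg_iter = iter(segment)
        gaps = set(int(g) for g in gap_cols)
        for col in range(width):
            text.append("-" if col in gaps else next(seg_iter))
        cursors[sp] += size
        return MafSequenceLine(
            source=f"{sp}.{chroms[sp]}",
            start=start,
            size=size,
            strand=strand,
            src_size=lengths[sp],
            text="".join(text),
        )

    blocks: List[MafBlock] = []
    fates: Dict[str, str] = {}

    chain_members = [species[:4], species[:5], species[:4]]
    for bi, width in enumerate(maf.chain_widths):
        members = chain_members[bi % len(chain_members)]
        lines = tuple(
            make_line(sp, width, int(rng.integers(0, maf.max_random_gaps + 1)))
            for sp in members
        )
        blocks.append(MafBlock(lines=lines, score=float(100 * (bi + 1))))
        fates[f"block_{bi}"] = "merged"
        if bi < len(maf.inter_block_gaps):
            for sp in species:
                cursors[sp] += maf.inter_block_gaps[bi]

    # gap-rich block: two species, ~95% gaps
    for sp in species[:2]:
        cursors[sp] += 50
    w = maf.gap_rich_width
    gap_lines = tuple(make_line(sp, w, w - 2) for sp in species[:2])
    blocks.append(MafBlock(lines=gap_lines, score=5.0))
    fates[f"block_{len(blocks) - 1}"] = "removed_ungap"

    # isolated block, far from the chain, second species on '-'
    for sp in species[:2]:
        cursors[sp] += 500
    iso_lines = (
        make_line(species[0], 60, 3),
        make_line(species[1], 60, 3, strand="-"),
    )
    blocks.append(MafBlock(lines=iso_lines, score=42.0))
    fates[f"block_{len(blocks) - 1}"] = "kept"

    return blocks, fates, 2


# ---------------------------------------------------------------------------
# Writers for the standard formats


def _write_gene_model_gff3(model: GeneModel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g_start = model.exons[0][0] + 1
        g_end = model.exons[-1][1]
        fh.write(
            f"{model.chrom}\tteloscan\tgene\t{g_start}\t{g_end}\t.\t{model.strand}\t.\t"
            f"ID={model.gene_id}\n"
        )
        for k, (s, e) in enumerate(model.exons, start=1):
            fh.write(
                f"{model.chrom}\tteloscan\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
                f"ID={model.gene_id}.exon{k};Parent={model.gene_id}\n"
            )


def _write_annotation_gtf(annotation: AnnotationSet, path: Path) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(annotation.cds, start=1):
            fh.write(
                f"{iv.chrom}\tteloscan\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t0\t"
                f'gene_id "cds_{k}"; transcript_id "cds_{k}.t"; gbkey "CDS";\n'
            )
        for k, (iv, family) in enumerate(annotation.ncrna, start=1):
            fh.write(
                f"{iv.chrom}\tteloscan\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "ncrna_{k}"; transcript_id "ncrna_{k}.t"; '
                f'gene_biotype "{family}";\n'
            )


def _write_bedgraph(track: CoverageTrack, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            depths = track.depths[chrom]
            boundaries = np.flatnonzero(np.diff(depths)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(depths)]))
            for s, e in zip(starts, ends):
                d = depths[s]
                if d != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")
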