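"""Multi-stage filtering of transcript candidates for a telomerase RNA gene.

Starting from assembled transcripts of a total-RNA library, the cascade
removes, in order: weakly covered transcripts, redundant (contained)
transcripts, anything overlapping annotated CDS or ncRNA genes,
transcripts with coding potential, transcripts longer than known TRs, and
transcripts without a valid telomere-template region. Survivors are then
annotated with expression contrast against a Poly(A)-enriched library,
structure-conservation loci and H/ACA box predictions, and ranked by a
rule-based score counting the soft properties expected of a genuine TR.

Interval work goes through :mod:`intervaltree`; per-base coverage is held
as numpy arrays per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .seqcore import (
    NucleotideSequence,
    TemplateScanParams,
    TemplateSite,
    find_template_sites,
    reverse_complement,
)

__all__ = [
    "GenomicInterval",
    "TranscriptRecord",
    "AnnotationSet",
    "ExternalScores",
    "CoverageTrack",
    "CoverageStats",
    "PolyAThresholds",
    "ScoreConfig",
    "CandidateReport",
    "CascadeResult",
    "NCRNA_FAMILIES",
    "dedup_cds",
    "overlap_filter",
    "coverage_stats",
    "attach_coverage",
    "min_coverage_filter",
    "redundancy_filter",
    "coding_filter",
    "length_filter",
    "scan_and_flag_templates",
    "polyA_classify",
    "annotate_structure_and_haca",
    "score_candidates",
    "compute_recall",
    "run_cascade",
    "extract_transcript_sequences",
    "read_bed_intervals",
    "read_bed_transcripts",
    "read_gtf_annotation",
    "read_coding_scores",
    "read_haca_predictions",
]

NCRNA_FAMILIES = ("tRNA", "miRNA", "snoRNA", "rRNA", "snRNA", "other")

# Stage labels, shared with the synthetic generator's ground-truth manifest.
STAGE_COVERAGE = "coverage"
STAGE_REDUNDANCY = "redundancy"
STAGE_OVERLAP = "annotation_overlap"
STAGE_CODING = "coding_potential"
STAGE_LENGTH = "length"
STAGE_TEMPLATE = "template"
FLAG_MULTI_TEMPLATE = "multi_template"
FATE_RANKED = "ranked"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptRecord:
    """A candidate transcript with coverage, template and filter state."""

    interval: GenomicInterval
    id: str
    coverage_total: Optional[float] = None  # sum of per-base depths, total library
    coverage_polyA: Optional[float] = None  # rescaled to the total library
    coverage_min: Optional[float] = None
    polyA_class: str = "unknown"
    template_sites: List[TemplateSite] = field(default_factory=list)
    has_structure_locus: bool = False
    haca: Optional[Tuple[int, int, float]] = None
    flags: Set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def mean_coverage(self) -> Optional[float]:
        if self.coverage_total is None:
            return None
        return self.coverage_total / self.length

    @property
    def valid_template_sites(self) -> List[TemplateSite]:
        return [s for s in self.template_sites if not s.overlong]

    @property
    def has_haca(self) -> bool:
        return self.haca is not None


@dataclass
class AnnotationSet:
    """Annotated CDS intervals and ncRNA genes with family labels."""

    cds: List[GenomicInterval] = field(default_factory=list)
    ncrna: List[Tuple[GenomicInterval, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, fam in self.ncrna:
            if fam not in NCRNA_FAMILIES:
                raise ValueError(f"unknown ncRNA family {fam!r}")


@dataclass
class ExternalScores:
    """Outputs of external tools consumed, never computed, by the cascade.

    ``coding_scores`` maps transcript id -> (score_a, score_b), each the
    coding probability reported by one of two independent classifiers;
    ``structure_loci`` are structure-conservation loci; ``haca_predictions``
    maps a sequence id to (start, end, confidence) H/ACA motif hits in
    transcript coordinates.
    """

    coding_scores: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    structure_loci: List[GenomicInterval] = field(default_factory=list)
    haca_predictions: Dict[str, List[Tuple[int, int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, (a, b) in self.coding_scores.items():
            if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
                raise ValueError(f"coding scores for {tid!r} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Coverage


class CoverageStats(NamedTuple):
    sum: float
    mean: float
    min: float


class CoverageTrack:
    """Per-base read depth, one numpy array per chromosome."""

    def __init__(self, depths: Mapping[str, np.ndarray]):
        self.depths = {c: np.asarray(d, dtype=float) for c, d in depths.items()}

    @classmethod
    def from_bedgraph(
        cls, path: Union[str, Path], chrom_sizes: Mapping[str, int]
    ) -> "CoverageTrack":
        depths = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
        table = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
            comment="#",
        )
        for row in table.itertuples(index=False):
            if row.chrom not in depths:
                raise ValueError(f"bedGraph chromosome {row.chrom!r} not in chrom_sizes")
            depths[row.chrom][row.start : row.end] = row.depth
        return cls(depths)

    def stats(self, interval: GenomicInterval) -> CoverageStats:
        if interval.chrom not in self.depths:
            raise KeyError(f"chromosome {interval.chrom!r} absent from coverage track")
        window = self.depths[interval.chrom][interval.start : interval.end]
        if len(window) == 0:
            return CoverageStats(0.0, 0.0, 0.0)
        return CoverageStats(float(window.sum()), float(window.mean()), float(window.min()))


def coverage_stats(interval: GenomicInterval, track: CoverageTrack) -> CoverageStats:
    """Sum / mean / min of per-base depth over the interval."""
    return track.stats(interval)


def attach_coverage(
    items: Sequence[TranscriptRecord],
    track_total: CoverageTrack,
    track_polyA: Optional[CoverageTrack] = None,
    polyA_scale: float = 1.0,
) -> List[TranscriptRecord]:
    """Populate coverage fields from the two library tracks.

    ``polyA_scale`` is the library-size rescaling factor applied to the
    Poly(A) track so both are on the total-library scale.
    """
    for item in items:
        st = track_total.stats(item.interval)
        item.coverage_total = st.sum
        item.coverage_min = st.min
        if track_polyA is not None:
            item.coverage_polyA = track_polyA.stats(item.interval).sum * polyA_scale
    return list(items)


# ---------------------------------------------------------------------------
# Filter stages


def dedup_cds(cds: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """One record per unique (chrom, start, end, strand), coordinate-sorted."""
    return sorted(set(cds))


def _interval_trees(
    intervals: Iterable[GenomicInterval], stranded: bool
) -> Dict[Tuple[str, str], IntervalTree]:
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand if stranded else ".")
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _tree_overlaps(
    trees: Mapping[Tuple[str, str], IntervalTree], iv: GenomicInterval, stranded: bool
) -> bool:
    keys = [(iv.chrom, iv.strand)] if stranded else [(iv.chrom, ".")]
    return any(k in trees and trees[k].overlaps(iv.start, iv.end) for k in keys)


def overlap_filter(
    items: Sequence[TranscriptRecord],
    annotation: AnnotationSet,
    *,
    stranded: bool = False,
) -> List[TranscriptRecord]:
    """Remove every transcript sharing >= 1 bp with annotated CDS or ncRNA.

    Strand-agnostic by default: a novel-ncRNA screen must drop antisense
    overlaps of known genes as well.
    """
    anno = list(annotation.cds) + [iv for iv, _ in annotation.ncrna]
    trees = _interval_trees(anno, stranded)
    return [i for i in items if not _tree_overlaps(trees, i.interval, stranded)]


def min_coverage_filter(
    items: Sequence[TranscriptRecord],
    threshold: float = 10.0,
    metric: str = "mean",
) -> List[TranscriptRecord]:
    """Retain transcripts with per-base depth >= threshold (mean by default).

    ``metric="min"`` instead requires every base to reach the threshold.
    """
    if metric not in ("mean", "min"):
        raise ValueError("metric must be 'mean' or 'min'")
    out = []
    for item in items:
        value = item.mean_coverage if metric == "mean" else item.coverage_min
        if value is None:
            raise ValueError(f"transcript {item.id!r} has no coverage attached")
        if value >= threshold:
            out.append(item)
    return out


def redundancy_filter(items: Sequence[TranscriptRecord]) -> List[TranscriptRecord]:
    """Remove transcripts fully contained in another retained transcript.

    Containment is same-strand. Among identical intervals the transcript
    with the lexicographically smallest id is kept. Implemented as a
    start-sorted sweep; equivalent to the quadratic containment check.
    """
    by_group: Dict[Tuple[str, str], List[TranscriptRecord]] = {}
    for item in items:
        by_group.setdefault((item.interval.chrom, item.interval.strand), []).append(item)

    kept_ids: Set[str] = set()
    for group in by_group.values():
        group.sort(key=lambda t: (t.interval.start, -t.interval.end, t.id))
        max_end = -1
        for item in group:
            if item.interval.end <= max_end:
                continue  # contained in an already kept transcript
            kept_ids.add(item.id)
            max_end = max(max_end, item.interval.end)
    return [i for i in items if i.id in kept_ids]


def coding_filter(
    items: Sequence[TranscriptRecord],
    scores: ExternalScores,
    cutoff: float = 0.5,
) -> List[TranscriptRecord]:
    """Remove transcripts classified as coding by either classifier.

    A score <= cutoff counts as non-coding; a transcript is removed when
    *either* score exceeds the cutoff. Unscored transcripts are retained
    and flagged ``unscored_coding``.
    """
    out = []
    for item in items:
        pair = scores.coding_scores.get(item.id)
        if pair is None:
            item.flags.add("unscored_coding")
            out.append(item)
        elif pair[0] <= cutoff and pair[1] <= cutoff:
            out.append(item)
    return out


def length_filter(
    items: Sequence[TranscriptRecord], max_len: int = 1000
) -> List[TranscriptRecord]:
    """Retain transcripts of at most ``max_len`` nt."""
    return [i for i in items if i.length <= max_len]


def extract_transcript_sequences(
    genome: Mapping[str, NucleotideSequence],
    items: Sequence[TranscriptRecord],
) -> Dict[str, NucleotideSequence]:
    """Strand-aware transcript sequences (reverse-complemented on '-')."""
    out: Dict[str, NucleotideSequence] = {}
    for item in items:
        iv = item.interval
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        sub = genome[iv.chrom].residues[iv.start : iv.end]
        if iv.strand == "-":
            sub = reverse_complement(sub)
        out[item.id] = NucleotideSequence(item.id, sub)
    return out


def scan_and_flag_templates(
    items: Sequence[TranscriptRecord],
    params: TemplateScanParams,
    sequences: Mapping[str, NucleotideSequence],
) -> List[TranscriptRecord]:
    """Attach template sites; drop template-free transcripts.

    Transcripts with >= 2 valid (non-overlong) sites are kept but flagged
    ``multi_template``: multiple templates are unexpected for a genuine
    TR, so they are excluded from ranking while still being reported.
    """
    out = []
    for item in items:
        if item.id not in sequences:
            raise KeyError(f"no sequence available for transcript {item.id!r}")
        item.template_sites = find_template_sites(sequences[item.id], params)
        valid = item.valid_template_sites
        if not valid:
            continue
        if len(valid) >= 2:
            item.flags.add(FLAG_MULTI_TEMPLATE)
        out.append(item)
    return out


# ---------------------------------------------------------------------------
# Annotation of survivors


@dataclass(frozen=True)
class PolyAThresholds:
    """Ratio bins for Poly(A)-library expression relative to total RNA.

    The bins are a reporting convention of this package (the underlying
    labels — absent / half / similar / abundant — are standard but their
    numeric boundaries are not): r < absent_below -> absent;
    r < half_below -> half; r <= similar_upto -> similar; else abundant.
    """

    absent_below: float = 0.1
    half_below: float = 0.7
    similar_upto: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.absent_below < self.half_below < self.similar_upto:
            raise ValueError("thresholds must be increasing and positive")


def polyA_classify(
    cov_total: float,
    cov_polyA_scaled: float,
    thresholds: PolyAThresholds = PolyAThresholds(),
    eps: float = 1e-9,
) -> str:
    """Classify Poly(A)-library expression relative to the total library."""
    if cov_total < 0 or cov_polyA_scaled < 0:
        raise ValueError("coverage must be non-negative")
    r = cov_polyA_scaled / max(cov_total, eps)
    if r < thresholds.absent_below:
        return "absent"
    if r < thresholds.half_below:
        return "half"
    if r <= thresholds.similar_upto:
        return "similar"
    return "abundant"


def annotate_structure_and_haca(
    items: Sequence[TranscriptRecord],
    scores: ExternalScores,
) -> List[TranscriptRecord]:
    """Set structure-locus overlap and the H/ACA annotation per transcript.

    Structure overlap is any-overlap (>= 1 bp) with the conserved-structure
    loci. When several H/ACA predictions exist for one transcript, the one
    furthest towards the transcript 3' end (largest end coordinate) is
    chosen — the motif marks the 3' terminus of H/ACA-class RNAs, and the
    predictor itself carries no positional bias.
    """
    trees = _interval_trees(scores.structure_loci, stranded=False)
    for item in items:
        item.has_structure_locus = _tree_overlaps(trees, item.interval, stranded=False)
        hits = scores.haca_predictions.get(item.id, [])
        item.haca = max(hits, key=lambda h: (h[1], h[2])) if hits else None
    return list(items)


# ---------------------------------------------------------------------------
# Scoring and ranking


@dataclass(frozen=True)
class ScoreConfig:
    """Soft criteria counted by the rule-based candidate score.

    ``near5p_max`` is the largest 1-based template start still counted as
    "near the 5' end"; known TRs place the template close to the 5'
    terminus, but no sharp number is established — 200 nt is this
    package's default.
    """

    near5p_max: int = 200
    min_tr_len: int = 200
    max_tr_len: int = 500


CRITERIA = (
    "single_template",
    "template_near_5p",
    "length_in_range",
    "polyA_absent",
    "structure_locus",
    "haca",
)


@dataclass
class CandidateReport:
    """Ranked per-candidate feature table.

    ``table`` is indexed by transcript id with the genomic location
    rendered 1-based inclusive, the observed template motif and its
    1-based transcript position, coverage, Poly(A) class, the boolean
    evidence columns, the criteria count and the rank (ties broken by
    descending total coverage, then id).
    """

    table: pd.DataFrame
    excluded_multi_template: List[str] = field(default_factory=list)

    @property
    def top_candidate(self) -> str:
        return self.table.index[0]

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, sep="\t", index_label="ID")


def score_candidates(
    items: Sequence[TranscriptRecord],
    config: ScoreConfig = ScoreConfig(),
) -> CandidateReport:
    """Score and rank single-template candidates by TR-like properties.

    Each candidate scores one point per satisfied criterion: a single
    template site, template start within ``near5p_max`` of the 5' end,
    length within the typical TR range, absence from the Poly(A) library,
    overlap with a conserved-structure locus, and an H/ACA prediction.
    Multi-template transcripts are excluded from ranking and listed
    separately.
    """
    excluded = [i.id for i in items if FLAG_MULTI_TEMPLATE in i.flags]
    eligible = [i for i in items if FLAG_MULTI_TEMPLATE not in i.flags]

    rows = []
    for item in eligible:
        sites = item.valid_template_sites
        if len(sites) != 1:
            raise ValueError(
                f"transcript {item.id!r} must carry exactly one valid template "
                "site at the ranking stage"
            )
        site = sites[0]
        crit = {
            "single_template": True,
            "template_near_5p": site.start_1based <= config.near5p_max,
            "length_in_range": config.min_tr_len <= item.length <= config.max_tr_len,
            "polyA_absent": item.polyA_class == "absent",
            "structure_locus": item.has_structure_locus,
            "haca": item.has_haca,
        }
        rows.append(
            {
                "ID": item.id,
                "Chrom": item.interval.chrom,
                "Start": item.interval.start + 1,
                "End": item.interval.end,
                "Strand": item.interval.strand,
                "Length": item.length,
                "Motif": site.motif,
                "Pos": site.start_1based,
                "Cov": item.coverage_total,
                "PolyA": item.polyA_class,
                "Structure": item.has_structure_locus,
                "HACA": item.has_haca,
                **crit,
                "Score": sum(crit.values()),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(
            ["Score", "Cov", "ID"], ascending=[False, False, True]
        ).set_index("ID")
        frame["Rank"] = range(1, len(frame) + 1)
    else:
        frame = frame.reindex(columns=["Score", "Rank"])
    return CandidateReport(table=frame, excluded_multi_template=sorted(excluded))


# ---------------------------------------------------------------------------
# Recall evaluation


def compute_recall(
    annotated: Sequence[Tuple[GenomicInterval, str]],
    predictions: Sequence[GenomicInterval],
    min_frac: float,
) -> pd.DataFrame:
    """Per-family recall of annotated genes by a prediction set.

    A gene counts as recalled when at least ``min_frac`` of its length is
    covered by the *union* of overlapping predictions (strand-agnostic).
    Returns a table with one row per family plus a ``Total`` row, columns
    ``n_genes``, ``n_recalled`` and ``recall_pct``.
    """
    if not 0.0 < min_frac <= 1.0:
        raise ValueError("min_frac must lie in (0, 1]")
    trees = _interval_trees(predictions, stranded=False)

    def covered_fraction(gene: GenomicInterval) -> float:
        key = (gene.chrom, ".")
        if key not in trees:
            return 0.0
        segments = sorted(
            (max(iv.begin, gene.start), min(iv.end, gene.end))
            for iv in trees[key].overlap(gene.start, gene.end)
        )
        covered = 0
        cursor = gene.start
        for s, e in segments:
            s = max(s, cursor)
            if e > s:
                covered += e - s
                cursor = e
        return covered / gene.length

    per_family: Dict[str, List[bool]] = {}
    for gene, family in annotated:
        per_family.setdefault(family, []).append(covered_fraction(gene) >= min_frac)

    rows = []
    for family in sorted(per_family):
        hits = per_family[family]
        rows.append(
            {
                "family": family,
                "n_genes": len(hits),
                "n_recalled": sum(hits),
                "recall_pct": 100.0 * sum(hits) / len(hits),
            }
        )
    all_hits = [h for hits in per_family.values() for h in hits]
    rows.append(
        {
            "family": "Total",
            "n_genes": len(all_hits),
            "n_recalled": sum(all_hits),
            "recall_pct": 100.0 * sum(all_hits) / len(all_hits) if all_hits else 0.0,
        }
    )
    return pd.DataFrame(rows).set_index("family")


# ---------------------------------------------------------------------------
# The composed cascade


@dataclass
class CascadeResult:
    """Outcome of the full filter cascade.

    ``stage_counts`` logs survivors after each stage (mirroring the
    narrative shape of a genome-scale screen); ``removal_stage`` maps each
    removed transcript id to the stage that removed it.
    """

    stage_counts: List[Tuple[str, int]]
    removal_stage: Dict[str, str]
    survivors: List[TranscriptRecord]
    report: CandidateReport

    def fate_of(self, transcript_id: str) -> str:
        if transcript_id in self.removal_stage:
            return self.removal_stage[transcript_id]
        if transcript_id in self.report.excluded_multi_template:
            return FLAG_MULTI_TEMPLATE
        return FATE_RANKED


def run_cascade(
    transcripts: Sequence[TranscriptRecord],
    annotation: AnnotationSet,
    external: ExternalScores,
    track_total: CoverageTrack,
    track_polyA: Optional[CoverageTrack],
    genome: Mapping[str, NucleotideSequence],
    *,
    coverage_threshold: float = 10.0,
    max_len: int = 1000,
    scan_params: TemplateScanParams = TemplateScanParams(),
    score_config: ScoreConfig = ScoreConfig(),
    polyA_thresholds: PolyAThresholds = PolyAThresholds(),
    polyA_scale: float = 1.0,
    stranded_overlap: bool = False,
) -> CascadeResult:
    """Run the full candidate cascade and rank the survivors."""
    items = attach_coverage(list(transcripts), track_total, track_polyA, polyA_scale)
    removal: Dict[str, str] = {}
    counts: List[Tuple[str, int]] = [("input", len(items))]

    def advance(stage: str, survivors: List[TranscriptRecord]) -> List[TranscriptRecord]:
        nonlocal items
        surviving_ids = {s.id for s in survivors}
        for item in items:
            if item.id not in surviving_ids:
                removal[item.id] = stage
        counts.append((stage, len(survivors)))
        items = survivors
        return survivors

    advance(STAGE_COVERAGE, min_coverage_filter(items, coverage_threshold))
    advance(STAGE_REDUNDANCY, redundancy_filter(items))
    advance(STAGE_OVERLAP, overlap_filter(items, annotation, stranded=stranded_overlap))
    advance(STAGE_CODING, coding_filter(items, external))
    advance(STAGE_LENGTH, length_filter(items, max_len))
    sequences = extract_transcript_sequences(genome, items)
    advance(STAGE_TEMPLATE, scan_and_flag_templates(items, scan_params, sequences))
    single = [i for i in items if FLAG_MULTI_TEMPLATE not in i.flags]
    counts.append(("single_template", len(single)))

    for item in items:
        if item.coverage_polyA is not None and item.coverage_total is not None:
            item.polyA_class = polyA_classify(
                item.coverage_total, item.coverage_polyA, polyA_thresholds
            )
    annotate_structure_and_haca(items, external)
    report = score_candidates(items, score_config)
    return CascadeResult(
        stage_counts=counts,
        removal_stage=removal,
        survivors=items,
        report=report,
    )


# ---------------------------------------------------------------------------
# Readers


def read_bed_intervals(path: Union[str, Path]) -> List[GenomicInterval]:
    """Read BED (>= 3 columns) into intervals; strand from column 6 if present."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def read_bed_transcripts(path: Union[str, Path]) -> List[TranscriptRecord]:
    """Read BED6 transcripts (name column = transcript id)."""
    out: List[TranscriptRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError("transcript BED requires at least 4 columns")
            strand = parts[5] if len(parts) >= 6 else "."
            out.append(
                TranscriptRecord(
                    interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand),
                    id=parts[3],
                )
            )
    return out


def read_gtf_annotation(
    path: Union[str, Path],
    ncrna_families: Sequence[str] = NCRNA_FAMILIES[:-1],
) -> AnnotationSet:
    """Extract CDS and ncRNA annotation from a GTF/GFF file.

    Tolerates both the ``gene_biotype`` and ``gbkey`` attribute dialects
    for identifying ncRNA families.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    cds: List[GenomicInterval] = []
    ncrna: List[Tuple[GenomicInterval, str]] = []
    for feat in db.all_features():
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        if feat.featuretype == "CDS" or "CDS" in feat.attributes.get("gbkey", []):
            cds.append(iv)
            continue
        family = None
        for key in ("gene_biotype", "gbkey", "biotype"):
            for val in feat.attributes.get(key, []):
                if val in ncrna_families:
                    family = val
        if family is not None:
            ncrna.append((iv, family))
    return AnnotationSet(cds=cds, ncrna=ncrna)


def read_coding_scores(path: Union[str, Path]) -> Dict[str, Tuple[float, float]]:
    """TSV with columns transcript_id, score_a, score_b."""
    table = pd.read_csv(path, sep="\t")
    return {
        str(r.transcript_id): (float(r.score_a), float(r.score_b))
        for r in table.itertuples(index=False)
    }


def read_haca_predictions(path: Union[str, Path]) -> Dict[str, List[Tuple[int, int, float]]]:
    """TSV with columns sequence_id, start, end, confidence."""
    table = pd.read_csv(path, sep="\t")
    out: Dict[str, List[Tuple[int, int, float]]] = {}
    for r in table.itertuples(index=False):
        out.setdefault(str(r.sequence_id), []).append(
            (int(r.start), int(r.end), float(r.confidence))
        )
    return out
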