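"""Intron-anchored annotation of telomerase-RNA homologs across species.

Fast-evolving ncRNAs such as TR cannot be found by sequence homology
search once species diverge; a conserved *syntenic anchor* can. Here the
anchor is an intron of a conserved host gene (in *Caenorhabditis*, intron
2 of *nmy-2*): for each species the orthologous intron is extracted from
the gene model, scanned for a telomere-template region with the same
scanner used for transcript candidates, and annotated with offsets,
candidate windows, H/ACA predictions and a presence/absence feature
matrix suitable for plotting next to a species tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .candidate_pipeline import GenomicInterval
from .seqcore import (
    NucleotideSequence,
    TemplateScanParams,
    TemplateSite,
    find_template_sites,
    is_telomeric_substring,
    reverse_complement,
)

__all__ = [
    "GeneModel",
    "IntronRecord",
    "TRWindow",
    "ConsensusMotif",
    "extract_intron",
    "select_orthologous_intron",
    "intron_template_scan",
    "annotate_intron_haca",
    "extract_tr_window",
    "consensus_motif",
    "build_feature_matrix",
    "read_gene_models_gff3",
]


@dataclass(frozen=True)
class GeneModel:
    """A host-gene model: ordered exons on one chromosome and strand.

    ``exons`` are genomic (chrom-forward) half-open intervals sorted by
    start; transcription order is derived from the strand.
    """

    species: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("gene model strand must be + or -")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be sorted and non-overlapping")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"invalid exon [{s}, {e})")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exons_tx_order(self) -> Tuple[Tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def n_introns(self) -> int:
        return max(0, len(self.exons) - 1)


@dataclass(frozen=True)
class IntronRecord:
    """An anchored host-gene intron with template/H/ACA annotation.

    ``ordinal`` is 0-based in transcription order (ordinal 0 = intron 1).
    ``template_site`` coordinates, ``offset5`` (template start minus
    intron 5' end) and ``offset3`` (intron 3' end minus template end) are
    on the *transcribed* strand of the intron. A zero-length interval
    marks an absent intron (abutting exons).
    """

    species: str
    ordinal: int
    chrom: str
    strand: str
    start: int
    end: int
    template_site: Optional[TemplateSite] = None
    haca: Optional[Tuple[int, int, float]] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("intron start must be <= end")
        if self.template_site is not None and not self.present:
            raise ValueError("template site on an absent intron")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def present(self) -> bool:
        return self.length > 0

    @property
    def offset5(self) -> Optional[int]:
        return None if self.template_site is None else self.template_site.start

    @property
    def offset3(self) -> Optional[int]:
        return None if self.template_site is None else self.length - self.template_site.end

    @property
    def interval(self) -> Optional[GenomicInterval]:
        if not self.present:
            return None
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def template_site_genomic(self) -> Optional[GenomicInterval]:
        """Template-site coordinates lifted back to the forward genome."""
        site = self.template_site
        if site is None:
            return None
        if self.strand == "+":
            return GenomicInterval(self.chrom, self.start + site.start, self.start + site.end, "+")
        return GenomicInterval(self.chrom, self.end - site.end, self.end - site.start, "-")


def extract_intron(model: GeneModel, ordinal: int) -> IntronRecord:
    """Intron ``ordinal`` (0-based, transcription order) of a gene model.

    On '-' strand models the transcription order runs against genomic
    coordinates, so intron i lies between the (i+1)-th and (i+2)-th exon
    counted from the genomic right. Abutting exons yield a zero-length,
    absent intron record.
    """
    if ordinal < 0 or ordinal + 1 >= model.n_exons:
        raise IndexError(
            f"gene {model.gene_id!r} has {model.n_introns} introns; "
            f"ordinal {ordinal} out of range"
        )
    up = model.exons_tx_order[ordinal]
    down = model.exons_tx_order[ordinal + 1]
    if model.strand == "+":
        start, end = up[1], down[0]
    else:
        start, end = down[1], up[0]
    return IntronRecord(
        species=model.species,
        ordinal=ordinal,
        chrom=model.chrom,
        strand=model.strand,
        start=start,
        end=end,
    )


def select_orthologous_intron(
    model: GeneModel, ref_flank_lengths: Tuple[int, int]
) -> int:
    """Pick the intron whose flanking exon lengths best match a reference.

    Host-gene exon/intron structure drifts between species, so the intron
    *number* of the orthologous intron may differ; the flanking exon
    lengths are a robust proxy. Returns the 0-based ordinal minimizing
    the summed absolute difference to ``ref_flank_lengths`` (upstream
    exon, downstream exon), ties to the smallest ordinal.
    """
    if model.n_introns == 0:
        raise ValueError(f"gene {model.gene_id!r} has no introns")
    ref_up, ref_down = ref_flank_lengths
    best, best_cost = 0, None
    for ordinal in range(model.n_introns):
        up = model.exons_tx_order[ordinal]
        down = model.exons_tx_order[ordinal + 1]
        cost = abs((up[1] - up[0]) - ref_up) + abs((down[1] - down[0]) - ref_down)
        if best_cost is None or cost < best_cost:
            best, best_cost = ordinal, cost
    return best


def _intron_sequence(intron: IntronRecord, genome: Mapping[str, NucleotideSequence]) -> str:
    if intron.chrom not in genome:
        raise KeyError(f"chromosome {intron.chrom!r} absent from genome for {intron.species}")
    sub = genome[intron.chrom].residues[intron.start : intron.end]
    return reverse_complement(sub) if intron.strand == "-" else sub


def intron_template_scan(
    intron: IntronRecord,
    genome: Mapping[str, NucleotideSequence],
    params: TemplateScanParams = TemplateScanParams(),
) -> IntronRecord:
    """Scan the transcribed strand of the intron for a template region.

    Attaches the single best valid site (longest, ties broken towards the
    5' end); introns report one template at most. Absent or template-free
    introns are returned unchanged.
    """
    if not intron.present:
        return intron
    seq = NucleotideSequence(f"{intron.species}|intron{intron.ordinal + 1}", _intron_sequence(intron, genome))
    valid = [s for s in find_template_sites(seq, params) if not s.overlong]
    if not valid:
        return replace(intron, template_site=None)
    best = max(valid, key=lambda s: (len(s.motif), -s.start))
    return replace(intron, template_site=best)


def annotate_intron_haca(
    intron: IntronRecord, predictions: Sequence[Tuple[int, int, float]]
) -> IntronRecord:
    """Attach the H/ACA prediction furthest towards the intron 3' end."""
    if not predictions:
        return replace(intron, haca=None)
    best = max(predictions, key=lambda h: (h[1], h[2]))
    return replace(intron, haca=best)


@dataclass(frozen=True)
class TRWindow:
    """A template-anchored candidate window on the transcribed strand.

    Spans ``upstream`` nt before and ``downstream`` nt after the template
    region, clipped at intron boundaries (truncation flags record any
    clipping). ``template_offset`` is the template start within the
    window, i.e. the effective upstream length.
    """

    species: str
    sequence: NucleotideSequence
    template_offset: int
    motif: str
    truncated_5p: bool = False
    truncated_3p: bool = False

    def __post_init__(self) -> None:
        got = self.sequence.residues[self.template_offset : self.template_offset + len(self.motif)]
        if got != self.motif:
            raise ValueError("window does not contain the template motif at its offset")


def extract_tr_window(
    intron: IntronRecord,
    genome: Mapping[str, NucleotideSequence],
    upstream: int = 70,
    downstream: int = 350,
    *,
    clip_to_intron: bool = True,
) -> TRWindow:
    """Extract the TR candidate window around the intron's template site.

    Defaults (70 nt upstream, 350 nt downstream) reflect the typical
    placement of the template close to the TR 5' end with the bulk of the
    molecule downstream. Windows are clipped at the intron boundaries —
    an intron-hosted TR cannot extend into the flanking exons — unless
    ``clip_to_intron=False``, which extends into the surrounding pre-mRNA.
    """
    site = intron.template_site
    if site is None:
        raise ValueError(f"intron of {intron.species} carries no template site")
    seq = _intron_sequence(intron, genome)
    n = len(seq)
    want_start = site.start - upstream
    want_end = site.end + downstream

    if clip_to_intron:
        actual_start = max(0, want_start)
        actual_end = min(n, want_end)
        window = seq[actual_start:actual_end]
        truncated_5p = want_start < 0
        truncated_3p = want_end > n
    else:
        # Extend into the surrounding pre-mRNA; clip only at chromosome ends.
        chrom_len = len(genome[intron.chrom].residues)
        if intron.strand == "+":
            lo = -intron.start  # transcribed coordinate of chromosome start
            hi = chrom_len - intron.start
        else:
            lo = intron.end - chrom_len
            hi = intron.end
        actual_start = max(lo, want_start)
        actual_end = min(hi, want_end)
        truncated_5p = want_start < lo
        truncated_3p = want_end > hi
        chrom_seq = genome[intron.chrom].residues
        if intron.strand == "+":
            window = chrom_seq[intron.start + actual_start : intron.start + actual_end]
        else:
            window = reverse_complement(
                chrom_seq[intron.end - actual_end : intron.end - actual_start]
            )
    effective_upstream = site.start - actual_start
    return TRWindow(
        species=intron.species,
        sequence=NucleotideSequence(
            f"{intron.species}|intron{intron.ordinal + 1}|offset{site.start}", window
        ),
        template_offset=effective_upstream,
        motif=site.motif,
        truncated_5p=truncated_5p,
        truncated_3p=truncated_3p,
    )


# ---------------------------------------------------------------------------
# Consensus motif


@dataclass(frozen=True)
class ConsensusMotif:
    """Phase-aligned consensus of per-species template motifs.

    ``consensus`` collects the contiguous positions supported by a strict
    majority of species; ``core`` the contiguous positions supported by
    all species up to the allowed number of exceptions. ``support`` maps
    column index (on the chosen rotation of the template language) to the
    number of species covering it; ``offsets`` gives each species' start
    column.
    """

    consensus: str
    core: str
    rotation: str
    support: Dict[int, int]
    offsets: Dict[str, int]


def _phase_of(motif: str, repeat: str) -> int:
    pos = (repeat * (len(motif) // len(repeat) + 2)).find(motif)
    if pos < 0:
        raise ValueError(f"motif {motif!r} is not in the cyclic template language")
    return pos % len(repeat)


def _best_contiguous(columns: Sequence[int]) -> Tuple[int, int]:
    """Longest contiguous run among sorted column indices (leftmost on tie)."""
    best = (0, 0)
    run_start = None
    prev = None
    for c in columns:
        if prev is None or c != prev + 1:
            run_start = c
        prev = c
        if c - run_start + 1 > best[1] - best[0]:
            best = (run_start, c + 1)
    return best


def consensus_motif(
    templates: Mapping[str, str],
    unit_repeat: Optional[str] = None,
    *,
    allowed_exceptions: int = 2,
) -> ConsensusMotif:
    """Phase-align per-species template motifs and summarize them.

    Every motif is a member of the cyclic template language and therefore
    has a unique phase on the repeated reverse complement of the telomere
    unit; alignment is gap-free phase matching. Among the possible
    rotations of the repeat, the one maximizing column agreement (sum of
    squared per-column support) is chosen, so shared cores stack.

    ``consensus`` keeps positions supported by > 50% of species; ``core``
    keeps positions supported by all species minus ``allowed_exceptions``
    (default 2 — template cores are near-universal, with rare drop-outs).
    """
    if len(templates) < 2:
        raise ValueError("consensus requires motifs from at least two species")
    if unit_repeat is None:
        from .seqcore import TelomereUnit

        unit_repeat = TelomereUnit().template_repeat
    k = len(unit_repeat)
    phases = {sp: _phase_of(m, unit_repeat) for sp, m in templates.items()}

    def stack_for(rot: int) -> Tuple[Dict[str, int], Dict[int, int]]:
        offsets = {sp: (phases[sp] - rot) % k for sp in templates}
        support: Dict[int, int] = {}
        for sp, off in offsets.items():
            for c in range(off, off + len(templates[sp])):
                support[c] = support.get(c, 0) + 1
        return offsets, support

    best_rot, best_obj = 0, None
    for rot in range(k):
        _, support = stack_for(rot)
        obj = sum(v * v for v in support.values())
        if best_obj is None or obj > best_obj:
            best_rot, best_obj = rot, obj
    offsets, support = stack_for(best_rot)
    rotation = unit_repeat[best_rot:] + unit_repeat[:best_rot]

    def column_char(c: int) -> str:
        return rotation[c % k]

    n = len(templates)
    majority_cols = sorted(c for c, v in support.items() if v > n / 2)
    core_cols = sorted(c for c, v in support.items() if v >= n - allowed_exceptions)
    cons_span = _best_contiguous(majority_cols) if majority_cols else (0, 0)
    core_span = _best_contiguous(core_cols) if core_cols else (0, 0)
    return ConsensusMotif(
        consensus="".join(column_char(c) for c in range(*cons_span)),
        core="".join(column_char(c) for c in range(*core_span)),
        rotation=rotation,
        support=support,
        offsets=offsets,
    )


# ---------------------------------------------------------------------------
# Feature matrix and I/O


def build_feature_matrix(introns: Sequence[IntronRecord]) -> pd.DataFrame:
    """Per-species presence/absence table for tree annotation.

    One row per species: intron presence and length, the template motif
    (pd.NA when absent) and H/ACA presence. Suitable for export as TSV
    next to a phylogeny. Duplicate species raise an error.
    """
    seen = set()
    rows = []
    for rec in introns:
        if rec.species in seen:
            raise ValueError(f"duplicate species {rec.species!r}")
        seen.add(rec.species)
        rows.append(
            {
                "species": rec.species,
                "intron_present": rec.present,
                "intron_length": rec.length if rec.present else pd.NA,
                "template": rec.template_site.motif if rec.template_site else pd.NA,
                "template_present": rec.template_site is not None,
                "haca_present": rec.haca is not None,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def read_gene_models_gff3(
    path: Union[str, Path], species: str
) -> List[GeneModel]:
    """Read gene models (exon features grouped by gene) from GFF3.

    Expects the shape written by exon-centric protein-to-genome aligners:
    exon features carrying a Parent or gene_id attribute.
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
    grouped: Dict[Tuple[str, str, str], List[Tuple[int, int]]] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent", []) or feat.attributes.get("gene_id", [])
        gene = parents[0] if parents else feat.id
        grouped.setdefault((gene, feat.seqid, feat.strand), []).append(
            (feat.start - 1, feat.end)
        )
    models = []
    for (gene, chrom, strand), exons in sorted(grouped.items()):
        models.append(
            GeneModel(
                species=species,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons)),
            )
        )
    return models
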