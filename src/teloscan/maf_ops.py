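"""Post-processing of whole-genome alignments in MAF format.

Progressive whole-genome aligners emit highly fragmented alignments: many
short blocks, often dominated by gap characters. Two operations restore
usable, cohesive alignments for downstream comparative screens:

* ``ungap_filter`` removes blocks whose overall gap fraction exceeds a
  threshold (default 0.9).
* ``merge_pass`` greedily merges consecutive blocks that share most of
  their species (default 75% Jaccard consensus) and whose per-species
  coordinates continue within a small distance (default 5 nt). Species
  present in only one of the two blocks are dropped, producing a
  consensus species set per merged block.

The reader/writer here preserves the exact ``##maf`` field layout so that
filtered files round-trip byte-identically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .seqcore import NucleotideSequence, reverse_complement

__all__ = [
    "MafSequenceLine",
    "MafBlock",
    "UngapParams",
    "MergeParams",
    "read_maf",
    "write_maf",
    "gap_fraction",
    "ungap_filter",
    "drop_gappy_lines",
    "blocks_adjacent",
    "merge_blocks",
    "merge_pass",
    "fragmentation_stats",
]

GAP = "-"


@dataclass(frozen=True)
class MafSequenceLine:
    """One 's' line of a MAF block.

    ``start`` is 0-based on the given strand (for '-', counted from the
    reverse-strand origin, as MAF specifies); ``size`` is the ungapped
    length; ``src_size`` the full source-sequence length.
    """

    source: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ungapped = len(self.text) - self.text.count(GAP)
        if ungapped != self.size:
            raise ValueError(
                f"{self.source}: size field ({self.size}) does not match "
                f"non-gap character count ({ungapped})"
            )
        if self.start + self.size > self.src_size:
            raise ValueError(f"{self.source}: start + size exceeds src_size")

    @property
    def species(self) -> str:
        """Assembly part of ``assembly.chromosome``."""
        return self.source.split(".", 1)[0]

    @property
    def end(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class MafBlock:
    """One alignment block: equally wide stranded sequence lines."""

    lines: Tuple[MafSequenceLine, ...]
    score: Optional[float] = None
    score_is_synthetic: bool = False

    def __post_init__(self) -> None:
        if not self.lines:
            raise ValueError("MAF block must contain at least one sequence line")
        object.__setattr__(self, "lines", tuple(self.lines))
        width = len(self.lines[0].text)
        if any(len(ln.text) != width for ln in self.lines):
            raise ValueError("all lines in a block must share the alignment width")
        species = [ln.species for ln in self.lines]
        if len(set(species)) != len(species):
            raise ValueError("at most one line per source assembly in a block")

    @property
    def width(self) -> int:
        return len(self.lines[0].text)

    @property
    def species(self) -> Tuple[str, ...]:
        return tuple(ln.species for ln in self.lines)

    @property
    def reference(self) -> MafSequenceLine:
        """Reference line = first line of the block (aligner convention)."""
        return self.lines[0]

    def line_for(self, species: str) -> MafSequenceLine:
        for ln in self.lines:
            if ln.species == species:
                return ln
        raise KeyError(species)


@dataclass(frozen=True)
class UngapParams:
    max_gap_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MergeParams:
    min_species_consensus: float = 0.75
    max_coordinate_distance: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.min_species_consensus <= 1.0:
            raise ValueError("min_species_consensus must lie in (0, 1]")
        if self.max_coordinate_distance < 0:
            raise ValueError("max_coordinate_distance must be >= 0")


# ---------------------------------------------------------------------------
# I/O


def read_maf(source: Union[str, Path, io.TextIOBase]) -> List[MafBlock]:
    """Parse a MAF file into blocks, in file order.

    'i', 'e' and 'q' lines are skipped; malformed lines raise a
    ``ValueError`` naming the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_maf(fh)

    blocks: List[MafBlock] = []
    lines: List[MafSequenceLine] = []
    score: Optional[float] = None
    in_block = False

    def flush() -> None:
        nonlocal lines, score, in_block
        if in_block:
            if not lines:
                raise ValueError("alignment block without sequence lines")
            blocks.append(MafBlock(lines=tuple(lines), score=score))
        lines, score, in_block = [], None, False

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            continue
        kind = line.split(None, 1)[0]
        if kind == "a":
            flush()
            in_block = True
            score = None
            for tok in line.split()[1:]:
                if tok.startswith("score="):
                    try:
                        score = float(tok[len("score=") :])
                    except ValueError as exc:
                        raise ValueError(f"line {lineno}: bad score field") from exc
        elif kind == "s":
            if not in_block:
                raise ValueError(f"line {lineno}: 's' line outside an 'a' block")
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"line {lineno}: expected 7 fields on 's' line")
            try:
                lines.append(
                    MafSequenceLine(
                        source=parts[1],
                        start=int(parts[2]),
                        size=int(parts[3]),
                        strand=parts[4],
                        src_size=int(parts[5]),
                        text=parts[6],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
        elif kind in ("i", "e", "q"):
            continue  # per-line metadata; not needed downstream
        else:
            raise ValueError(f"line {lineno}: unknown MAF line type {kind!r}")
    flush()
    return blocks


def write_maf(blocks: Iterable[MafBlock], dest: Union[str, Path, io.TextIOBase]) -> None:
    """Write blocks under a ``##maf version=1`` header."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_maf(blocks, fh)
        return
    dest.write("##maf version=1\n")
    for block in blocks:
        if block.score is None:
            dest.write("\na\n")
        else:
            dest.write(f"\na score={block.score:g}\n")
        for ln in block.lines:
            dest.write(
                f"s {ln.source} {ln.start} {ln.size} {ln.strand} "
                f"{ln.src_size} {ln.text}\n"
            )


# ---------------------------------------------------------------------------
# Gap filtering


def gap_fraction(block: MafBlock) -> float:
    """Fraction of gap characters over the whole block matrix."""
    total = len(block.lines) * block.width
    gaps = sum(ln.text.count(GAP) for ln in block.lines)
    return gaps / total


def ungap_filter(blocks: Sequence[MafBlock], params: UngapParams = UngapParams()) -> List[MafBlock]:
    """Remove blocks whose overall gap fraction exceeds the threshold.

    Order-preserving and idempotent. This is the block-matrix reading of
    the gap threshold; see ``drop_gappy_lines`` for the per-line variant.
    """
    return [b for b in blocks if gap_fraction(b) <= params.max_gap_fraction]


def drop_gappy_lines(
    blocks: Sequence[MafBlock], max_line_gap_fraction: float = 0.9
) -> List[MafBlock]:
    """Alternative mode: drop individual lines that are mostly gaps.

    Blocks left without any line are removed entirely. All-gap columns
    that may result are retained (no re-projection of coordinates).
    """
    out: List[MafBlock] = []
    for b in blocks:
        kept = tuple(
            ln for ln in b.lines if ln.text.count(GAP) / len(ln.text) <= max_line_gap_fraction
        )
        if kept:
            out.append(MafBlock(lines=kept, score=b.score, score_is_synthetic=b.score_is_synthetic))
    return out


# ---------------------------------------------------------------------------
# Block merging


def blocks_adjacent(a: MafBlock, b: MafBlock, params: MergeParams = MergeParams()) -> bool:
    """True when ``b`` can be merged onto the end of ``a``.

    Requires (i) Jaccard species overlap >= the consensus threshold and
    (ii) for every shared species: same source and strand, with the
    coordinate gap between the end of its segment in ``a`` and its start
    in ``b`` within [0, max_coordinate_distance].
    """
    sa = {ln.species: ln for ln in a.lines}
    sb = {ln.species: ln for ln in b.lines}
    shared = set(sa) & set(sb)
    union = set(sa) | set(sb)
    if not shared:
        return False
    if len(shared) / len(union) < params.min_species_consensus:
        return False
    for sp in shared:
        la, lb = sa[sp], sb[sp]
        if la.source != lb.source or la.strand != lb.strand:
            return False
        gap = lb.start - la.end
        if gap < 0 or gap > params.max_coordinate_distance:
            return False
    return True


GenomeMap = Mapping[str, Union[str, NucleotideSequence]]


def _fetch_interval(seq: Union[str, NucleotideSequence], start: int, end: int, strand: str, src_size: int) -> str:
    """Fetch [start, end) given in strand coordinates from a forward sequence."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if len(residues) != src_size:
        raise ValueError("genome sequence length does not match src_size field")
    if strand == "+":
        return residues[start:end]
    fwd_start = src_size - end
    fwd_end = src_size - start
    return reverse_complement(residues[fwd_start:fwd_end])


def merge_blocks(
    a: MafBlock,
    b: MafBlock,
    params: MergeParams = MergeParams(),
    genomes: Optional[GenomeMap] = None,
) -> MafBlock:
    """Merge two adjacent blocks into one consensus-species block.

    Species present in only one block are removed. For each shared
    species with a coordinate gap g > 0, g extra columns are inserted
    between the two parts in which only that species carries residues
    (fetched from ``genomes`` keyed by source when provided, otherwise
    'N') and every other species carries gaps. The resulting score is the
    sum of the parts and flagged synthetic.
    """
    if not blocks_adjacent(a, b, params):
        raise ValueError("merge_blocks called on non-adjacent blocks")
    sb = {ln.species: ln for ln in b.lines}
    shared = [ln for ln in a.lines if ln.species in sb]  # preserve a's order

    gaps = {ln.species: sb[ln.species].start - ln.end for ln in shared}
    inserts: Dict[str, str] = {}
    for ln in shared:
        g = gaps[ln.species]
        if g == 0:
            inserts[ln.species] = ""
        elif genomes is not None and ln.source in genomes:
            inserts[ln.species] = _fetch_interval(
                genomes[ln.source], ln.end, ln.end + g, ln.strand, ln.src_size
            )
        else:
            inserts[ln.species] = "N" * g

    # Insert columns species by species, in line order.
    insert_width = sum(len(v) for v in inserts.values())
    merged_lines: List[MafSequenceLine] = []
    for ln in shared:
        lb = sb[ln.species]
        middle_parts: List[str] = []
        for other in shared:
            seg = inserts[other.species]
            middle_parts.append(seg if other.species == ln.species else GAP * len(seg))
        middle = "".join(middle_parts)
        assert len(middle) == insert_width
        merged_lines.append(
            MafSequenceLine(
                source=ln.source,
                start=ln.start,
                size=ln.size + gaps[ln.species] + lb.size,
                strand=ln.strand,
                src_size=ln.src_size,
                text=ln.text + middle + lb.text,
            )
        )
    score = None
    if a.score is not None and b.score is not None:
        score = a.score + b.score
    return MafBlock(lines=tuple(merged_lines), score=score, score_is_synthetic=True)


def merge_pass(
    blocks: Sequence[MafBlock],
    params: MergeParams = MergeParams(),
    genomes: Optional[GenomeMap] = None,
) -> List[MafBlock]:
    """Greedy left-to-right merge over reference-sorted blocks.

    Repeatedly merges the current block with its successor while they are
    adjacent; the block count never increases and every output block is
    either an input block or a merge chain of consecutive inputs.
    """
    blocks = list(blocks)
    for prev, nxt in zip(blocks, blocks[1:]):
        if (
            prev.reference.source == nxt.reference.source
            and prev.reference.strand == nxt.reference.strand
            and nxt.reference.start < prev.reference.start
        ):
            raise ValueError("blocks must be sorted by reference coordinate")
    if not blocks:
        return []
    out: List[MafBlock] = []
    cur = blocks[0]
    for nxt in blocks[1:]:
        if blocks_adjacent(cur, nxt, params):
            cur = merge_blocks(cur, nxt, params, genomes=genomes)
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def fragmentation_stats(blocks: Sequence[MafBlock]) -> Dict[str, float]:
    """Summary of alignment fragmentation (per the reference species lines)."""
    if not blocks:
        return {"n_blocks": 0, "mean_width": 0.0, "reference_span": 0, "blocks_per_mb": 0.0}
    widths = [b.width for b in blocks]
    starts = [b.reference.start for b in blocks]
    ends = [b.reference.end for b in blocks]
    span = max(ends) - min(starts)
    return {
        "n_blocks": len(blocks),
        "mean_width": sum(widths) / len(widths),
        "reference_span": span,
        "blocks_per_mb": len(blocks) / span * 1_000_000 if span else float("inf"),
    }
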