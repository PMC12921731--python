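"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the algorithms used by the package (the
scanner's phase DP, the sweep-based containment filter, the interval
trees) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest

from teloscan.candidate_pipeline import GenomicInterval
from teloscan.maf_ops import MafBlock, MafSequenceLine
from teloscan.seqcore import NucleotideSequence, TemplateScanParams, reverse_complement
from teloscan.synthetic_data import SyntheticScenario, generate_scenario


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic scenario (seed 42), shared across tests."""
    return generate_scenario(SyntheticScenario(), seed=42)


# ---------------------------------------------------------------------------
# Scanner oracle


def oracle_template_sites(
    residues: str, params: TemplateScanParams
) -> List[Tuple[int, int, bool]]:
    """Exhaustive substring oracle for maximal telomere-template runs.

    Membership is tested by literal substring search in the repeated
    reverse complement; runs are grown one residue at a time and
    maximality is decided by explicit containment filtering. Returns
    (start, end, overlong) triples for runs >= min_template_len.
    """
    repeat = reverse_complement(params.unit.unit)
    k = len(repeat)

    def member(m: str) -> bool:
        return m in repeat * (len(m) // k + 2)

    n = len(residues)
    runs = set()
    for i in range(n):
        j = i
        while j < n and member(residues[i : j + 1]):
            j += 1
        if j > i:
            runs.add((i, j))
    maximal = [
        (s, e)
        for (s, e) in runs
        if not any((s2 <= s and e <= e2 and (s2, e2) != (s, e)) for (s2, e2) in runs)
    ]
    return sorted(
        (s, e, (e - s) > params.max_template_len)
        for (s, e) in maximal
        if (e - s) >= params.min_template_len
    )


# ---------------------------------------------------------------------------
# Interval oracles


def oracle_union_covered_fraction(
    gene: GenomicInterval, predictions: List[GenomicInterval]
) -> float:
    """Per-base union coverage of a gene by predictions (boolean mask)."""
    mask = np.zeros(gene.length, dtype=bool)
    for p in predictions:
        if p.chrom != gene.chrom:
            continue
        lo = max(p.start, gene.start) - gene.start
        hi = min(p.end, gene.end) - gene.start
        if hi > lo:
            mask[lo:hi] = True
    return mask.mean()


def oracle_any_overlap(iv: GenomicInterval, others: List[GenomicInterval]) -> bool:
    return any(
        o.chrom == iv.chrom and iv.start < o.end and o.start < iv.end for o in others
    )


# ---------------------------------------------------------------------------
# MAF chain generator for merge/conservation checks


def random_merge_chain(
    rng: np.random.Generator,
    n_blocks: int = 4,
    n_species: int = 4,
    max_gap: int = 5,
) -> Tuple[List[MafBlock], Dict[str, NucleotideSequence]]:
    """A chain of pairwise-adjacent blocks over freshly drawn genomes.

    Every block carries the same species; per-species coordinates advance
    with random inter-block gaps <= max_gap, so the whole chain merges
    into one block whose residues must equal the genomic substrings.
    """
    genomes: Dict[str, NucleotideSequence] = {}
    lengths: Dict[str, int] = {}
    cursors: Dict[str, int] = {}
    species = [f"g{j}" for j in range(n_species)]
    for sp in species:
        n = 2000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        genomes[f"{sp}.c1"] = NucleotideSequence("c1", seq)
        lengths[sp] = n
        cursors[sp] = int(rng.integers(0, 50))

    blocks = []
    for _ in range(n_blocks):
        width = int(rng.integers(20, 60))
        lines = []
        for sp in species:
            n_gaps = int(rng.integers(0, width // 3))
            size = width - n_gaps
            start = cursors[sp]
            segment = genomes[f"{sp}.c1"].residues[start : start + size]
            gap_cols = set(int(g) for g in rng.choice(width, size=n_gaps, replace=False))
            it = iter(segment)
            text = "".join("-" if c in gap_cols else next(it) for c in range(width))
            lines.append(
                MafSequenceLine(
                    source=f"{sp}.c1",
                    start=start,
                    size=size,
                    strand="+",
                    src_size=lengths[sp],
                    text=text,
                )
            )
            cursors[sp] += size
        blocks.append(MafBlock(lines=tuple(lines)))
        for sp in species:
            cursors[sp] += int(rng.integers(0, max_gap + 1))
    return blocks, genomes
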