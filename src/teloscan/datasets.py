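"""Published reference data: the nine template-carrying TR candidates
reported for the *C. elegans* genome screen.

Each record carries the genomic location (1-based inclusive, as printed),
transcript length, the observed template-region motif and its 1-based
start position relative to the candidate 5' end, total-library coverage
(sum of per-base depths), the Poly(A)-library expression class, and
whether a conserved-structure locus and an H/ACA prediction support the
candidate. TR_C2 — experimentally confirmed since as the *C. elegans*
telomerase RNA — is the intron-hosted candidate on the reverse strand of
chromosome I.
"""

from __future__ import annotations

from typing import Dict, List

from .candidate_pipeline import GenomicInterval, TranscriptRecord
from .seqcore import TemplateSite, TelomereUnit

__all__ = [
    "CELEGANS_TR_CANDIDATES",
    "CELEGANS_TELOMERE_UNIT",
    "CELEGANS_CONSENSUS_TEMPLATE",
    "CELEGANS_TEMPLATE_CORE",
    "celegans_candidate_records",
]

CELEGANS_TELOMERE_UNIT = TelomereUnit("TTAGGC")

# Cross-species template consensus reported for Caenorhabditis and its
# near-universal core.
CELEGANS_CONSENSUS_TEMPLATE = "TAAGCCTAAGC"
CELEGANS_TEMPLATE_CORE = "TAAGCCT"

# Columns: id, chrom, start (1-based), end (inclusive), strand, length,
# motif, pos (1-based template start in transcript), coverage, polyA
# class, structure locus, H/ACA prediction.
CELEGANS_TR_CANDIDATES: List[Dict] = [
    dict(id="TR_C1", chrom="chrI", start=2_700_026, end=2_700_251, strand="+",
         length=226, motif="AAGCCTAAGCC", pos=127, cov=10, polyA="similar",
         structure=False, haca=True),
    dict(id="TR_C2", chrom="chrI", start=7_933_766, end=7_934_092, strand="-",
         length=327, motif="TAAGCCTAAG", pos=29, cov=818, polyA="absent",
         structure=True, haca=True),
    dict(id="TR_C3", chrom="chrI", start=12_084_754, end=12_085_008, strand="-",
         length=255, motif="CCTAAGCC", pos=185, cov=10, polyA="abundant",
         structure=False, haca=False),
    dict(id="TR_C4", chrom="chrII", start=7_392_341, end=7_392_646, strand="+",
         length=306, motif="AGCCTAAGC", pos=288, cov=11, polyA="similar",
         structure=False, haca=False),
    dict(id="TR_C5", chrom="chrIII", start=698_155, end=698_470, strand="+",
         length=316, motif="AGCCTAAG", pos=84, cov=13, polyA="similar",
         structure=False, haca=True),
    dict(id="TR_C6", chrom="chrIII", start=11_609_100, end=11_609_499, strand="-",
         length=400, motif="CTAAGCCT", pos=289, cov=55, polyA="absent",
         structure=False, haca=True),
    dict(id="TR_C7", chrom="chrIII", start=12_868_600, end=12_869_526, strand="-",
         length=927, motif="CTAAGCCT", pos=541, cov=13, polyA="similar",
         structure=False, haca=False),
    dict(id="TR_C8", chrom="chrV", start=11_606_871, end=11_607_858, strand="+",
         length=988, motif="GCCTAAGC", pos=923, cov=23, polyA="half",
         structure=False, haca=True),
    dict(id="TR_C9", chrom="chrX", start=16_432_746, end=16_433_073, strand="-",
         length=328, motif="CTAAGCCTAA", pos=269, cov=51, polyA="half",
         structure=False, haca=False),
]


def celegans_candidate_records() -> List[TranscriptRecord]:
    """The published candidate feature table as TranscriptRecord objects.

    Printed 1-based inclusive coordinates are converted to the internal
    0-based half-open convention, and each candidate's printed motif and
    transcript position become its (single) template site, so the records
    can be fed directly into the scoring/ranking stage.
    """
    records = []
    for row in CELEGANS_TR_CANDIDATES:
        site_start = row["pos"] - 1
        site = TemplateSite(
            sequence_id=row["id"],
            start=site_start,
            end=site_start + len(row["motif"]),
            motif=row["motif"],
            template_len=CELEGANS_TELOMERE_UNIT.unit_length,
            annealing_len=len(row["motif"]) - CELEGANS_TELOMERE_UNIT.unit_length,
        )
        rec = TranscriptRecord(
            interval=GenomicInterval(
                row["chrom"], row["start"] - 1, row["end"], row["strand"]
            ),
            id=row["id"],
            coverage_total=float(row["cov"]),  # printed sum of per-base depths
            polyA_class=row["polyA"],
            template_sites=[site],
            has_structure_locus=row["structure"],
            haca=(row["length"] - 30, row["length"] - 10, 0.8) if row["haca"] else None,
        )
        records.append(rec)
    return records
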