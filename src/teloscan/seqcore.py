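"""Nucleotide sequence handling and the telomere-template scanner.

Telomerase copies a short template inside its RNA subunit (TR) into
telomeric DNA. For a telomere terminal repeat such as ``TTAGGC``, any
functional template region must read as a circular permutation of the
reverse complement of that unit — i.e. it is a substring of the infinite
repetition ``...GCCTAAGCCTAA...``. A template region decomposes into a
*template* part (one full unit, the part that is actually copied) and an
*annealing* part that base-pairs with the existing chromosome end.

The scanner in this module reports every maximal run of a sequence that
belongs to this cyclic template language, subject to length bounds: with
the default 8–20 nt bounds and a 6 nt unit, annealing parts are 2–14 nt
long. Runs longer than the upper bound are telomeric repeat arrays rather
than plausible TR templates; they are reported with ``overlong=True`` and
excluded from candidate calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, NamedTuple, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleotideSequence",
    "TelomereUnit",
    "TemplateScanParams",
    "TemplateSite",
    "SiteDecomposition",
    "normalize_sequence",
    "reverse_complement",
    "is_telomeric_substring",
    "find_template_sites",
    "decompose_site",
    "read_fasta",
    "write_fasta",
    "sites_to_frame",
    "write_sites_bed",
    "write_sites_tsv",
]

_ALLOWED = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains illegal characters: "
                f"{sorted(bad)}; use normalize_sequence() for raw input"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_sequence(raw: str, identifier: str = "") -> NucleotideSequence:
    """Normalize raw input to the DNA alphabet.

    Lowercase is mapped to uppercase and U (RNA) to T. Any character
    outside {A, C, G, T, N} raises a ``ValueError`` naming the offending
    character and its 1-based position.
    """
    if not raw:
        raise ValueError("empty sequence")
    norm = raw.upper().replace("U", "T")
    for pos, ch in enumerate(norm):
        if ch not in _ALLOWED:
            raise ValueError(
                f"illegal character {raw[pos]!r} at position {pos + 1}"
                + (f" in sequence {identifier!r}" if identifier else "")
            )
    return NucleotideSequence(identifier, norm)


def reverse_complement(s: str) -> str:
    """Watson–Crick reverse complement; N maps to N."""
    bad = set(s) - _ALLOWED
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TelomereUnit:
    """The tandem DNA repeat added at chromosome ends (TTAGGC in *Caenorhabditis*)."""

    unit: str = "TTAGGC"

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("telomere unit must be non-empty")
        if set(self.unit) - set("ACGT"):
            raise ValueError(f"telomere unit {self.unit!r} must be uppercase DNA over ACGT")

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def template_repeat(self) -> str:
        """Reverse complement of the unit: one period of the template language."""
        return reverse_complement(self.unit)


@dataclass(frozen=True)
class TemplateScanParams:
    """Length bounds for template-region calls.

    ``min_template_len``/``max_template_len`` bound the whole template
    region (template part + annealing part). The defaults (8, 20) with a
    6 nt unit imply annealing parts of 2–14 nt.
    """

    min_template_len: int = 8
    max_template_len: int = 20
    unit: TelomereUnit = field(default_factory=TelomereUnit)
    min_annealing_len: int = 2

    def __post_init__(self) -> None:
        k = self.unit.unit_length
        if self.min_template_len < k + self.min_annealing_len:
            raise ValueError(
                "min_template_len must allow one full unit plus "
                f"min_annealing_len ({k} + {self.min_annealing_len})"
            )
        if self.max_template_len < self.min_template_len:
            raise ValueError("max_template_len must be >= min_template_len")
        if self.min_annealing_len < 1:
            raise ValueError("min_annealing_len must be positive")


@dataclass(frozen=True)
class TemplateSite:
    """A maximal telomere-template match inside a sequence.

    Coordinates are 0-based half-open on the scanned sequence. ``overlong``
    marks maximal runs exceeding ``max_template_len`` (telomeric arrays);
    such sites are never valid TR template candidates.
    """

    sequence_id: str
    start: int
    end: int
    motif: str
    template_len: int
    annealing_len: int
    maximal: bool = True
    overlong: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif):
            raise ValueError("site span does not match motif length")

    @property
    def start_1based(self) -> int:
        return self.start + 1


def is_telomeric_substring(motif: str, unit: TelomereUnit = TelomereUnit()) -> bool:
    """True iff ``motif`` is a substring of the cyclic template language.

    The language is the set of substrings of the infinite repetition of
    the reverse complement of the telomere unit (equivalently, of any of
    its circular permutations). N never matches.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    k = unit.unit_length
    reps = -(-len(motif) // k) + 1
    return motif in unit.template_repeat * reps


def find_template_sites(
    seq: NucleotideSequence,
    params: TemplateScanParams = TemplateScanParams(),
    *,
    truncate_overlong: bool = False,
) -> List[TemplateSite]:
    """Report every maximal run of ``seq`` in the cyclic template language.

    Runs are returned left to right. Runs shorter than
    ``min_template_len`` are omitted; runs longer than
    ``max_template_len`` are flagged ``overlong`` (or, with
    ``truncate_overlong=True``, truncated to ``max_template_len`` from
    their 5' end and marked non-maximal). Maximality means the run cannot
    be extended by one residue on either side and stay in the language;
    overlapping maximal runs of different phase are reported separately.
    """
    s = seq.residues
    n = len(s)
    rc = params.unit.template_repeat
    k = len(rc)

    # run[p][i] = length of the longest in-language run starting at i whose
    # first character sits at phase p of the repeated reverse complement.
    run = [[0] * (n + 1) for _ in range(k)]
    longest = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        ch = s[i]
        best = 0
        for p in range(k):
            if ch == rc[p]:
                val = 1 + run[(p + 1) % k][i + 1]
            else:
                val = 0
            run[p][i] = val
            if val > best:
                best = val
        longest[i] = best

    sites: List[TemplateSite] = []
    ulen = k
    for i in range(n):
        length = longest[i]
        if length < params.min_template_len:
            continue
        if i > 0 and longest[i - 1] == length + 1:
            continue  # extendable to the left: not a maximal run start
        overlong = length > params.max_template_len
        if overlong and truncate_overlong:
            motif = s[i : i + params.max_template_len]
            sites.append(
                TemplateSite(
                    sequence_id=seq.identifier,
                    start=i,
                    end=i + params.max_template_len,
                    motif=motif,
                    template_len=ulen,
                    annealing_len=params.max_template_len - ulen,
                    maximal=False,
                    overlong=False,
                )
            )
        else:
            motif = s[i : i + length]
            sites.append(
                TemplateSite(
                    sequence_id=seq.identifier,
                    start=i,
                    end=i + length,
                    motif=motif,
                    template_len=ulen,
                    annealing_len=length - ulen,
                    maximal=True,
                    overlong=overlong,
                )
            )
    return sites


class SiteDecomposition(NamedTuple):
    annealing: str
    template: str


def decompose_site(
    site: TemplateSite,
    params: TemplateScanParams = TemplateScanParams(),
    *,
    annealing_at: str = "3p",
) -> SiteDecomposition:
    """Split a template-region motif into annealing and template parts.

    The template part spans one full telomere unit; the annealing part is
    the remainder. By default the annealing part is taken at the 3' end of
    the motif (template first); pass ``annealing_at="5p"`` for the
    opposite orientation.
    """
    if site.overlong:
        raise ValueError("cannot decompose an overlong site (telomeric array)")
    k = params.unit.unit_length
    if len(site.motif) < k:
        raise ValueError("motif shorter than one telomere unit")
    if annealing_at == "3p":
        return SiteDecomposition(annealing=site.motif[k:], template=site.motif[:k])
    if annealing_at == "5p":
        return SiteDecomposition(annealing=site.motif[:-k], template=site.motif[-k:])
    raise ValueError("annealing_at must be '3p' or '5p'")


# ---------------------------------------------------------------------------
# FASTA and site export


def read_fasta(path: Union[str, Path]) -> List[NucleotideSequence]:
    """Read a (multi-record) FASTA file, normalizing residues on ingest."""
    return [
        normalize_sequence(str(rec.seq), identifier=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[NucleotideSequence], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.identifier, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def sites_to_frame(sites: Sequence[TemplateSite]) -> pd.DataFrame:
    """Tabulate sites with 1-based inclusive start positions for reporting."""
    return pd.DataFrame(
        {
            "sequence_id": [s.sequence_id for s in sites],
            "start_1based": [s.start_1based for s in sites],
            "motif": [s.motif for s in sites],
            "template_len": [s.template_len for s in sites],
            "annealing_len": [s.annealing_len for s in sites],
            "overlong": [s.overlong for s in sites],
        }
    )


def write_sites_tsv(sites: Sequence[TemplateSite], path: Union[str, Path]) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def write_sites_bed(sites: Sequence[TemplateSite], path: Union[str, Path]) -> None:
    """Export sites as BED6 (name = motif, score = motif length, strand '+')."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.sequence_id}\t{s.start}\t{s.end}\t{s.motif}\t{len(s.motif)}\t+\n"
            )
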