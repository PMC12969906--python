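"""Codon-119 genotyping of ace-1 amplicon sequences.

The G119S substitution in acetylcholinesterase-1 (Torpedo numbering) is
encoded at a single codon of the *ace-1* gene: GGC and GGT code for the
susceptible glycine (G class), AGC for the resistant serine (S).  Field
samples are Sanger-sequenced bidirectionally and heterozygotes arrive as
IUPAC ambiguity codes in a single consensus sequence (e.g. ``RGC`` for a
GGC/AGC individual).  This module anchors each amplicon to a short fixed
reference, reads the codon, and resolves it to an unordered allele pair.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "AmpliconRef",
    "GenotypeCall",
    "PopulationCounts",
    "NoAnchorError",
    "UnresolvableCodonError",
    "DEFAULT_REF",
    "KNOWN_ALLELES",
    "locate_codon",
    "call_codon119",
    "tally_population",
    "read_amplicon_fasta",
    "calls_to_csv",
]

#: Codon alleles observed at position 119 and their amino-acid class.
KNOWN_ALLELES = ("GGC", "GGT", "AGC")
RESISTANT_ALLELE = "AGC"

FLANK = 10  # exact-match anchor length on each side of the codon

# IUPAC code -> set of bases, and the inverse for emitting consensus codons.
IUPAC_SETS = {code.upper(): frozenset(bases.upper()) for code, bases in ambiguous_dna_values.items()}
SET_TO_IUPAC = {bases: code for code, bases in IUPAC_SETS.items()}


class NoAnchorError(ValueError):
    """The codon-119 flanking anchors could not be located uniquely."""


class UnresolvableCodonError(ValueError):
    """The observed codon is not explained by exactly one known allele pair."""


@dataclass(frozen=True)
class AmpliconRef:
    """Reference amplicon spanning ace-1 codon 119.

    Parameters
    ----------
    sequence
        Nucleotide sequence of the reference amplicon (193 bp in the assay
        this package models).
    codon119_offset
        0-based index of the first base of codon 119 within ``sequence``.
    reference_codon
        Expected codon at that offset; the susceptible GGC.
    """

    sequence: str
    codon119_offset: int
    reference_codon: str = "GGC"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if self.codon119_offset < FLANK:
            raise ValueError("codon offset leaves no room for the upstream anchor")
        if self.codon119_offset + 3 + FLANK > len(seq):
            raise ValueError("codon offset leaves no room for the downstream anchor")
        if seq[self.codon119_offset : self.codon119_offset + 3] != self.reference_codon:
            raise ValueError(
                f"reference codon at offset {self.codon119_offset} is "
                f"{seq[self.codon119_offset:self.codon119_offset + 3]!r}, "
                f"expected {self.reference_codon!r}"
            )

    @property
    def left_flank(self) -> str:
        return self.sequence[self.codon119_offset - FLANK : self.codon119_offset]

    @property
    def right_flank(self) -> str:
        return self.sequence[self.codon119_offset + 3 : self.codon119_offset + 3 + FLANK]


# Synthetic stand-in for the sequenced 193 bp ace-1 amplicon (the real
# amplicon is defined by the assay primers; any fixed sequence with unique
# codon flanks exercises the same logic).  Codon 119 (GGC) sits at 0-based
# offset 90.
_SYNTHETIC_AMPLICON = (
    "GCCCTCTCCACCGGGGGTGGGCATGTGAGGTAAATCAAAAGTACGGGCAT"
    "TATCATCTGCATGCACGGATTCGTACGTCGTACCAAGTAGGGCAACCCTA"
    "GTCACGGTCTAGTTAGTATAGGCCGCCGCGAAGGAACCCGCTGCCCTTTG"
    "TACTGGTACGTATCCACTTGCTACACGAGGTTTGCGATCGCTC"
)

DEFAULT_REF = AmpliconRef(sequence=_SYNTHETIC_AMPLICON, codon119_offset=90)


@dataclass(frozen=True)
class GenotypeCall:
    """Resolved codon-119 genotype for one sample.

    ``allele_pair`` is the unordered pair of codon alleles; ``genotype_class``
    is GG/GS/SS by the number of resistant (AGC) alleles in the pair.  When
    ``qc_flag`` is not ``"ok"`` the pair is undefined (``None``).
    """

    sample_id: str
    population: str
    observed_codon: str | None
    allele_pair: tuple[str, str] | None
    genotype_class: str | None
    qc_flag: str = "ok"


@dataclass
class PopulationCounts:
    """Genotype counts for one population; the unit of all popgen statistics."""

    population: str
    n: int
    n_gg: int
    n_gs: int
    n_ss: int
    n_ggt_alleles: int = 0

    def __post_init__(self) -> None:
        if self.n_gg + self.n_gs + self.n_ss != self.n:
            raise ValueError("genotype counts do not sum to n")
        if not 0 <= self.n_ggt_alleles <= 2 * self.n_gg + self.n_gs:
            raise ValueError("GGT allele count exceeds available G alleles")


def _bases(symbol: str) -> frozenset[str]:
    try:
        return IUPAC_SETS[symbol.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {symbol!r}") from None


def _matches(flank: str, segment: str) -> bool:
    """True when every flank base is compatible with the (possibly ambiguous)
    segment base."""
    if len(flank) != len(segment):
        return False
    try:
        return all(f in _bases(s) for f, s in zip(flank, segment))
    except ValueError:
        return False


def _find_anchor(seq: str, left: str, right: str) -> list[int]:
    """All codon offsets where both 10-mer flanks match, codon between them."""
    hits = []
    span = len(left) + 3 + len(right)
    for i in range(len(seq) - span + 1):
        if _matches(left, seq[i : i + len(left)]) and _matches(
            right, seq[i + len(left) + 3 : i + span]
        ):
            hits.append(i + len(left))
    return hits


def locate_codon(seq: str, ref: AmpliconRef = DEFAULT_REF) -> tuple[int, str]:
    """Anchor ``seq`` to the reference and return the codon-119 position.

    Both orientations are searched; ambiguity codes in ``seq`` match any
    compatible base.  Returns ``(offset, oriented_seq)`` where ``offset`` is
    the 0-based codon start within ``oriented_seq`` (``seq`` itself on a
    forward hit, its reverse complement otherwise).

    Raises
    ------
    NoAnchorError
        If the flank pair does not match exactly once across the two strands.
    """
    if not seq:
        raise NoAnchorError("empty sequence")
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    fwd = _find_anchor(seq, ref.left_flank, ref.right_flank)
    rev = _find_anchor(rc, ref.left_flank, ref.right_flank)
    if len(fwd) + len(rev) != 1:
        raise NoAnchorError(
            f"expected exactly one anchor hit, found {len(fwd)} forward and {len(rev)} reverse"
        )
    return (fwd[0], seq) if fwd else (rev[0], rc)


def _resolve_pair(codon: str) -> tuple[str, str]:
    """Unordered allele pair explaining an observed (possibly ambiguous) codon.

    A consensus codon with ambiguity at more than one position cannot be
    phased — the double peaks could pair into haplotypes outside the known
    allele set — so it is rejected outright rather than force-fit.
    """
    sets = [_bases(b) for b in codon]
    if sum(len(s) > 1 for s in sets) > 1:
        raise UnresolvableCodonError(
            f"codon {codon!r} is ambiguous at more than one position; phase unknown"
        )
    candidates = []
    for i, a in enumerate(KNOWN_ALLELES):
        for b in KNOWN_ALLELES[i:]:
            if all({a[k], b[k]} == set(sets[k]) for k in range(3)):
                candidates.append((a, b))
    if len(candidates) != 1:
        raise UnresolvableCodonError(
            f"codon {codon!r} explained by {len(candidates)} allele pairs, need exactly 1"
        )
    return tuple(sorted(candidates[0]))


def genotype_class(pair: Sequence[str]) -> str:
    n_res = sum(a == RESISTANT_ALLELE for a in pair)
    return ("GG", "GS", "SS")[n_res]


def call_codon119(
    seq: str,
    ref: AmpliconRef = DEFAULT_REF,
    sample_id: str = "",
    population: str = "",
    strict: bool = True,
) -> GenotypeCall:
    """Call the codon-119 genotype of one amplicon sequence.

    With ``strict=False``, anchoring or resolution failures yield a call with
    ``qc_flag`` set (``no_anchor`` / ``unresolvable``) instead of raising.
    """
    try:
        offset, oriented = locate_codon(seq, ref)
    except NoAnchorError:
        if strict:
            raise
        return GenotypeCall(sample_id, population, None, None, None, "no_anchor")
    codon = oriented[offset : offset + 3]
    try:
        pair = _resolve_pair(codon)
    except (UnresolvableCodonError, ValueError):
        if strict:
            raise
        return GenotypeCall(sample_id, population, codon, None, None, "unresolvable")
    return GenotypeCall(sample_id, population, codon, pair, genotype_class(pair))


def tally_population(calls: Iterable[GenotypeCall]) -> PopulationCounts:
    """Aggregate OK genotype calls from one population into counts.

    GGT alleles are counted separately (they belong to the susceptible G
    class but mark a distinct synonymous allele).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no calls to tally")
    pops = {c.population for c in calls}
    if len(pops) != 1:
        raise ValueError(f"calls span multiple populations: {sorted(pops)}")
    if any(c.qc_flag != "ok" for c in calls):
        raise ValueError("tally requires qc_flag == 'ok' for every call")
    counts = {"GG": 0, "GS": 0, "SS": 0}
    n_ggt = 0
    for c in calls:
        counts[c.genotype_class] += 1
        n_ggt += sum(a == "GGT" for a in c.allele_pair)
    return PopulationCounts(
        population=pops.pop(),
        n=len(calls),
        n_gg=counts["GG"],
        n_gs=counts["GS"],
        n_ss=counts["SS"],
        n_ggt_alleles=n_ggt,
    )


def read_amplicon_fasta(
    path: str | Path,
    ref: AmpliconRef = DEFAULT_REF,
    delimiter: str = "|",
    strict: bool = True,
) -> list[GenotypeCall]:
    """Genotype every record of a FASTA file.

    Record IDs are parsed as ``sampleID<delimiter>population``; a missing
    delimiter leaves the population empty.
    """
    calls = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample, _, pop = rec.id.partition(delimiter)
        calls.append(call_codon119(str(rec.seq), ref, sample, pop, strict=strict))
    return calls


def calls_to_csv(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    """Write calls as the genotype-table CSV consumed by the popgen stage."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["sample_id", "population", "observed_codon", "allele1", "allele2", "genotype_class", "qc_flag"]
        )
        for c in calls:
            a1, a2 = c.allele_pair if c.allele_pair else ("", "")
            w.writerow([c.sample_id, c.population, c.observed_codon or "", a1, a2, c.genotype_class or "", c.qc_flag])
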