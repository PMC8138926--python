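"""In-silico PCR and codon-level mutation naming for the IDH sequencing assays.

Primer placement uses exact matching only: the forward primer must occur
exactly once on the plus strand and the reverse primer's reverse complement
exactly once downstream of it. Amplicon coordinates are 0-based half-open and
lengths include both primers (standard amplicon convention). Mutation naming
translates reference and observed codons with the standard genetic code and
emits labels like ``R132H`` (or ``wild-type`` when the codons agree).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

_DNA_ALPHABET = set("ACGT")
MIN_PRIMER_LENGTH = 15

# Printed primer pairs of the Sanger assays (5'->3').
IDH1_PRIMERS = ("CGGTCTTCAGAGAAGCCATT", "GCAAAATCACATTATTGCCAAC")
IDH2_PRIMERS = ("GCTGCAGTGGGACCACTATT", "TGTGGCCTTGTACTGCAGAG")


class PCRError(ValueError):
    """Primer binding failure in in-silico PCR."""


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self):
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if set(seq) - _DNA_ALPHABET:
                raise ValueError(f"{name} primer contains non-ACGT characters")
            if len(seq) < MIN_PRIMER_LENGTH:
                raise ValueError(
                    f"{name} primer shorter than {MIN_PRIMER_LENGTH} nt"
                )


@dataclass(frozen=True)
class Amplicon:
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MutationCall:
    gene: str
    codon_number: int
    ref_codon: str
    obs_codon: str
    label: str


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


def _find_all(template: str, query: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = template.find(query, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1  # overlapping occurrences count


def in_silico_pcr(template: str, primers: PrimerPair) -> Amplicon:
    """Place a primer pair on a template by exact matching; return the amplicon.

    The amplicon runs from the first base of the forward primer's binding site
    through the last base of the reverse primer's binding site (the reverse
    complement of the reverse primer on the plus strand).
    """
    template = template.upper()
    if set(template) - _DNA_ALPHABET:
        raise ValueError("template contains non-ACGT characters")
    fwd_sites = _find_all(template, primers.forward)
    if len(fwd_sites) == 0:
        raise PCRError("forward primer not found on the template")
    if len(fwd_sites) > 1:
        raise PCRError(f"forward primer binds {len(fwd_sites)} sites (need exactly 1)")
    rev_site_seq = revcomp(primers.reverse)
    rev_sites = _find_all(template, rev_site_seq)
    if len(rev_sites) == 0:
        raise PCRError("reverse primer not found on the template")
    if len(rev_sites) > 1:
        raise PCRError(f"reverse primer binds {len(rev_sites)} sites (need exactly 1)")
    start = fwd_sites[0]
    end = rev_sites[0] + len(rev_site_seq)
    if rev_sites[0] < start:
        raise PCRError("reverse primer site lies upstream of the forward site")
    return Amplicon(start=start, end=end, sequence=template[start:end])


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code ('*' for stop)."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - _DNA_ALPHABET:
        raise ValueError(f"invalid codon {codon!r}: need a 3-mer over ACGT")
    return str(Seq(codon).translate())


def name_codon_mutation(gene: str, codon_number: int, ref_codon: str,
                        obs_codon: str) -> MutationCall:
    """Name a codon substitution, e.g. (IDH1, 132, CGT, CAT) -> R132H.

    Identical codons (or synonymous changes) yield the label ``wild-type``;
    a stop gain is written with ``*``.
    """
    ref_aa = translate_codon(ref_codon)
    obs_aa = translate_codon(obs_codon)
    if ref_aa == "*":
        raise ValueError("reference codon translates to a stop codon")
    label = "wild-type" if ref_aa == obs_aa else f"{ref_aa}{codon_number}{obs_aa}"
    return MutationCall(
        gene=gene,
        codon_number=codon_number,
        ref_codon=ref_codon.upper(),
        obs_codon=obs_codon.upper(),
        label=label,
    )
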