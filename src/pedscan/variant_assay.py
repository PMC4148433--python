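"""Coding-variant annotation and in-silico RFLP genotyping.

Maps a cDNA substitution (HGVS-style ``c.`` coordinates, c.1 = A of the
start codon) to its codon and amino-acid change, predicts restriction
fragments for each allele of a PCR amplicon, and classifies genotypes from
observed fragment ladders — the gel-based assay used to screen a family and
breed panels once a candidate variant is in hand.

Only top-strand cut coordinates matter for fragment lengths on a gel, so
enzymes are modeled as a recognition sequence plus a signed cut offset, with
the reverse-complement orientation handled by coordinate reflection;
overhang chemistry is ignored.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq


class AssayError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Coding-variant annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingVariant:
    """A single-base substitution in a coding sequence.

    ``cdna_position`` is 1-based within the CDS (position 1 = A of ATG).
    """

    cdna_position: int
    ref_base: str
    alt_base: str
    cds: str

    def __post_init__(self) -> None:
        if self.cdna_position < 1:
            raise AssayError("cdna_position must be >= 1 (1-based)")
        if len(self.cds) % 3 != 0:
            raise AssayError("CDS length must be a multiple of 3")
        if self.cdna_position > len(self.cds):
            raise AssayError("cdna_position beyond CDS end")
        found = self.cds[self.cdna_position - 1].upper()
        if found != self.ref_base.upper():
            raise AssayError(
                f"reference mismatch at c.{self.cdna_position}: CDS has "
                f"{found!r}, variant says {self.ref_base!r}"
            )

    @property
    def codon_index(self) -> int:
        return codon_of(self.cdna_position)[0]

    @property
    def codon_offset(self) -> int:
        return codon_of(self.cdna_position)[1]


def codon_of(cdna_position: int) -> tuple[int, int]:
    """(codon index, position within codon) of a 1-based cDNA coordinate.

    c.1010 falls in codon 337 at codon position 2 — the arithmetic behind
    reading a ``c.1010T>C`` call as an I337T substitution.
    """
    if cdna_position < 1:
        raise AssayError("cdna_position must be >= 1")
    return math.ceil(cdna_position / 3), (cdna_position - 1) % 3 + 1


def predict_aa_change(variant: CodingVariant) -> tuple[str, str, str]:
    """(ref_aa, alt_aa, label) for a coding substitution.

    Translation uses the standard genetic code; the label is the familiar
    RefAA-index-AltAA single-letter form (e.g. ``"I337T"``).
    """
    idx, offset = codon_of(variant.cdna_position)
    start = (idx - 1) * 3
    codon = variant.cds[start:start + 3].upper()
    alt_codon = (
        codon[: offset - 1] + variant.alt_base.upper() + codon[offset:]
    )
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return ref_aa, alt_aa, f"{ref_aa}{idx}{alt_aa}"


# ---------------------------------------------------------------------------
# Restriction digest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeSpec:
    """An (possibly asymmetric) restriction enzyme.

    ``recognition`` is given on one strand; the enzyme cuts the scanned
    strand immediately before index ``match_start + cut_offset`` (so a
    negative offset cuts 5' of the site).  When ``scans_both_strands`` the
    reverse-complement orientation is also cut, at the reflected
    coordinate ``match_start + len(recognition) - cut_offset``.
    """

    name: str
    recognition: str
    cut_offset: int
    scans_both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.recognition:
            raise AssayError("empty recognition sequence")


# BtsI: cuts two bases 5' of CACTGC as written (…NN^CACTGC…), equivalently
# two bases 3' of GCAGTG on the opposite strand.
BTSI = EnzymeSpec(name="BtsI", recognition="CACTGC", cut_offset=-2)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


@dataclass(frozen=True)
class DigestResult:
    """Fragment ladder from digesting one allele's amplicon."""

    allele_label: str
    fragment_lengths: tuple[int, ...]

    @property
    def band_sizes(self) -> frozenset:
        """Distinct fragment sizes — what a gel lane shows."""
        return frozenset(self.fragment_lengths)


def digest(
    amplicon_sequence: str,
    enzyme: EnzymeSpec,
    allele_label: str = "",
) -> DigestResult:
    """Cut an amplicon at every enzyme site (both orientations when the
    enzyme scans both strands) and return sorted fragment lengths.

    An uncut sequence yields a single full-length fragment; fragment
    lengths always sum to the amplicon length.  A recognition site whose
    cut coordinate falls outside the sequence raises an error (the enzyme
    cannot produce a defined fragment there).
    """
    seq = amplicon_sequence.upper()
    n = len(seq)
    rec = enzyme.recognition.upper()
    cuts: set[int] = set()
    for i in _find_all(seq, rec):
        pos = i + enzyme.cut_offset
        if not 0 <= pos <= n:
            raise AssayError(
                f"{enzyme.name}: cut at {pos} outside sequence of length {n}"
            )
        cuts.add(pos)
    if enzyme.scans_both_strands:
        rc = str(Seq(rec).reverse_complement())
        if rc != rec:
            for i in _find_all(seq, rc):
                pos = i + len(rec) - enzyme.cut_offset
                if not 0 <= pos <= n:
                    raise AssayError(
                        f"{enzyme.name}: cut at {pos} outside sequence of "
                        f"length {n}"
                    )
                cuts.add(pos)
    bounds = [0] + sorted(c for c in cuts if 0 < c < n) + [n]
    fragments = tuple(
        sorted(b - a for a, b in zip(bounds, bounds[1:]))
    )
    return DigestResult(allele_label=allele_label, fragment_lengths=fragments)


# ---------------------------------------------------------------------------
# Genotype classification and cohort screening
# ---------------------------------------------------------------------------

HOM_REF = "homozygous_ref"
HET = "heterozygous"
HOM_ALT = "homozygous_alt"
INCONSISTENT = "inconsistent"


def _bands_match(
    observed: frozenset, expected: frozenset, rel_tol: float
) -> bool:
    if rel_tol <= 0:
        return observed == expected
    def one_way(xs, ys):
        return all(
            any(abs(x - y) <= rel_tol * y for y in ys) for x in xs
        )
    return one_way(observed, expected) and one_way(expected, observed)


def genotype_from_fragments(
    observed_lengths,
    expected_per_allele: dict,
    rel_tol: float = 0.0,
) -> str:
    """Classify a gel lane against the per-allele expected ladders.

    ``expected_per_allele`` maps the two allele labels (ref first) to their
    :class:`DigestResult` or fragment-length iterables.  A lane matching
    the ref ladder alone is ``homozygous_ref``; the alt ladder alone,
    ``homozygous_alt``; the union of band sizes, ``heterozygous``; anything
    else (including ambiguous ladders) is ``inconsistent``.  ``rel_tol``
    optionally allows +/- that relative error when matching band sizes,
    mimicking real gel resolution.
    """
    if len(expected_per_allele) != 2:
        raise AssayError("expected ladders for exactly 2 alleles")
    (ref_label, ref_exp), (alt_label, alt_exp) = expected_per_allele.items()

    def bands(x) -> frozenset:
        if isinstance(x, DigestResult):
            return x.band_sizes
        return frozenset(int(v) for v in x)

    ref_bands, alt_bands = bands(ref_exp), bands(alt_exp)
    obs = bands(observed_lengths)
    matches = []
    if _bands_match(obs, ref_bands, rel_tol):
        matches.append(HOM_REF)
    if _bands_match(obs, alt_bands, rel_tol):
        matches.append(HOM_ALT)
    if _bands_match(obs, ref_bands | alt_bands, rel_tol):
        matches.append(HET)
    if len(matches) == 1:
        return matches[0]
    return INCONSISTENT


def screen_cohort(genotype_calls) -> dict:
    """Tally per-class counts of a screened cohort.

    Returns a dict with the three genotype classes, ``inconsistent``, and
    ``total`` (always the length of the input).
    """
    counts = Counter(genotype_calls)
    known = (HOM_REF, HET, HOM_ALT, INCONSISTENT)
    unknown = set(counts) - set(known)
    if unknown:
        raise AssayError(f"unknown genotype classes: {sorted(unknown)}")
    out = {k: counts.get(k, 0) for k in known}
    out["total"] = sum(out.values())
    return out
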