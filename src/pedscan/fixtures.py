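"""Synthetic sequence and region fixtures for the worked examples.

The real primer/amplicon sequences and gene coordinates live in the dog
genome and are not bundled; these constructors build *synthetic* stand-ins
that reproduce the assay's observable arithmetic exactly: a 470-bp amplicon
pair whose variant allele carries a single BtsI site cutting into 204 + 266
bp fragments, a synthetic CDS in which c.1010 is the middle base of an ATT
isoleucine codon at residue 337, and an 18-gene candidate list spread over
13 chromosomes.  Everything is generated deterministically at call time.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from .pedigree_io import Region
from .variant_assay import BTSI

AMPLICON_LENGTH = 470
CUT_AT = 204  # variant-allele fragments: 204 + 266 bp
VARIANT_OFFSET = CUT_AT + 2 + len(BTSI.recognition) - 1  # last base of site

# The 18 candidate genes and their chromosomes (13 distinct), as screened
# for this phenotype.
CANDIDATE_GENES = [
    ("3", "DOK7"),
    ("5", "AGRN"),
    ("5", "CHRNB1"),
    ("5", "CHRNE"),
    ("5", "DPAGT1"),
    ("6", "ALG14"),
    ("9", "SCN4A"),
    ("10", "GFPT1"),
    ("11", "ALG2"),
    ("11", "MUSK"),
    ("13", "PLEC1"),
    ("18", "RAPSN"),
    ("20", "LAMB2"),
    ("23", "COLQ"),
    ("25", "CHRNG"),
    ("25", "CHRND"),
    ("28", "CHAT"),
    ("36", "CHRNA1"),
]


def _random_seq_without_sites(
    n: int, rng: np.random.Generator, forbidden: tuple[str, ...]
) -> str:
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=n))
        if not any(f in seq for f in forbidden):
            return seq


def synthetic_exon14_amplicons(seed: int = 7) -> tuple[str, str]:
    """(wild_type, variant) synthetic 470-bp amplicons.

    The two sequences differ at a single base.  The wild-type carries
    ``CACTGT`` where the variant's T>C substitution completes the BtsI site
    ``CACTGC``; the enzyme therefore cuts only the variant allele, two
    bases 5' of the site, into 204 and 266 bp fragments.  The surrounding
    sequence contains no BtsI site in either orientation.
    """
    rec = BTSI.recognition  # CACTGC
    rc = str(Seq(rec).reverse_complement())  # GCAGTG
    site_start = CUT_AT + 2  # cut_offset is -2, cut must land at CUT_AT
    rng = np.random.default_rng(seed)
    forbidden = (rec, rc)
    while True:
        left = _random_seq_without_sites(site_start, rng, forbidden)
        right = _random_seq_without_sites(
            AMPLICON_LENGTH - site_start - len(rec), rng, forbidden
        )
        wild = left + rec[:-1] + "T" + right  # CACTGT: no site
        variant = left + rec + right          # CACTGC: one site
        # junction-spanning sites could sneak in; verify both alleles
        wild_ok = rec not in wild and rc not in wild
        var_ok = (
            wild != variant
            and variant.count(rec) == 1
            and rc not in variant
        )
        if wild_ok and var_ok:
            return wild, variant


def synthetic_colq_cds(seed: int = 11, n_codons: int = 360) -> str:
    """A synthetic CDS with an ATT isoleucine codon at residue 337.

    Length is ``3 * (n_codons + 1)`` including the stop; c.1010 (codon 337,
    position 2) is the T whose substitution to C turns ATT into ACT —
    the I337T change.  No internal stop codons.
    """
    if n_codons < 337:
        raise ValueError("need at least 337 codons")
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    codons[336] = "ATT"  # residue 337
    codons.append("TAA")
    return "".join(codons)


def synthetic_candidate_gene_regions(
    gene_length_bp: int = 200_000, spacing_bp: int = 5_000_000
) -> list[Region]:
    """BED-style regions (0-based half-open) for the 18 candidate genes.

    Coordinates are synthetic: genes on a shared chromosome are placed
    ``spacing_bp`` apart starting at 10 Mb.  The chromosome set has 13
    distinct values, mirroring the published candidate-gene geometry.
    """
    regions = []
    per_chrom: dict[str, int] = {}
    for chrom, gene in CANDIDATE_GENES:
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        start = 10_000_000 + k * spacing_bp
        regions.append(
            Region(
                chromosome=chrom,
                start_bp=start,
                end_bp=start + gene_length_bp,
                label=gene,
            )
        )
    return regions


def candidate_regions_for_simulation(
    causal_locus: tuple[str, int],
    chromosome_names: tuple[str, ...],
    gene_length_bp: int = 2_000_000,
) -> list[Region]:
    """Candidate-gene regions laid out on simulated chromosomes.

    Each of the 18 genes is assigned round-robin to a simulated chromosome
    at staggered positions; the gene named COLQ is placed so that it
    contains the causal locus.
    """
    causal_chrom, causal_pos = causal_locus
    regions = []
    per_chrom: dict[str, int] = {}
    for i, (_, gene) in enumerate(CANDIDATE_GENES):
        if gene == "COLQ":
            start = max(0, causal_pos - gene_length_bp // 2)
            regions.append(
                Region(
                    chromosome=causal_chrom,
                    start_bp=start,
                    end_bp=start + gene_length_bp,
                    label=gene,
                )
            )
            continue
        chrom = chromosome_names[i % len(chromosome_names)]
        k = per_chrom.get(chrom, 0)
        per_chrom[chrom] = k + 1
        start = 5_000_000 + k * 12_000_000
        if chrom == causal_chrom and abs(start - causal_pos) < 8_000_000:
            start = causal_pos + 10_000_000 + k * 3_000_000
        regions.append(
            Region(
                chromosome=chrom,
                start_bp=start,
                end_bp=start + gene_length_bp,
                label=gene,
            )
        )
    return regions
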