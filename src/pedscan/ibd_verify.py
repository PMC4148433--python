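"""Identity-by-descent vs identity-by-state discrimination.

A candidate region that survived the recessive filter is only causal-grade
evidence if the shared homozygous segment is identical by descent — both
case chromosomes copies of one ancestral haplotype — rather than merely
identical by state.  Highly polymorphic microsatellites flanking the region
discriminate the two: case homozygosity at markers that are heterozygous
elsewhere in the family is very unlikely unless the segment is IBD, while a
heterozygous case immediately rules IBD out.  The verdict is rule-based, not
probabilistic, combining microsatellite homozygosity with an identical
phased SNP haplotype across the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pedigree_io import (
    GenotypeMatrix,
    Pedigree,
    PedigreeError,
)
from .segregation_scan import CandidateRegion, nuclear_family, cases_of

logger = logging.getLogger(__name__)

UNRESOLVED = None


@dataclass
class PhasedHaplotypes:
    """Phase-resolved haplotypes for the litter of a nuclear family.

    ``haplotypes[ind][copy][j]`` is the allele on the paternal (copy 0) or
    maternal (copy 1) chromosome at marker index ``j``, or ``None`` where
    Mendelian logic cannot resolve phase.  ``resolved[ind][j]`` is the
    boolean mask of resolved sites; ``inconsistent_markers`` lists markers
    flagged (and masked) for Mendelian inconsistency.
    """

    individual_ids: list
    haplotypes: dict
    resolved: dict
    inconsistent_markers: list = field(default_factory=list)


def _trio_phase(
    father: tuple | None, mother: tuple | None, child: tuple | None
) -> tuple[str, str] | None | str:
    """Phase one child call given parent calls at one marker.

    Returns the (paternal, maternal) allele pair when uniquely determined,
    ``None`` when ambiguous or any call is missing, and ``"mendel"`` when
    no assignment is consistent (Mendelian inconsistency).
    """
    if father is None or mother is None or child is None:
        return None
    assignments = {
        (a, b)
        for a in father
        for b in mother
        if tuple(sorted((a, b))) == child
    }
    if not assignments:
        return "mendel"
    if len(assignments) == 1:
        return next(iter(assignments))
    return None


def phase_nuclear_family(
    matrix: GenotypeMatrix, pedigree: Pedigree
) -> PhasedHaplotypes:
    """Phase the litter of the nuclear family by per-marker Mendelian logic.

    Phase is resolved only where transmission is uniquely determined (e.g.
    a homozygous parent, or a homozygous child); nothing is ever guessed,
    and markers showing a Mendelian inconsistency in any trio are masked
    everywhere with a logged warning (possible genotyping error).
    """
    sire, dam, litter = nuclear_family(pedigree)
    offspring = [o.id for o in litter if o.id in matrix.individual_ids]
    if sire.id not in matrix.individual_ids or dam.id not in matrix.individual_ids:
        raise PedigreeError("both parents must be genotyped for phasing")
    if not offspring:
        raise PedigreeError("no genotyped offspring to phase")

    n = matrix.n_markers
    haplotypes = {
        ind: [np.full(n, None, dtype=object), np.full(n, None, dtype=object)]
        for ind in offspring
    }
    inconsistent: list[str] = []
    for j, marker in enumerate(matrix.marker_map):
        f = matrix.call_at(sire.id, j)
        m = matrix.call_at(dam.id, j)
        results = {}
        bad = False
        for ind in offspring:
            r = _trio_phase(f, m, matrix.call_at(ind, j))
            if r == "mendel":
                bad = True
                break
            results[ind] = r
        if bad:
            inconsistent.append(marker.id)
            logger.warning(
                "Mendelian inconsistency at marker %s; masked "
                "(possible genotyping error)", marker.id,
            )
            continue
        for ind, r in results.items():
            if r is not None:
                haplotypes[ind][0][j], haplotypes[ind][1][j] = r
    resolved = {
        ind: np.array([a is not None for a in haplotypes[ind][0]])
        for ind in offspring
    }
    return PhasedHaplotypes(
        individual_ids=offspring,
        haplotypes=haplotypes,
        resolved=resolved,
        inconsistent_markers=inconsistent,
    )


@dataclass
class IbdVerdict:
    """Outcome of IBD verification for one candidate region."""

    region: CandidateRegion
    flanking_marker_ids: list
    case_homozygous_at_flank: dict  # marker id -> {case id: bool}
    shared_allele_consistent: bool
    verdict: str  # "ibd_consistent" | "not_ibd" | "uninformative"

    def to_dict(self) -> dict:
        return {
            "region": self.region.to_dict(),
            "flanking_marker_ids": self.flanking_marker_ids,
            "case_homozygous_at_flank": self.case_homozygous_at_flank,
            "shared_allele_consistent": self.shared_allele_consistent,
            "verdict": self.verdict,
        }


def verify_ibd(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    region: CandidateRegion,
    flank_window_bp: int = 1_000_000,
) -> IbdVerdict:
    """Classify a candidate region as IBD-consistent, not IBD, or
    uninformative using microsatellites within the region span plus
    ``flank_window_bp`` on each side.

    A microsatellite is informative when >=2 distinct alleles are observed
    in the nuclear family.  ``ibd_consistent`` requires every case to be
    homozygous for one shared allele at every informative microsatellite
    *and* the cases' phased SNP haplotypes to be identical across the
    region; a heterozygous case — or cases homozygous for different
    alleles — at an informative microsatellite yields ``not_ibd``;
    with no informative microsatellite the verdict is ``uninformative``.
    """
    if region.chromosome not in matrix.marker_map.chromosomes:
        raise ValueError(
            f"region chromosome {region.chromosome!r} not in marker map"
        )
    cases = [c for c in cases_of(pedigree) if c in matrix.individual_ids]
    sire, dam, litter = nuclear_family(pedigree)
    family = [
        i.id
        for i in [sire, dam, *litter]
        if i.id in matrix.individual_ids
    ]

    lo = region.start_bp - flank_window_bp
    hi = region.end_bp + flank_window_bp
    flank = [
        (j, m)
        for j, m in matrix.marker_map.on_chromosome(region.chromosome)
        if m.kind == "microsatellite" and lo <= m.position_bp <= hi
    ]

    hom_by_marker: dict = {}
    saw_heterozygous_case = False
    shared_allele_consistent = True
    n_informative = 0
    for j, marker in flank:
        observed = set()
        for ind in family:
            call = matrix.call_at(ind, j)
            if call is not None:
                observed.update(call)
        informative = len(observed) >= 2
        hom_flags = {}
        case_alleles = set()
        for c in cases:
            call = matrix.call_at(c, j)
            if call is None:
                hom_flags[c] = None
                continue
            hom = call[0] == call[1]
            hom_flags[c] = hom
            if hom:
                case_alleles.add(call[0])
            elif informative:
                saw_heterozygous_case = True
        hom_by_marker[marker.id] = hom_flags
        if not informative:
            continue
        n_informative += 1
        if any(flag is False for flag in hom_flags.values()):
            shared_allele_consistent = False
        elif len(case_alleles) > 1:
            # homozygous, but for different alleles: cannot be one shared
            # ancestral segment
            shared_allele_consistent = False
            saw_heterozygous_case = True

    if n_informative == 0:
        return IbdVerdict(
            region=region,
            flanking_marker_ids=[m.id for _, m in flank],
            case_homozygous_at_flank=hom_by_marker,
            shared_allele_consistent=False,
            verdict="uninformative",
        )
    if saw_heterozygous_case:
        return IbdVerdict(
            region=region,
            flanking_marker_ids=[m.id for _, m in flank],
            case_homozygous_at_flank=hom_by_marker,
            shared_allele_consistent=False,
            verdict="not_ibd",
        )

    # All informative microsatellites show every case homozygous for one
    # shared allele; additionally require the identical phased SNP
    # haplotype across the region itself.
    phased = phase_nuclear_family(matrix, pedigree)
    region_snps = [
        (j, m)
        for j, m in matrix.marker_map.on_chromosome(region.chromosome)
        if m.kind == "snp"
        and region.start_bp <= m.position_bp <= region.end_bp
    ]
    haplotype_identical = True
    for j, marker in region_snps:
        site_alleles = set()
        for c in cases:
            if c not in phased.haplotypes:
                continue
            for copy in (0, 1):
                a = phased.haplotypes[c][copy][j]
                if a is not None:
                    site_alleles.add(a)
        if len(site_alleles) > 1:
            haplotype_identical = False
            break

    all_hom = all(
        flag is not False
        for flags in hom_by_marker.values()
        for flag in flags.values()
    )
    consistent = all_hom and haplotype_identical
    return IbdVerdict(
        region=region,
        flanking_marker_ids=[m.id for _, m in flank],
        case_homozygous_at_flank=hom_by_marker,
        shared_allele_consistent=consistent,
        verdict="ibd_consistent" if consistent else "uninformative",
    )


def count_mendelian_errors(
    matrix: GenotypeMatrix, pedigree: Pedigree
) -> list[tuple[str, str]]:
    """(individual, marker) pairs whose call cannot be explained by one
    allele from each genotyped parent.  Empty on error-free simulations."""
    errors = []
    for ind in pedigree:
        if ind.is_founder or ind.id not in matrix.individual_ids:
            continue
        if (
            ind.sire_id not in matrix.individual_ids
            or ind.dam_id not in matrix.individual_ids
        ):
            continue
        for j, marker in enumerate(matrix.marker_map):
            child = matrix.call_at(ind.id, j)
            f = matrix.call_at(ind.sire_id, j)
            m = matrix.call_at(ind.dam_id, j)
            if child is None or f is None or m is None:
                continue
            ok = any(
                tuple(sorted((a, b))) == child for a in f for b in m
            )
            if not ok:
                errors.append((ind.id, marker.id))
    return errors
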