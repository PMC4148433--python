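"""Recessive segregation filtering of nuclear-family genotypes.

The core inference of the package: a marker is consistent with autosomal
recessive transmission of a fully penetrant allele when (a) every affected
individual is homozygous for the same allele and (b) that allele's
frequency among the unaffected nuclear-family members falls inside the
interval the pedigree structure itself dictates.  With both parents of an
affected offspring being obligate heterozygotes and each unaffected sibling
carrying 0 or 1 copies, the admissible control frequency for a control set
of ``p`` carrier parents and ``s`` unaffected siblings is

    [ p / (2 (p + s)),  (p + s) / (2 (p + s)) ]

— (2/14, 7/14) = (0.14, 0.50) for 2 parents and 5 unaffected littermates.
Frequencies are always compared unrounded; rounding is a reporting artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .pedigree_io import (
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    PedigreeError,
    Phenotype,
    Region,
)


@dataclass
class FilterParams:
    """Knobs of the recessive marker filter.

    ``control_bounds`` may be supplied explicitly (e.g. the published
    interval) or left ``None`` to be derived from the pedigree structure.
    ``min_run_length`` is the minimum number of consecutive passing markers
    that forms a reportable candidate region.  The default of 1 reflects
    that, absent linkage disequilibrium among markers, a shared private
    allele announces itself at a single marker while its common neighbours
    legitimately fail the control bound; identity-by-state noise is
    suppressed downstream by candidate-gene intersection and the IBD
    verification stage.  With real array data (strong local LD) larger
    values are appropriate.
    """

    case_freq_required: float = 1.0
    control_bounds: tuple[float, float] | None = None
    min_run_length: int = 1
    rounding_decimals: int = 2

    def __post_init__(self) -> None:
        if self.control_bounds is not None:
            low, high = self.control_bounds
            if not 0.0 <= low <= high <= 1.0:
                raise ValueError(
                    f"control bounds must satisfy 0 <= low <= high <= 1, "
                    f"got {self.control_bounds}"
                )
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")


@dataclass
class CandidateRegion:
    """A maximal run of markers passing the recessive filter."""

    chromosome: str
    first_marker_id: str
    last_marker_id: str
    start_bp: int
    end_bp: int
    n_markers: int
    shared_case_alleles: dict  # marker id -> shared homozygous case allele
    control_frequency: float   # mean risk-allele frequency among controls
    labels: list = field(default_factory=list)  # candidate gene names hit
    excluded_by_unaffected_homozygote: bool = False

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "first_marker_id": self.first_marker_id,
            "last_marker_id": self.last_marker_id,
            "start_bp": self.start_bp,
            "end_bp": self.end_bp,
            "n_markers": self.n_markers,
            "shared_case_alleles": self.shared_case_alleles,
            "control_frequency": self.control_frequency,
            "labels": self.labels,
            "excluded_by_unaffected_homozygote":
                self.excluded_by_unaffected_homozygote,
        }


def nuclear_family(
    pedigree: Pedigree,
) -> tuple[Individual, Individual, list[Individual]]:
    """The (sire, dam, littermates) of the litter containing the affected.

    All affected individuals must belong to a single full-sib litter whose
    parents are in the pedigree.
    """
    affected = pedigree.affected
    if not affected:
        raise PedigreeError("pedigree contains no affected individual")
    parent_pairs = {(a.sire_id, a.dam_id) for a in affected}
    if len(parent_pairs) != 1 or None in next(iter(parent_pairs)):
        raise PedigreeError(
            "affected individuals must form one litter with known parents"
        )
    sire_id, dam_id = next(iter(parent_pairs))
    litter = pedigree.offspring_of(sire_id, dam_id)
    return pedigree[sire_id], pedigree[dam_id], litter


def controls_of(pedigree: Pedigree) -> list[str]:
    """Unaffected members of the nuclear family (parents + littermates)."""
    sire, dam, litter = nuclear_family(pedigree)
    return [
        i.id
        for i in [sire, dam, *litter]
        if i.phenotype is Phenotype.UNAFFECTED
    ]


def cases_of(pedigree: Pedigree) -> list[str]:
    return [i.id for i in pedigree.affected]


def risk_allele_freq(
    matrix: GenotypeMatrix,
    marker_id: str,
    group_ids: list[str],
    risk_allele: str,
) -> float:
    """Frequency of ``risk_allele`` among the called alleles of a group.

    Denominator is twice the number of *fully called* group members
    (missing calls shrink it).  Returns NaN when every call is missing —
    an undefined frequency, deliberately distinct from 0.
    """
    if not group_ids:
        raise ValueError("group is empty")
    n_called = 0
    n_risk = 0
    for ind in group_ids:
        call = matrix.call(ind, marker_id)
        if call is None:
            continue
        n_called += 1
        n_risk += sum(a == risk_allele for a in call)
    if n_called == 0:
        return math.nan
    return n_risk / (2 * n_called)


def derive_control_bounds(
    pedigree: Pedigree, rounding_decimals: int | None = None
) -> tuple[float, float]:
    """Admissible risk-allele frequency interval among the controls.

    Under fully penetrant autosomal recessive inheritance, both unaffected
    parents of an affected offspring are obligate heterozygotes (1 risk
    allele each) and every unaffected sibling carries 0 or 1 copies.  Over
    a control set of ``p`` obligate-carrier parents and ``s`` unaffected
    siblings the attainable frequency therefore ranges from ``p / (2(p+s))``
    (no sibling carries it) to ``(p+s) / (2(p+s))`` (every sibling is a
    carrier).  Unrounded values are returned unless ``rounding_decimals``
    is given.
    """
    sire, dam, litter = nuclear_family(pedigree)
    carrier_parents = [
        i for i in (sire, dam) if i.phenotype is Phenotype.UNAFFECTED
    ]
    unaffected_sibs = [
        i for i in litter if i.phenotype is Phenotype.UNAFFECTED
    ]
    n_controls = len(carrier_parents) + len(unaffected_sibs)
    if n_controls == 0:
        raise PedigreeError("no genotyped unaffected controls in the family")
    low = len(carrier_parents) / (2 * n_controls)
    high = (len(carrier_parents) + len(unaffected_sibs)) / (2 * n_controls)
    if rounding_decimals is not None:
        low = round(low, rounding_decimals)
        high = round(high, rounding_decimals)
    return low, high


def recessive_marker_filter(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Per-marker recessive-segregation decision table.

    A marker passes iff all cases are fully called and homozygous for one
    shared allele (case frequency equals ``case_freq_required``) and that
    allele's control frequency lies in the closed interval
    ``[low, high]`` — compared unrounded.  Returns a DataFrame indexed by
    marker id with columns ``chromosome, position_bp, kind, case_allele,
    case_freq, control_freq, passes``.
    """
    params = params or FilterParams()
    cases = cases_of(pedigree)
    if len([c for c in cases if c in matrix.individual_ids]) < 2:
        raise PedigreeError("need >=2 genotyped cases")
    controls = [
        c for c in controls_of(pedigree) if c in matrix.individual_ids
    ]
    if params.control_bounds is not None:
        low, high = params.control_bounds
    else:
        low, high = derive_control_bounds(pedigree)

    rows = []
    for marker in matrix.marker_map:
        case_allele = None
        case_freq = math.nan
        control_freq = math.nan
        passes = False
        calls = [matrix.call(c, marker.id) for c in cases]
        # A case with a missing call fails the marker (conservative).
        if all(call is not None for call in calls):
            homozygous = all(a == b for a, b in calls)
            shared = len({call[0] for call in calls}) == 1
            if homozygous and shared:
                case_allele = calls[0][0]
                case_freq = 1.0
                control_freq = risk_allele_freq(
                    matrix, marker.id, controls, case_allele
                )
                passes = (
                    case_freq == params.case_freq_required
                    and not math.isnan(control_freq)
                    and low <= control_freq <= high
                )
        rows.append(
            {
                "marker_id": marker.id,
                "chromosome": marker.chromosome,
                "position_bp": marker.position_bp,
                "kind": marker.kind,
                "case_allele": case_allele,
                "case_freq": case_freq,
                "control_freq": control_freq,
                "passes": passes,
            }
        )
    return pd.DataFrame(rows).set_index("marker_id")


def exclude_unaffected_homozygotes(
    matrix: GenotypeMatrix,
    pedigree: Pedigree,
    decisions: pd.DataFrame,
) -> pd.DataFrame:
    """Fail passing markers at which any unaffected nuclear-family member
    is homozygous for the shared case allele.

    This is the manual-examination step of the published procedure: a
    control frequency inside the admissible interval can still be produced
    by a single unaffected homozygote, which directly contradicts full
    penetrance.  Adds an ``excluded_unaffected_hom`` column and updates
    ``passes``.
    """
    decisions = decisions.copy()
    controls = [
        c for c in controls_of(pedigree) if c in matrix.individual_ids
    ]
    excluded = []
    for marker_id, row in decisions.iterrows():
        flag = False
        if row["passes"]:
            allele = row["case_allele"]
            for ind in controls:
                call = matrix.call(ind, marker_id)
                if call is not None and call == (allele, allele):
                    flag = True
                    break
        excluded.append(flag)
    decisions["excluded_unaffected_hom"] = excluded
    decisions["passes"] = decisions["passes"] & ~decisions[
        "excluded_unaffected_hom"
    ]
    return decisions


def extract_candidate_regions(
    decisions: pd.DataFrame,
    marker_map: MarkerMap,
    params: FilterParams | None = None,
    regions: list[Region] | None = None,
) -> list[CandidateRegion]:
    """Maximal runs of >= ``min_run_length`` consecutive passing SNP markers.

    When candidate-gene ``regions`` (BED, 0-based half-open) are supplied,
    only runs whose bp span intersects at least one region are reported,
    labeled with the genes hit.  Microsatellites are not part of runs (they
    are reserved for IBD verification) but do not break them either.
    """
    params = params or FilterParams()
    out: list[CandidateRegion] = []
    for chrom in marker_map.chromosomes:
        snps = [
            (i, m)
            for i, m in marker_map.on_chromosome(chrom)
            if m.kind == "snp"
        ]
        has_excl = "excluded_unaffected_hom" in decisions.columns

        def _is_excluded(marker_id: str) -> bool:
            return has_excl and bool(
                decisions.loc[marker_id, "excluded_unaffected_hom"]
            )

        run: list = []
        for pos_in_chrom, (idx, marker) in enumerate(snps + [(None, None)]):
            row = decisions.loc[marker.id] if marker is not None else None
            if row is not None and bool(row["passes"]):
                run.append((marker, row))
                continue
            if len(run) >= params.min_run_length:
                first, last = run[0][0], run[-1][0]
                # Note when the run was bounded by a marker knocked out by
                # the unaffected-homozygote rule rather than by the
                # frequency filter itself.
                start_in_chrom = pos_in_chrom - len(run)
                neighbours = []
                if start_in_chrom > 0:
                    neighbours.append(snps[start_in_chrom - 1][1].id)
                if pos_in_chrom < len(snps):
                    neighbours.append(snps[pos_in_chrom][1].id)
                span_excluded = any(_is_excluded(n) for n in neighbours)
                freqs = [r["control_freq"] for _, r in run]
                candidate = CandidateRegion(
                    chromosome=chrom,
                    first_marker_id=first.id,
                    last_marker_id=last.id,
                    start_bp=first.position_bp,
                    end_bp=last.position_bp,
                    n_markers=len(run),
                    shared_case_alleles={
                        m.id: r["case_allele"] for m, r in run
                    },
                    control_frequency=float(sum(freqs) / len(freqs)),
                    excluded_by_unaffected_homozygote=span_excluded,
                )
                if regions is not None:
                    hits = [
                        r.label or f"{r.chromosome}:{r.start_bp}-{r.end_bp}"
                        for r in regions
                        if r.chromosome == chrom
                        and r.overlaps_span(
                            candidate.start_bp, candidate.end_bp
                        )
                    ]
                    if hits:
                        candidate.labels = hits
                        out.append(candidate)
                else:
                    out.append(candidate)
            run = []
    return out
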