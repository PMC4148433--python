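"""Gene-drop simulator for a linebred nuclear family.

Founder haplotypes are dropped through the pedigree meiosis by meiosis under
a Haldane recombination model (Poisson crossovers, no interference, uniform
cM-to-bp scaling).  One founder haplotype carries a planted recessive causal
allele, and the drop is conditioned — by rejection resampling of the causal
chromosome's meioses — so that exactly the pedigree's affected individuals
are homozygous for it.  The full founder origin of every transmitted segment
is recorded as truth, which is what lets tests verify that the downstream
segregation filter and IBD logic recover the planted locus.

The default configuration emulates the study design this package targets:
a linebred dog family whose sire and dam share two recent common ancestors,
a litter of 7 genotyped offspring of which 2 are affected, dense biallelic
SNPs (a desk-scale stand-in for a ~170k genome-wide array), and sparse
highly polymorphic microsatellites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pedigree_io import (
    MISSING_ALLELE,
    GenotypeMatrix,
    Individual,
    Marker,
    MarkerMap,
    Pedigree,
    Phenotype,
    Sex,
)

CAUSAL_MARKER_ID = "CAUSAL"
CAUSAL_REF = "T"   # wild-type allele at the planted locus
CAUSAL_ALT = "C"   # recessive causal allele (echoes a T>C substitution)

BP_PER_CM = 1_000_000  # uniform map: 1 cM per Mb


class SimulationError(RuntimeError):
    """Conditioning on the affection pattern failed within the round bound."""


@dataclass
class SimConfig:
    """Configuration of one simulated family dataset.

    The defaults are the study conditions: six ~100 Mb chromosomes (named
    after candidate-gene-bearing canine chromosomes), 150 SNPs and 4
    microsatellites per chromosome, SNP founder allele frequencies uniform
    on [0.05, 0.95], 6 equifrequent microsatellite alleles, the causal locus
    mid-chromosome "23", and no genotyping error.
    """

    seed: int = 0
    n_chromosomes: int = 6
    chromosome_length_cM: float = 100.0
    n_snps_per_chromosome: int = 150
    n_microsatellites_per_chromosome: int = 4
    founder_allele_freq_range: tuple[float, float] = (0.05, 0.95)
    microsatellite_allele_count: int = 6
    causal_locus: tuple[str, int] = ("23", 50_000_000)
    microsatellite_positions: dict | None = None
    chromosome_names: tuple[str, ...] | None = ("3", "5", "23", "25", "28", "36")
    causal_founder_haplotype: tuple[str, int] | None = None
    pedigree_template: str = "labrador_fig1"
    genotyping_error_rate: float = 0.0
    max_conditioning_rounds: int = 10_000

    def __post_init__(self) -> None:
        if self.chromosome_names is None:
            self.chromosome_names = tuple(
                str(i + 1) for i in range(self.n_chromosomes)
            )
        self.chromosome_names = tuple(self.chromosome_names)
        if len(self.chromosome_names) != self.n_chromosomes:
            raise ValueError("chromosome_names length != n_chromosomes")
        if min(
            self.n_chromosomes,
            self.n_snps_per_chromosome,
            self.microsatellite_allele_count,
        ) < 1:
            raise ValueError("all counts must be positive")
        if self.microsatellite_allele_count < 4:
            raise ValueError("microsatellite_allele_count must be >= 4")
        if not 0.0 <= self.genotyping_error_rate <= 1.0:
            raise ValueError("genotyping_error_rate must be in [0, 1]")
        chrom, pos = self.causal_locus
        if chrom not in self.chromosome_names:
            raise ValueError(f"causal chromosome {chrom!r} not simulated")
        if not 1 <= pos <= self.chromosome_length_bp:
            raise ValueError("causal locus outside its chromosome")
        if self.microsatellite_positions is not None:
            self.microsatellite_positions = {
                c: tuple(sorted({int(p) for p in ps}))
                for c, ps in self.microsatellite_positions.items()
            }
            for c, ps in self.microsatellite_positions.items():
                if c not in self.chromosome_names:
                    raise ValueError(f"microsatellite chromosome {c!r} not simulated")
                if ps and not (1 <= ps[0] and ps[-1] <= self.chromosome_length_bp):
                    raise ValueError("microsatellite position outside chromosome")

    @property
    def chromosome_length_bp(self) -> int:
        return int(round(self.chromosome_length_cM * BP_PER_CM))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_cM": self.chromosome_length_cM,
            "n_snps_per_chromosome": self.n_snps_per_chromosome,
            "n_microsatellites_per_chromosome": self.n_microsatellites_per_chromosome,
            "founder_allele_freq_range": list(self.founder_allele_freq_range),
            "microsatellite_allele_count": self.microsatellite_allele_count,
            "microsatellite_positions": (
                {c: list(ps) for c, ps in self.microsatellite_positions.items()}
                if self.microsatellite_positions is not None
                else None
            ),
            "causal_locus": [self.causal_locus[0], self.causal_locus[1]],
            "chromosome_names": list(self.chromosome_names),
            "causal_founder_haplotype": (
                list(self.causal_founder_haplotype)
                if self.causal_founder_haplotype
                else None
            ),
            "pedigree_template": self.pedigree_template,
            "genotyping_error_rate": self.genotyping_error_rate,
            "max_conditioning_rounds": self.max_conditioning_rounds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("founder_allele_freq_range", "causal_locus",
                    "chromosome_names", "causal_founder_haplotype"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Pedigree template
# ---------------------------------------------------------------------------

def build_fig1_pedigree() -> Pedigree:
    """Multigenerational linebred pedigree: the sire and dam share exactly
    two common ancestors (their grandparents ``anc1``/``anc2``), and the
    final litter has 7 genotyped offspring of which 2 are affected.

    The 9-member nuclear profiling set (both parents + 7 littermates) is
    recorded in ``metadata["nuclear_family"]``.
    """
    inds = [
        # the two recent common ancestors
        Individual("anc1", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
        Individual("anc2", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
        # unrelated founder mates
        Individual("gm1", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
        Individual("gp2", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
        # two offspring of the common-ancestor pair
        Individual("gp1", "anc1", "anc2", Sex.MALE, Phenotype.UNAFFECTED),
        Individual("gm2", "anc1", "anc2", Sex.FEMALE, Phenotype.UNAFFECTED),
        # parents of the litter (first cousins)
        Individual("sire", "gp1", "gm1", Sex.MALE, Phenotype.UNAFFECTED),
        Individual("dam", "gp2", "gm2", Sex.FEMALE, Phenotype.UNAFFECTED),
    ]
    litter = []
    for i in range(1, 8):
        litter.append(
            Individual(
                f"pup{i}",
                "sire",
                "dam",
                Sex.MALE if i % 2 else Sex.FEMALE,
                Phenotype.AFFECTED if i <= 2 else Phenotype.UNAFFECTED,
            )
        )
    ped = Pedigree(
        inds + litter,
        metadata={
            "nuclear_family": ["sire", "dam"] + [p.id for p in litter],
            "template": "labrador_fig1",
        },
    )
    return ped


# ---------------------------------------------------------------------------
# Meiosis under Haldane
# ---------------------------------------------------------------------------

def meiosis_mosaic(
    length_cM: float, rng: np.random.Generator
) -> list[tuple[float, float, int]]:
    """One gamete's parental-copy mosaic over ``[0, length_cM)``.

    Crossover count is Poisson(length_cM / 100) with uniform positions
    (Haldane, no interference); the starting parental copy is fair.
    Returns ``(start_cM, end_cM, copy)`` segments tiling the chromosome.
    """
    n_xo = rng.poisson(length_cM / 100.0)
    cuts = np.sort(rng.uniform(0.0, length_cM, size=n_xo))
    copy = int(rng.integers(2))
    bounds = [0.0, *cuts.tolist(), length_cM]
    segments = []
    for i in range(len(bounds) - 1):
        if bounds[i] < bounds[i + 1]:
            segments.append((bounds[i], bounds[i + 1], (copy + i) % 2))
    return segments


def copy_at(
    mosaic: Sequence[tuple[float, float, int]], position_cM: float
) -> int:
    """Parental copy transmitted at a cM position of a gamete mosaic."""
    for s, e, c in mosaic:
        if s <= position_cM < e:
            return c
    return mosaic[-1][2]


def _mosaic_to_bp(
    mosaic: Sequence[tuple[float, float, int]], length_bp: int
) -> list[tuple[int, int, int]]:
    out = []
    for s, e, c in mosaic:
        sb = int(round(s * BP_PER_CM))
        eb = int(round(e * BP_PER_CM))
        sb, eb = min(sb, length_bp), min(eb, length_bp)
        if sb < eb:
            out.append((sb, eb, c))
    if out:
        out[-1] = (out[-1][0], length_bp, out[-1][2])
    else:
        out = [(0, length_bp, 0)]
    return out


def _compose(
    parent_mosaics: tuple[list, list], gamete_bp: Sequence[tuple[int, int, int]]
) -> list[tuple[int, int, str]]:
    """Founder-origin mosaic of a gamete given the parent's two mosaics."""
    out: list[tuple[int, int, str]] = []
    for s, e, c in gamete_bp:
        for ps, pe, fh in parent_mosaics[c]:
            a, b = max(s, ps), min(e, pe)
            if a < b:
                out.append((a, b, fh))
    out.sort()
    merged: list[tuple[int, int, str]] = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def _fhid_at(segments: Sequence[tuple[int, int, str]], bp0: int) -> str:
    """Founder haplotype id at a 0-based bp offset."""
    for s, e, fh in segments:
        if s <= bp0 < e:
            return fh
    return segments[-1][2]


# ---------------------------------------------------------------------------
# Truth record
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth of one simulation.

    ``mosaics[ind][chrom]`` holds the founder-origin segment lists for the
    individual's (paternal, maternal) chromosome copies; segments are
    0-based half-open ``(start_bp, end_bp, founder_haplotype_id)`` tiling
    ``[0, chromosome_length_bp)``.  ``founder_hap_alleles[fhid][chrom]`` is
    the allele carried by that founder haplotype at each of the
    chromosome's markers, in map order.
    """

    mosaics: dict
    founder_hap_alleles: dict
    chromosome_lengths_bp: dict
    causal_locus: tuple[str, int]
    causal_fhid: str
    marker_ids_by_chrom: dict = field(default_factory=dict)

    def founder_hap_at(self, ind_id: str, chrom: str, bp_1based: int,
                       copy: int) -> str:
        return _fhid_at(self.mosaics[ind_id][chrom][copy], bp_1based - 1)

    def causal_copy_flags(self, ind_id: str) -> tuple[bool, bool]:
        chrom, pos = self.causal_locus
        return tuple(
            self.founder_hap_at(ind_id, chrom, pos, c) == self.causal_fhid
            for c in (0, 1)
        )

    def causal_genotype(self, ind_id: str) -> int:
        """Number of causal-allele copies carried (0, 1 or 2)."""
        return sum(self.causal_copy_flags(ind_id))

    def allele(self, ind_id: str, copy: int, chrom: str,
               chrom_marker_index: int, bp_1based: int) -> str:
        fhid = self.founder_hap_at(ind_id, chrom, bp_1based, copy)
        return self.founder_hap_alleles[fhid][chrom][chrom_marker_index]

    def ibd_over_span(
        self, chrom: str, start_bp: int, end_bp: int, ind_ids: Sequence[str]
    ) -> bool:
        """True iff one single founder haplotype underlies every chromosome
        copy of every listed individual across the whole 1-based closed span
        ``[start_bp, end_bp]``."""
        s0, e0 = start_bp - 1, end_bp  # 0-based half-open
        fhids: set[str] | None = None
        for ind in ind_ids:
            for c in (0, 1):
                covering = {
                    fh
                    for s, e, fh in self.mosaics[ind][chrom][c]
                    if s < e0 and e > s0
                }
                if len(covering) != 1:
                    return False
                fhids = covering if fhids is None else fhids & covering
        return fhids is not None and len(fhids) == 1

    def ibd_at(self, chrom: str, bp_1based: int, ind_ids: Sequence[str]) -> bool:
        """True iff every chromosome copy of every listed individual at the
        position descends from one and the same founder haplotype."""
        fhids = {
            self.founder_hap_at(i, chrom, bp_1based, c)
            for i in ind_ids
            for c in (0, 1)
        }
        return len(fhids) == 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "mosaics": self.mosaics,
                "founder_hap_alleles": {
                    fh: {c: list(a) for c, a in per.items()}
                    for fh, per in self.founder_hap_alleles.items()
                },
                "chromosome_lengths_bp": self.chromosome_lengths_bp,
                "causal_locus": list(self.causal_locus),
                "causal_fhid": self.causal_fhid,
                "marker_ids_by_chrom": self.marker_ids_by_chrom,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        mosaics = {
            ind: {
                chrom: [
                    [tuple(seg) for seg in copy_segs] for copy_segs in copies
                ]
                for chrom, copies in per.items()
            }
            for ind, per in d["mosaics"].items()
        }
        return cls(
            mosaics=mosaics,
            founder_hap_alleles=d["founder_hap_alleles"],
            chromosome_lengths_bp=d["chromosome_lengths_bp"],
            causal_locus=(d["causal_locus"][0], int(d["causal_locus"][1])),
            causal_fhid=d["causal_fhid"],
            marker_ids_by_chrom=d.get("marker_ids_by_chrom", {}),
        )


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------

def _make_marker_map(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    markers = []
    L = config.chromosome_length_bp
    causal_chrom, causal_pos = config.causal_locus
    explicit_ms = config.microsatellite_positions
    for chrom in config.chromosome_names:
        n_snp = config.n_snps_per_chromosome
        if explicit_ms is not None:
            fixed_ms = list(explicit_ms.get(chrom, ()))
            n_ms = 0
        else:
            fixed_ms = []
            n_ms = config.n_microsatellites_per_chromosome
        taken = set(fixed_ms)
        if chrom == causal_chrom:
            taken.add(causal_pos)
        positions: set[int] = set()
        while len(positions) < n_snp + n_ms:
            draw = rng.integers(1, L + 1, size=n_snp + n_ms - len(positions))
            positions.update(int(p) for p in draw if int(p) not in taken)
        pos_sorted = sorted(positions)[: n_snp + n_ms]
        snp_pos = sorted(
            rng.choice(pos_sorted, size=n_snp, replace=False).tolist()
        )
        ms_pos = sorted(set(pos_sorted) - set(snp_pos) | set(fixed_ms))
        for i, p in enumerate(snp_pos):
            a1, a2 = (str(b) for b in
                      rng.choice(list("ACGT"), size=2, replace=False))
            markers.append(
                Marker(
                    id=f"snp_{chrom}_{i:04d}",
                    chromosome=chrom,
                    position_bp=int(p),
                    kind="snp",
                    alleles=tuple(sorted((a1, a2))),
                )
            )
        for i, p in enumerate(ms_pos):
            sizes = tuple(
                str(150 + 4 * k)
                for k in range(config.microsatellite_allele_count)
            )
            markers.append(
                Marker(
                    id=f"ms_{chrom}_{i:02d}",
                    chromosome=chrom,
                    position_bp=int(p),
                    kind="microsatellite",
                    alleles=sizes,
                )
            )
        if chrom == causal_chrom:
            markers.append(
                Marker(
                    id=CAUSAL_MARKER_ID,
                    chromosome=chrom,
                    position_bp=causal_pos,
                    kind="snp",
                    alleles=tuple(sorted((CAUSAL_REF, CAUSAL_ALT))),
                )
            )
    return MarkerMap(markers)


def _draw_founder_alleles(
    config: SimConfig,
    marker_map: MarkerMap,
    founder_hap_ids: list[str],
    rng: np.random.Generator,
) -> dict:
    """Per founder haplotype and chromosome, alleles at every marker."""
    lo, hi = config.founder_allele_freq_range
    out: dict[str, dict[str, np.ndarray]] = {fh: {} for fh in founder_hap_ids}
    for chrom in config.chromosome_names:
        chrom_markers = [m for _, m in marker_map.on_chromosome(chrom)]
        n = len(chrom_markers)
        per_hap = {fh: np.empty(n, dtype=object) for fh in founder_hap_ids}
        for j, marker in enumerate(chrom_markers):
            if marker.id == CAUSAL_MARKER_ID:
                for fh in founder_hap_ids:
                    per_hap[fh][j] = CAUSAL_REF
            elif marker.kind == "snp":
                p = rng.uniform(lo, hi)
                draws = rng.random(len(founder_hap_ids)) < p
                for fh, take_first in zip(founder_hap_ids, draws):
                    per_hap[fh][j] = marker.alleles[0 if take_first else 1]
            else:
                idx = rng.integers(len(marker.alleles),
                                   size=len(founder_hap_ids))
                for fh, k in zip(founder_hap_ids, idx):
                    per_hap[fh][j] = marker.alleles[int(k)]
        for fh in founder_hap_ids:
            out[fh][chrom] = per_hap[fh]
    return out


def _drop_chromosome(
    pedigree: Pedigree,
    chrom_length_bp: int,
    length_cM: float,
    rng: np.random.Generator,
) -> dict:
    """One gene drop of a single chromosome: founder-origin mosaics."""
    mosaics: dict[str, list] = {}
    for ind in pedigree:
        if ind.is_founder:
            mosaics[ind.id] = [
                [(0, chrom_length_bp, f"{ind.id}:0")],
                [(0, chrom_length_bp, f"{ind.id}:1")],
            ]
        else:
            copies = []
            for parent in (ind.sire_id, ind.dam_id):
                gamete = _mosaic_to_bp(
                    meiosis_mosaic(length_cM, rng), chrom_length_bp
                )
                copies.append(_compose(tuple(mosaics[parent]), gamete))
            mosaics[ind.id] = copies
    return mosaics


def _affection_pattern_ok(
    pedigree: Pedigree,
    chrom_mosaics: dict,
    causal_pos: int,
    causal_fhid: str,
) -> bool:
    for ind in pedigree:
        n_causal = sum(
            _fhid_at(chrom_mosaics[ind.id][c], causal_pos - 1) == causal_fhid
            for c in (0, 1)
        )
        if ind.phenotype is Phenotype.AFFECTED and n_causal != 2:
            return False
        if ind.phenotype is Phenotype.UNAFFECTED and n_causal == 2:
            return False
    return True


def simulate(
    config: SimConfig, pedigree: Pedigree | None = None
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Run one conditioned gene drop.

    Returns the unphased genotype matrix for all pedigree members and the
    :class:`TruthRecord` of founder origins.  Chromosomes segregate
    independently, so conditioning on the affection pattern resamples only
    the causal chromosome's meioses (bounded rounds; exact rejection
    sampling).
    """
    if pedigree is None:
        if config.pedigree_template != "labrador_fig1":
            raise ValueError(
                "custom pedigree_template requires an explicit pedigree"
            )
        pedigree = build_fig1_pedigree()

    ss = np.random.SeedSequence(config.seed)
    rng_map, rng_founder, rng_drop, rng_err = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    marker_map = _make_marker_map(config, rng_map)
    founder_hap_ids = [
        f"{f.id}:{c}" for f in pedigree.founders for c in (0, 1)
    ]
    founder_alleles = _draw_founder_alleles(
        config, marker_map, founder_hap_ids, rng_founder
    )

    causal_chrom, causal_pos = config.causal_locus
    if config.causal_founder_haplotype is not None:
        fid, copy = config.causal_founder_haplotype
        causal_fhid = f"{fid}:{copy}"
    elif "anc1" in pedigree:
        causal_fhid = "anc1:0"
    else:
        causal_fhid = f"{pedigree.founders[0].id}:0"
    if causal_fhid not in founder_hap_ids:
        raise ValueError(f"unknown causal founder haplotype {causal_fhid!r}")
    causal_chrom_markers = marker_map.on_chromosome(causal_chrom)
    causal_j = next(
        j
        for j, (_, m) in enumerate(causal_chrom_markers)
        if m.id == CAUSAL_MARKER_ID
    )
    founder_alleles[causal_fhid][causal_chrom][causal_j] = CAUSAL_ALT

    L = config.chromosome_length_bp
    mosaics: dict[str, dict[str, list]] = {ind.id: {} for ind in pedigree}
    for chrom in config.chromosome_names:
        if chrom == causal_chrom:
            for round_no in range(config.max_conditioning_rounds):
                drop = _drop_chromosome(
                    pedigree, L, config.chromosome_length_cM, rng_drop
                )
                if _affection_pattern_ok(pedigree, drop, causal_pos,
                                         causal_fhid):
                    break
            else:
                raise SimulationError(
                    f"affection pattern not realized within "
                    f"{config.max_conditioning_rounds} resampling rounds; "
                    f"try a different seed"
                )
        else:
            drop = _drop_chromosome(
                pedigree, L, config.chromosome_length_cM, rng_drop
            )
        for ind_id, copies in drop.items():
            mosaics[ind_id][chrom] = copies

    # Genotypes from mosaics.
    ind_ids = pedigree.ids
    calls = np.empty((len(ind_ids), len(marker_map), 2), dtype=object)
    for chrom in config.chromosome_names:
        chrom_markers = marker_map.on_chromosome(chrom)
        positions0 = np.array([m.position_bp - 1 for _, m in chrom_markers])
        for i, ind_id in enumerate(ind_ids):
            for c in (0, 1):
                segs = mosaics[ind_id][chrom][c]
                ends = np.array([e for _, e, _ in segs])
                seg_idx = np.searchsorted(ends, positions0, side="right")
                seg_idx = np.minimum(seg_idx, len(segs) - 1)
                for local_j, (global_j, _m) in enumerate(chrom_markers):
                    fhid = segs[int(seg_idx[local_j])][2]
                    calls[i, global_j, c] = (
                        founder_alleles[fhid][chrom][local_j]
                    )

    # Genotyping errors: symmetric allele flip per call allele.
    e = config.genotyping_error_rate
    if e > 0:
        for global_j, marker in enumerate(marker_map):
            others = {
                a: [b for b in marker.alleles if b != a]
                for a in marker.alleles
            }
            if all(len(v) == 0 for v in others.values()):
                continue
            for i in range(len(ind_ids)):
                for c in (0, 1):
                    if rng_err.random() < e:
                        alts = others[calls[i, global_j, c]]
                        if alts:
                            calls[i, global_j, c] = alts[
                                int(rng_err.integers(len(alts)))
                            ]

    matrix = GenotypeMatrix(marker_map, ind_ids, calls)
    truth = TruthRecord(
        mosaics=mosaics,
        founder_hap_alleles=founder_alleles,
        chromosome_lengths_bp={c: L for c in config.chromosome_names},
        causal_locus=(causal_chrom, causal_pos),
        causal_fhid=causal_fhid,
        marker_ids_by_chrom={
            chrom: [m.id for _, m in marker_map.on_chromosome(chrom)]
            for chrom in config.chromosome_names
        },
    )
    return matrix, truth


def plant_obligate_carriers(pedigree: Pedigree, truth: TruthRecord) -> Pedigree:
    """Annotate ancestors on a causal-allele transmission path to an
    affected individual as obligate carriers (``metadata["obligate_carriers"]``).

    An ancestor is on the path iff it carries the causal founder haplotype
    at the causal locus and lies between the carrier founder and an affected
    individual; affected individuals themselves are not flagged.
    """
    carriers: set[str] = set()
    for affected in pedigree.affected:
        stack = [affected.id]
        seen = set()
        while stack:
            iid = stack.pop()
            if iid in seen:
                continue
            seen.add(iid)
            ind = pedigree[iid]
            if ind.is_founder:
                continue
            for parent in (ind.sire_id, ind.dam_id):
                if truth.causal_genotype(parent) >= 1:
                    if pedigree[parent].phenotype is not Phenotype.AFFECTED:
                        carriers.add(parent)
                    stack.append(parent)
    pedigree.metadata["obligate_carriers"] = sorted(carriers)
    return pedigree
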