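"""Data model and file I/O for pedigrees, markers, and genotypes.

File formats are the PLINK *text* dialect (PED/MAP and FAM-style pedigree
files) and 3/4-column BED for candidate-gene regions.  Genomic positions are
stored 1-based as in MAP files; BED regions keep their native 0-based
half-open convention, and the conversion between the two happens exactly
once, at the region-intersection boundary in :mod:`pedscan.segregation_scan`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

MISSING_ALLELE = "0"

SNP_ALLELES = frozenset("ACGT")


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unresolved parent, cycle, ...)."""


class FormatError(ValueError):
    """Malformed input file."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


# PLINK numeric codes <-> enums (bijective on the documented code sets).
_SEX_FROM_CODE = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_FROM_CODE = {
    "2": Phenotype.AFFECTED,
    "1": Phenotype.UNAFFECTED,
    "0": Phenotype.UNKNOWN,
    "-9": Phenotype.UNKNOWN,
}
_PHENO_TO_CODE = {
    Phenotype.AFFECTED: "2",
    Phenotype.UNAFFECTED: "1",
    Phenotype.UNKNOWN: "0",
}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``sire_id``/``dam_id`` are both ``None`` for founders and both set for
    non-founders; half-known parentage is rejected.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN

    def __post_init__(self) -> None:
        if (self.sire_id is None) != (self.dam_id is None):
            raise PedigreeError(
                f"individual {self.id!r}: sire and dam must both be "
                "present or both absent"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None


class Pedigree:
    """An ordered collection of individuals forming a valid family graph.

    Validated on construction: parent references resolve, no individual is
    its own ancestor, and at least one founder exists.  Iteration order is a
    topological order (parents before offspring).
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        metadata: dict | None = None,
    ) -> None:
        members = list(individuals)
        by_id = {}
        for ind in members:
            if ind.id in by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            by_id[ind.id] = ind
        for ind in members:
            for parent in (ind.sire_id, ind.dam_id):
                if parent is not None and parent not in by_id:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent "
                        f"{parent!r}"
                    )
        self._by_id = by_id
        self._order = self._toposort(members)
        if not any(i.is_founder for i in members):
            raise PedigreeError("pedigree has no founder")
        self.metadata: dict = dict(metadata or {})

    def _toposort(self, members: list[Individual]) -> list[Individual]:
        order: list[Individual] = []
        state: dict[str, int] = {}  # 0 in progress, 1 done

        def visit(ind: Individual, chain: tuple[str, ...]) -> None:
            if state.get(ind.id) == 1:
                return
            if state.get(ind.id) == 0:
                raise PedigreeError(
                    f"cyclic ancestry involving {ind.id!r} "
                    f"(path {' -> '.join(chain)})"
                )
            state[ind.id] = 0
            if not ind.is_founder:
                visit(self._by_id[ind.sire_id], chain + (ind.id,))
                visit(self._by_id[ind.dam_id], chain + (ind.id,))
            state[ind.id] = 1
            order.append(ind)

        for ind in members:
            visit(ind, ())
        return order

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._order)

    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._order == other._order

    @property
    def ids(self) -> list[str]:
        return [i.id for i in self._order]

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self._order if i.is_founder]

    @property
    def affected(self) -> list[Individual]:
        return [i for i in self._order if i.phenotype is Phenotype.AFFECTED]

    @property
    def unaffected(self) -> list[Individual]:
        return [i for i in self._order if i.phenotype is Phenotype.UNAFFECTED]

    def offspring_of(self, sire_id: str, dam_id: str) -> list[Individual]:
        return [
            i
            for i in self._order
            if i.sire_id == sire_id and i.dam_id == dam_id
        ]

    def ancestors_of(self, ind_id: str) -> set[str]:
        """All ancestor ids of ``ind_id`` (excluding itself)."""
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            ind = self._by_id[stack.pop()]
            for parent in (ind.sire_id, ind.dam_id):
                if parent is not None and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out


@dataclass(frozen=True)
class Marker:
    """A genotyped locus: biallelic SNP or multiallelic microsatellite."""

    id: str
    chromosome: str
    position_bp: int
    kind: str  # "snp" | "microsatellite"
    alleles: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise FormatError(
                f"marker {self.id!r}: position must be >= 1 (1-based)"
            )
        if self.kind not in ("snp", "microsatellite"):
            raise FormatError(f"marker {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "snp":
            bad = set(self.alleles) - SNP_ALLELES
            if bad:
                raise FormatError(
                    f"marker {self.id!r}: SNP alleles must be A/C/G/T, "
                    f"got {sorted(bad)}"
                )
            if len(self.alleles) > 2:
                raise FormatError(
                    f"marker {self.id!r}: SNP has >2 alleles {self.alleles}"
                )


def _chrom_key(chrom: str) -> tuple[int, int | str]:
    """Numeric-aware chromosome sort key (chr2 before chr10)."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (0, int(m.group(1)))
    return (1, chrom)


class MarkerMap:
    """Ordered marker list, strictly increasing in (chromosome, position)."""

    def __init__(self, markers: Iterable[Marker]) -> None:
        ms = sorted(
            markers, key=lambda m: (_chrom_key(m.chromosome), m.position_bp)
        )
        for a, b in zip(ms, ms[1:]):
            if a.chromosome == b.chromosome and a.position_bp == b.position_bp:
                raise FormatError(
                    f"duplicate position {a.chromosome}:{a.position_bp} "
                    f"(markers {a.id!r}, {b.id!r})"
                )
        ids = [m.id for m in ms]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate marker ids in map")
        self._markers = ms
        self._index = {m.id: i for i, m in enumerate(ms)}

    def __iter__(self) -> Iterator[Marker]:
        return iter(self._markers)

    def __len__(self) -> int:
        return len(self._markers)

    def __getitem__(self, i: int) -> Marker:
        return self._markers[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return self._markers == other._markers

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    def get(self, marker_id: str) -> Marker:
        return self._markers[self._index[marker_id]]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._index

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self._markers]

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self._markers:
            seen.setdefault(m.chromosome, None)
        return list(seen)

    def on_chromosome(self, chrom: str) -> list[tuple[int, Marker]]:
        """(map index, marker) pairs for one chromosome, in position order."""
        return [
            (i, m)
            for i, m in enumerate(self._markers)
            if m.chromosome == chrom
        ]


class GenotypeMatrix:
    """Unphased diploid calls for markers x individuals.

    Calls are stored as an ``(n_individuals, n_markers, 2)`` array of allele
    symbols, each pair canonically sorted (calls are unordered); missing is
    ``("0", "0")`` — half-missing calls are rejected.
    """

    def __init__(
        self,
        marker_map: MarkerMap,
        individual_ids: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=object)
        if calls.shape != (len(individual_ids), len(marker_map), 2):
            raise FormatError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(individual_ids)} individuals x {len(marker_map)} markers"
            )
        canon = calls.copy()
        for i, ind in enumerate(individual_ids):
            for j, marker in enumerate(marker_map):
                a, b = calls[i, j]
                if (a == MISSING_ALLELE) != (b == MISSING_ALLELE):
                    raise FormatError(
                        f"half-missing call for individual {ind!r} at marker "
                        f"{marker.id!r}: {a!r}/{b!r}"
                    )
                if a != MISSING_ALLELE:
                    for sym in (a, b):
                        if marker.alleles and sym not in marker.alleles:
                            raise FormatError(
                                f"allele {sym!r} not in allele set of marker "
                                f"{marker.id!r}"
                            )
                if b < a:
                    a, b = b, a
                canon[i, j, 0], canon[i, j, 1] = a, b
        self.marker_map = marker_map
        self.individual_ids = list(individual_ids)
        self._row = {ind: i for i, ind in enumerate(self.individual_ids)}
        self.calls = canon

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def call(self, ind_id: str, marker_id: str) -> tuple[str, str] | None:
        """Unordered allele pair, or None when the call is missing."""
        a, b = self.calls[self._row[ind_id], self.marker_map.index_of(marker_id)]
        if a == MISSING_ALLELE:
            return None
        return (a, b)

    def call_at(self, ind_id: str, marker_index: int) -> tuple[str, str] | None:
        a, b = self.calls[self._row[ind_id], marker_index]
        if a == MISSING_ALLELE:
            return None
        return (a, b)

    def __eq__(self, other: object) -> bool:
        """Equality on what PED/MAP encodes: marker identity/placement,
        individual order, and calls.  Allele *sets* are inferred from
        observed data on read, so they are deliberately not compared."""
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            [(m.id, m.chromosome, m.position_bp) for m in self.marker_map]
            == [(m.id, m.chromosome, m.position_bp) for m in other.marker_map]
            and self.individual_ids == other.individual_ids
            and bool(np.all(self.calls == other.calls))
        )


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open (BED convention)."""

    chromosome: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise FormatError(
                f"region {self.label or self.chromosome}: start "
                f"{self.start_bp} must be < end {self.end_bp}"
            )

    def contains_position(self, position_bp_1based: int) -> bool:
        """Membership of a 1-based marker position in this 0-based interval.

        The single 0/1-based conversion of the package happens here.
        """
        return self.start_bp < position_bp_1based <= self.end_bp

    def overlaps_span(self, start_bp_1based: int, end_bp_1based: int) -> bool:
        """Overlap with a closed 1-based span [start, end]."""
        return start_bp_1based <= self.end_bp and end_bp_1based > self.start_bp


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _tokenized_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if tokens and not tokens[0].startswith("#"):
                yield lineno, tokens


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PLINK FAM-style pedigree file.

    Columns: family, individual, sire, dam, sex, phenotype; ``0`` = missing
    parent; sex 1=male / 2=female / 0=unknown; phenotype 2=affected /
    1=unaffected / 0 or -9 = unknown.
    """
    individuals = []
    for lineno, tok in _tokenized_lines(path):
        if len(tok) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(tok)}")
        _fam, iid, sire, dam, sex, pheno = tok[:6]
        if sex not in _SEX_FROM_CODE:
            raise FormatError(f"{path}:{lineno}: bad sex code {sex!r}")
        if pheno not in _PHENO_FROM_CODE:
            raise FormatError(f"{path}:{lineno}: bad phenotype code {pheno!r}")
        individuals.append(
            Individual(
                id=iid,
                sire_id=None if sire == "0" else sire,
                dam_id=None if dam == "0" else dam,
                sex=_SEX_FROM_CODE[sex],
                phenotype=_PHENO_FROM_CODE[pheno],
            )
        )
    return Pedigree(individuals)


def write_pedigree(
    pedigree: Pedigree, path: str | Path, family_id: str = "FAM1"
) -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [
                        family_id,
                        ind.id,
                        ind.sire_id or "0",
                        ind.dam_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        _PHENO_TO_CODE[ind.phenotype],
                    ]
                )
                + "\n"
            )


def _read_map(path: str | Path) -> list[tuple[str, str, int]]:
    rows = []
    for lineno, tok in _tokenized_lines(path):
        if len(tok) < 4:
            raise FormatError(f"{path}:{lineno}: MAP needs 4 columns")
        chrom, mid, _cm, bp = tok[:4]  # genetic distance ignored on read
        rows.append((chrom, mid, int(bp)))
    return rows


def read_genotypes(
    ped_path: str | Path, map_path: str | Path
) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeMatrix`.

    Marker kinds and allele sets are inferred from the data: a marker whose
    non-missing symbols are all single A/C/G/T letters is a SNP (at most two
    distinct symbols allowed, a third is an error); anything else is treated
    as a microsatellite, whose symbols (e.g. fragment sizes like ``"184"``)
    are accepted verbatim.
    """
    map_rows = _read_map(map_path)
    n_markers = len(map_rows)
    individuals: list[str] = []
    raw_calls: list[list[tuple[str, str]]] = []
    for lineno, tok in _tokenized_lines(ped_path):
        if len(tok) != 6 + 2 * n_markers:
            raise FormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} columns "
                f"(6 + 2 alleles x {n_markers} markers), got {len(tok)}"
            )
        iid = tok[1]
        row = []
        for j in range(n_markers):
            a, b = tok[6 + 2 * j], tok[7 + 2 * j]
            if (a == MISSING_ALLELE) != (b == MISSING_ALLELE):
                raise FormatError(
                    f"{ped_path}:{lineno}: half-missing call for individual "
                    f"{iid!r} at marker {map_rows[j][1]!r}"
                )
            row.append((a, b))
        individuals.append(iid)
        raw_calls.append(row)

    # Infer per-marker allele sets and kinds.
    markers = []
    for j, (chrom, mid, bp) in enumerate(map_rows):
        observed: dict[str, None] = {}
        for row in raw_calls:
            for sym in row[j]:
                if sym != MISSING_ALLELE:
                    observed.setdefault(sym, None)
        symbols = list(observed)
        is_snp = all(s in SNP_ALLELES for s in symbols)
        if is_snp and len(symbols) > 2:
            raise FormatError(
                f"marker {mid!r}: {len(symbols)} distinct SNP alleles "
                f"{sorted(symbols)} (max 2)"
            )
        markers.append(
            Marker(
                id=mid,
                chromosome=chrom,
                position_bp=bp,
                kind="snp" if is_snp else "microsatellite",
                alleles=tuple(sorted(symbols)),
            )
        )

    marker_map = MarkerMap(markers)
    # PED columns follow MAP file order; reorder to the sorted map order.
    perm = [map_rows.index((m.chromosome, m.id, m.position_bp)) for m in marker_map]
    calls = np.empty((len(individuals), n_markers, 2), dtype=object)
    for i, row in enumerate(raw_calls):
        for jj, src in enumerate(perm):
            calls[i, jj, 0], calls[i, jj, 1] = row[src]
    return GenotypeMatrix(marker_map, individuals, calls)


def write_genotypes(
    matrix: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    pedigree: Pedigree | None = None,
    family_id: str = "FAM1",
) -> None:
    """Write a PLINK text PED/MAP pair re-readable with no loss.

    When ``pedigree`` is given, its parent/sex/phenotype codes fill the PED
    leading columns; otherwise individuals are written as unknown founders.
    """
    with open(map_path, "w") as fh:
        for m in matrix.marker_map:
            fh.write(f"{m.chromosome}\t{m.id}\t0\t{m.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(matrix.individual_ids):
            if pedigree is not None and iid in pedigree:
                ind = pedigree[iid]
                lead = [
                    family_id,
                    iid,
                    ind.sire_id or "0",
                    ind.dam_id or "0",
                    _SEX_TO_CODE[ind.sex],
                    _PHENO_TO_CODE[ind.phenotype],
                ]
            else:
                lead = [family_id, iid, "0", "0", "0", "0"]
            alleles = [sym for pair in matrix.calls[i] for sym in pair]
            fh.write("\t".join(lead + alleles) + "\n")


def read_regions(path: str | Path) -> list[Region]:
    """Read a 3/4-column BED file (0-based half-open) of candidate regions."""
    regions = []
    for lineno, tok in _tokenized_lines(path):
        if len(tok) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
        chrom, start, end = tok[0], int(tok[1]), int(tok[2])
        if start >= end:
            raise FormatError(
                f"{path}:{lineno}: degenerate interval {chrom}:{start}-{end}"
            )
        regions.append(
            Region(
                chromosome=chrom,
                start_bp=start,
                end_bp=end,
                label=tok[3] if len(tok) > 3 else "",
            )
        )
    return regions


def write_regions(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(
            regions, key=lambda r: (_chrom_key(r.chromosome), r.start_bp)
        ):
            cols = [r.chromosome, str(r.start_bp), str(r.end_bp)]
            if r.label:
                cols.append(r.label)
            fh.write("\t".join(cols) + "\n")
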