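"""Shared fixtures: the linebred family and small simulated datasets."""

import numpy as np
import pytest

import pedscan as ps


@pytest.fixture(scope="session")
def fig1_pedigree():
    return ps.build_fig1_pedigree()


@pytest.fixture(scope="session")
def small_sim():
    """One default-condition simulation shared by read-only tests."""
    pedigree = ps.build_fig1_pedigree()
    config = ps.SimConfig(seed=42)
    matrix, truth = ps.simulate(config, pedigree)
    return config, pedigree, matrix, truth


def make_matrix(marker_defs, calls_by_individual):
    """Hand-build a GenotypeMatrix.

    marker_defs: list of (id, chrom, pos, kind, alleles)
    calls_by_individual: {ind_id: [(a, b) or None, ...]} in marker order.
    """
    markers = [
        ps.Marker(id=i, chromosome=c, position_bp=p, kind=k, alleles=tuple(a))
        for i, c, p, k, a in marker_defs
    ]
    marker_map = ps.MarkerMap(markers)
    ind_ids = list(calls_by_individual)
    calls = np.empty((len(ind_ids), len(markers), 2), dtype=object)
    order = {m.id: j for j, m in enumerate(marker_map)}
    for i, ind in enumerate(ind_ids):
        for orig_j, call in enumerate(calls_by_individual[ind]):
            j = order[markers[orig_j].id]
            if call is None:
                calls[i, j] = (ps.MISSING_ALLELE, ps.MISSING_ALLELE)
            else:
                calls[i, j] = call
    return ps.GenotypeMatrix(marker_map, ind_ids, calls)
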