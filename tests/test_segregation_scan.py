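"""Recessive segregation filter: frequencies, derived bounds, regions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pedscan as ps
from pedscan.fixtures import candidate_regions_for_simulation
from pedscan.synthetic_family import CAUSAL_MARKER_ID

from conftest import make_matrix


def family_with_carriers(n_carrier_sibs, n_wildtype_sibs, marker="m1"):
    """Nuclear family genotypes at one biallelic marker: 2 affected AA
    cases, 2 obligate-heterozygote parents, and unaffected sibs."""
    inds = [
        ps.Individual("sire", sex=ps.Sex.MALE,
                      phenotype=ps.Phenotype.UNAFFECTED),
        ps.Individual("dam", sex=ps.Sex.FEMALE,
                      phenotype=ps.Phenotype.UNAFFECTED),
    ]
    calls = {"sire": [("A", "G")], "dam": [("A", "G")]}
    k = 0
    for pheno, genotype, count in [
        (ps.Phenotype.AFFECTED, ("A", "A"), 2),
        (ps.Phenotype.UNAFFECTED, ("A", "G"), n_carrier_sibs),
        (ps.Phenotype.UNAFFECTED, ("G", "G"), n_wildtype_sibs),
    ]:
        for _ in range(count):
            k += 1
            inds.append(ps.Individual(f"pup{k}", "sire", "dam",
                                      phenotype=pheno))
            calls[f"pup{k}"] = [genotype]
    ped = ps.Pedigree(inds)
    matrix = make_matrix([(marker, "23", 100, "snp", "AG")], calls)
    return ped, matrix


class TestRiskAlleleFreq:
    def test_published_carrier_configuration_gives_0_36(self):
        """2 het parents + 3 carrier and 2 wild-type littermates carry the
        risk allele at 5/14 ~ 0.36 among the 7 controls."""
        ped, matrix = family_with_carriers(3, 2)
        controls = ps.segregation_scan.controls_of(ped)
        assert len(controls) == 7
        freq = ps.risk_allele_freq(matrix, "m1", controls, "A")
        assert freq == pytest.approx(5 / 14)
        assert round(freq, 2) == 0.36

    def test_all_homozygous_risk_gives_1(self):
        ped, matrix = family_with_carriers(0, 0)
        cases = ps.segregation_scan.cases_of(ped)
        assert ps.risk_allele_freq(matrix, "m1", cases, "A") == 1.0

    def test_all_missing_is_undefined_not_zero(self):
        matrix = make_matrix(
            [("m1", "1", 10, "snp", "AG")], {"x": [None], "y": [None]}
        )
        assert math.isnan(ps.risk_allele_freq(matrix, "m1", ["x", "y"], "A"))

    @settings(max_examples=200, deadline=None)
    @given(
        genotypes=st.lists(
            st.sampled_from([("A", "A"), ("A", "G"), ("G", "G"), None]),
            min_size=1, max_size=7,
        )
    )
    def test_matches_direct_counting_oracle(self, genotypes):
        ids = [f"i{k}" for k in range(len(genotypes))]
        matrix = make_matrix(
            [("m1", "1", 10, "snp", "AG")],
            {i: [g] for i, g in zip(ids, genotypes)},
        )
        called = [g for g in genotypes if g is not None]
        expected = (
            math.nan
            if not called
            else sum(a == "A" for g in called for a in g) / (2 * len(called))
        )
        got = ps.risk_allele_freq(matrix, "m1", ids, "A")
        assert (math.isnan(got) and math.isnan(expected)) or got == expected


def bounds_by_enumeration(n_carrier_parents, n_unaffected_sibs):
    """Enumerate every carrier/non-carrier assignment to unaffected sibs
    (each 0 or 1 risk alleles) and take min/max realized control frequency."""
    n_controls = n_carrier_parents + n_unaffected_sibs
    freqs = []
    for assignment in itertools.product((0, 1), repeat=n_unaffected_sibs):
        freqs.append(
            (n_carrier_parents + sum(assignment)) / (2 * n_controls)
        )
    return min(freqs), max(freqs)


class TestDeriveControlBounds:
    def test_published_family_interval(self, fig1_pedigree):
        low, high = ps.derive_control_bounds(fig1_pedigree)
        assert low == pytest.approx(2 / 14)
        assert high == pytest.approx(7 / 14)
        assert ps.derive_control_bounds(fig1_pedigree, 2) == (0.14, 0.50)

    def test_collapses_without_unaffected_sibs(self):
        ped, _ = family_with_carriers(0, 0)
        assert ps.derive_control_bounds(ped) == (0.5, 0.5)

    def test_no_affected_is_error(self):
        ped = ps.Pedigree([ps.Individual("a")])
        with pytest.raises(ps.PedigreeError):
            ps.derive_control_bounds(ped)

    @pytest.mark.parametrize("n_sibs", range(0, 13))
    def test_equals_enumeration_oracle(self, n_sibs):
        inds = [
            ps.Individual("sire", sex=ps.Sex.MALE,
                          phenotype=ps.Phenotype.UNAFFECTED),
            ps.Individual("dam", sex=ps.Sex.FEMALE,
                          phenotype=ps.Phenotype.UNAFFECTED),
            ps.Individual("case", "sire", "dam",
                          phenotype=ps.Phenotype.AFFECTED),
        ] + [
            ps.Individual(f"s{k}", "sire", "dam",
                          phenotype=ps.Phenotype.UNAFFECTED)
            for k in range(n_sibs)
        ]
        ped = ps.Pedigree(inds)
        assert ps.derive_control_bounds(ped) == bounds_by_enumeration(
            2, n_sibs
        )


class TestRecessiveMarkerFilter:
    def test_chr23_configuration_passes(self):
        ped, matrix = family_with_carriers(3, 2)
        decisions = ps.recessive_marker_filter(matrix, ped)
        row = decisions.loc["m1"]
        assert row["passes"]
        assert row["case_allele"] == "A"
        assert row["control_freq"] == pytest.approx(5 / 14)

    def test_heterozygous_case_fails(self):
        ped, matrix = family_with_carriers(3, 2)
        # make one case heterozygous
        i = matrix.individual_ids.index("pup1")
        matrix.calls[i, 0] = ("A", "G")
        decisions = ps.recessive_marker_filter(matrix, ped)
        assert not decisions.loc["m1", "passes"]

    def test_control_freq_below_lower_bound_fails(self):
        """Controls carrying fewer copies than the obligate-carrier parents
        imply is impossible under recessive IBD transmission; such markers
        (1/14 here, with a parent not carrying the case allele) fail."""
        ped, matrix = family_with_carriers(1, 4)
        i = matrix.individual_ids.index("sire")
        matrix.calls[i, 0] = ("G", "G")
        decisions = ps.recessive_marker_filter(matrix, ped)
        assert decisions.loc["m1", "control_freq"] == pytest.approx(2 / 14)
        # 2/14 equals the lower bound, so shift one more carrier out
        j = matrix.individual_ids.index("dam")
        matrix.calls[j, 0] = ("G", "G")
        decisions = ps.recessive_marker_filter(matrix, ped)
        assert decisions.loc["m1", "control_freq"] == pytest.approx(1 / 14)
        assert not decisions.loc["m1", "passes"]

    def test_case_missing_call_fails_conservatively(self):
        ped, matrix = family_with_carriers(3, 2)
        i = matrix.individual_ids.index("pup1")
        matrix.calls[i, 0] = ("0", "0")
        decisions = ps.recessive_marker_filter(matrix, ped)
        assert not decisions.loc["m1", "passes"]

    def test_widening_bounds_is_monotone(self, small_sim):
        """No passing marker is lost when the control interval widens."""
        _, pedigree, matrix, _ = small_sim
        narrow = ps.recessive_marker_filter(
            matrix, pedigree, ps.FilterParams(control_bounds=(2/14, 7/14))
        )
        wide = ps.recessive_marker_filter(
            matrix, pedigree, ps.FilterParams(control_bounds=(0.0, 1.0))
        )
        assert (narrow["passes"] <= wide["passes"]).all()


class TestUnaffectedHomozygoteExclusion:
    def test_unaffected_homozygote_fails_marker(self):
        ped, matrix = family_with_carriers(2, 3)
        # one "wild-type" sib is actually homozygous for the case allele;
        # 2 parents + 2 carriers + 1 hom = 6/14, inside the bounds
        i = matrix.individual_ids.index("pup7")
        matrix.calls[i, 0] = ("A", "A")
        decisions = ps.recessive_marker_filter(matrix, ped)
        assert decisions.loc["m1", "passes"]
        decisions = ps.exclude_unaffected_homozygotes(matrix, ped, decisions)
        assert decisions.loc["m1", "excluded_unaffected_hom"]
        assert not decisions.loc["m1", "passes"]

    def test_no_homozygotes_leaves_pass_set_unchanged(self):
        ped, matrix = family_with_carriers(3, 2)
        before = ps.recessive_marker_filter(matrix, ped)
        after = ps.exclude_unaffected_homozygotes(matrix, ped, before)
        assert (before["passes"] == after["passes"]).all()

    def test_causal_marker_never_excluded_on_simulations(self):
        """Full penetrance: an unaffected member is never homozygous for
        the planted allele, so the causal marker survives the exclusion."""
        for seed in range(10):
            ped = ps.build_fig1_pedigree()
            matrix, truth = ps.simulate(ps.SimConfig(seed=300 + seed), ped)
            decisions = ps.recessive_marker_filter(matrix, ped)
            decisions = ps.exclude_unaffected_homozygotes(
                matrix, ped, decisions
            )
            assert decisions.loc[CAUSAL_MARKER_ID, "passes"]
            assert not decisions.loc[CAUSAL_MARKER_ID,
                                     "excluded_unaffected_hom"]


class TestExtractCandidateRegions:
    def test_no_passing_markers_gives_empty_list(self, small_sim):
        _, pedigree, matrix, _ = small_sim
        decisions = ps.recessive_marker_filter(
            matrix, pedigree, ps.FilterParams(control_bounds=(0.99, 1.0))
        )
        decisions = decisions.assign(passes=False)
        assert ps.extract_candidate_regions(
            decisions, matrix.marker_map
        ) == []

    def test_short_runs_dropped_by_min_run_length(self):
        ped, matrix = family_with_carriers(3, 2)
        decisions = ps.recessive_marker_filter(matrix, ped)
        assert decisions.loc["m1", "passes"]
        params = ps.FilterParams(min_run_length=2)
        assert ps.extract_candidate_regions(
            decisions, matrix.marker_map, params
        ) == []
        params = ps.FilterParams(min_run_length=1)
        regions = ps.extract_candidate_regions(
            decisions, matrix.marker_map, params
        )
        assert len(regions) == 1
        assert regions[0].n_markers == 1

    def test_causal_gene_region_reported(self, small_sim):
        config, pedigree, matrix, truth = small_sim
        decisions = ps.recessive_marker_filter(matrix, pedigree)
        decisions = ps.exclude_unaffected_homozygotes(
            matrix, pedigree, decisions
        )
        genes = candidate_regions_for_simulation(
            config.causal_locus, config.chromosome_names
        )
        assert len(genes) == 18
        candidates = ps.extract_candidate_regions(
            decisions, matrix.marker_map, ps.FilterParams(), genes
        )
        labels = {lab for c in candidates for lab in c.labels}
        assert "COLQ" in labels

    def test_specificity_weakly_improves_with_density_at_run_support_3(self):
        """With run support 3, spurious identity-by-state regions need three
        adjacent lucky markers, so the count of reported non-causal genes
        does not grow as the map gets denser."""
        params = ps.FilterParams(min_run_length=3)
        false_counts = {}
        for n_snps in (150, 400):
            total = 0
            for seed in range(8):
                ped = ps.build_fig1_pedigree()
                cfg = ps.SimConfig(
                    seed=500 + seed, n_snps_per_chromosome=n_snps
                )
                matrix, _ = ps.simulate(cfg, ped)
                decisions = ps.recessive_marker_filter(matrix, ped, params)
                decisions = ps.exclude_unaffected_homozygotes(
                    matrix, ped, decisions
                )
                genes = candidate_regions_for_simulation(
                    cfg.causal_locus, cfg.chromosome_names
                )
                candidates = ps.extract_candidate_regions(
                    decisions, matrix.marker_map, params, genes
                )
                total += sum(
                    1 for c in candidates if "COLQ" not in c.labels
                )
            false_counts[n_snps] = total
        assert false_counts[400] <= false_counts[150] + 1
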