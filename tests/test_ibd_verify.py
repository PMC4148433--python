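"""Phasing and microsatellite-based IBD verification."""

import logging

import pytest

import pedscan as ps
from pedscan.fixtures import candidate_regions_for_simulation
from pedscan.ibd_verify import _trio_phase
from pedscan.pipeline import targeted_microsatellite_positions

from conftest import make_matrix


def verification_family():
    """Sire/dam + 2 affected and 1 unaffected pup."""
    return ps.Pedigree([
        ps.Individual("sire", sex=ps.Sex.MALE,
                      phenotype=ps.Phenotype.UNAFFECTED),
        ps.Individual("dam", sex=ps.Sex.FEMALE,
                      phenotype=ps.Phenotype.UNAFFECTED),
        ps.Individual("case1", "sire", "dam",
                      phenotype=ps.Phenotype.AFFECTED),
        ps.Individual("case2", "sire", "dam",
                      phenotype=ps.Phenotype.AFFECTED),
        ps.Individual("sib", "sire", "dam",
                      phenotype=ps.Phenotype.UNAFFECTED),
    ])


def region_chr1(start=1000, end=3000):
    return ps.CandidateRegion(
        chromosome="1", first_marker_id="s1", last_marker_id="s2",
        start_bp=start, end_bp=end, n_markers=2,
        shared_case_alleles={"s1": "A", "s2": "T"},
        control_frequency=0.3,
    )


def verification_matrix(case2_ms=("184", "184"), ms_position=500):
    """Two region SNPs on chr1 plus one flanking microsatellite."""
    return make_matrix(
        [
            ("ms1", "1", ms_position, "microsatellite",
             ("180", "184", "188")),
            ("s1", "1", 1000, "snp", "AG"),
            ("s2", "1", 3000, "snp", "CT"),
        ],
        {
            "sire": [("180", "184"), ("A", "G"), ("C", "T")],
            "dam": [("180", "184"), ("A", "G"), ("C", "T")],
            "case1": [("184", "184"), ("A", "A"), ("T", "T")],
            "case2": [case2_ms, ("A", "A"), ("T", "T")],
            "sib": [("180", "184"), ("A", "G"), ("C", "T")],
        },
    )


class TestTrioPhase:
    def test_homozygous_father_resolves_phase(self):
        assert _trio_phase(("A", "A"), ("A", "G"), ("A", "G")) == ("A", "G")

    def test_homozygous_child_resolves_phase(self):
        assert _trio_phase(("A", "G"), ("A", "G"), ("A", "A")) == ("A", "A")

    def test_all_heterozygous_is_ambiguous(self):
        assert _trio_phase(("A", "G"), ("A", "G"), ("A", "G")) is None

    def test_missing_call_is_unresolved(self):
        assert _trio_phase(None, ("A", "G"), ("A", "G")) is None

    def test_impossible_transmission_flags_mendel(self):
        assert _trio_phase(("A", "A"), ("A", "A"), ("A", "G")) == "mendel"


class TestPhaseNuclearFamily:
    def test_inconsistent_marker_masked_and_logged(self, caplog):
        ped = verification_family()
        matrix = make_matrix(
            [("m1", "1", 100, "snp", "AG"), ("m2", "1", 200, "snp", "CT")],
            {
                "sire": [("A", "A"), ("C", "C")],
                "dam": [("A", "A"), ("C", "T")],
                "case1": [("A", "G"), ("C", "C")],  # G from nowhere
                "case2": [("A", "A"), ("C", "T")],
                "sib": [("A", "A"), ("C", "C")],
            },
        )
        with caplog.at_level(logging.WARNING):
            phased = ps.phase_nuclear_family(matrix, ped)
        assert phased.inconsistent_markers == ["m1"]
        assert "m1" in caplog.text
        # masked for everyone, including the consistent offspring
        for ind in phased.individual_ids:
            assert phased.haplotypes[ind][0][0] is None
            assert not phased.resolved[ind][0]
        # the clean marker still phases where determined
        assert phased.haplotypes["case2"][0][1] == "C"  # paternal C
        assert phased.haplotypes["case2"][1][1] == "T"

    def test_never_guesses_ambiguous_sites(self):
        ped = verification_family()
        matrix = make_matrix(
            [("m1", "1", 100, "snp", "AG")],
            {
                "sire": [("A", "G")], "dam": [("A", "G")],
                "case1": [("A", "G")], "case2": [("A", "A")],
                "sib": [("G", "G")],
            },
        )
        phased = ps.phase_nuclear_family(matrix, ped)
        assert not phased.resolved["case1"][0]
        assert phased.resolved["case2"][0]
        assert phased.resolved["sib"][0]

    def test_resolved_phase_matches_simulation_truth(self, small_sim):
        """Wherever Mendelian logic claims a phase, it equals the simulated
        parental origin (copy 0 paternal, copy 1 maternal)."""
        config, pedigree, matrix, truth = small_sim
        phased = ps.phase_nuclear_family(matrix, pedigree)
        assert phased.inconsistent_markers == []
        local_index = {}
        for chrom in config.chromosome_names:
            for local_j, (global_j, m) in enumerate(
                matrix.marker_map.on_chromosome(chrom)
            ):
                local_index[global_j] = (chrom, local_j, m.position_bp)
        n_checked = 0
        for ind in phased.individual_ids:
            for j in range(matrix.n_markers):
                if not phased.resolved[ind][j]:
                    continue
                chrom, local_j, pos = local_index[j]
                for copy in (0, 1):
                    assert phased.haplotypes[ind][copy][j] == truth.allele(
                        ind, copy, chrom, local_j, pos
                    )
                n_checked += 1
        assert n_checked > 1000  # the check has real coverage


class TestVerifyIbd:
    def test_shared_homozygous_flank_is_ibd_consistent(self):
        ped = verification_family()
        matrix = verification_matrix()
        verdict = ps.verify_ibd(matrix, ped, region_chr1())
        assert verdict.verdict == "ibd_consistent"
        assert verdict.shared_allele_consistent
        assert verdict.flanking_marker_ids == ["ms1"]
        assert verdict.case_homozygous_at_flank["ms1"] == {
            "case1": True, "case2": True
        }

    def test_heterozygous_case_rules_out_ibd(self):
        ped = verification_family()
        matrix = verification_matrix(case2_ms=("180", "184"))
        verdict = ps.verify_ibd(matrix, ped, region_chr1())
        assert verdict.verdict == "not_ibd"

    def test_cases_homozygous_for_different_alleles_rules_out_ibd(self):
        ped = verification_family()
        matrix = verification_matrix(case2_ms=("180", "180"))
        verdict = ps.verify_ibd(matrix, ped, region_chr1())
        assert verdict.verdict == "not_ibd"

    def test_no_informative_microsatellite_is_uninformative(self):
        ped = verification_family()
        # only one allele observed anywhere in the family
        matrix = make_matrix(
            [
                ("ms1", "1", 500, "microsatellite", ("180", "184")),
                ("s1", "1", 1000, "snp", "AG"),
                ("s2", "1", 3000, "snp", "CT"),
            ],
            {i: [("184", "184"), ("A", "A"), ("T", "T")]
             for i in ("sire", "dam", "case1", "case2", "sib")},
        )
        verdict = ps.verify_ibd(matrix, ped, region_chr1())
        assert verdict.verdict == "uninformative"

    def test_microsatellite_outside_window_is_ignored(self):
        ped = verification_family()
        # region [1000, 3000], window 1 Mb; place the marker beyond it
        matrix = verification_matrix(ms_position=3000 + 1_000_001)
        verdict = ps.verify_ibd(matrix, ped, region_chr1())
        assert verdict.verdict == "uninformative"
        assert verdict.flanking_marker_ids == []

    def test_discordant_region_haplotype_blocks_consistency(self):
        """Cases share the flank homozygote but differ inside the region:
        not promoted to ibd_consistent."""
        ped = verification_family()
        matrix = make_matrix(
            [
                ("ms1", "1", 500, "microsatellite", ("180", "184")),
                ("s1", "1", 1000, "snp", "AG"),
            ],
            {
                "sire": [("180", "184"), ("A", "G")],
                "dam": [("180", "184"), ("A", "G")],
                "case1": [("184", "184"), ("A", "A")],
                "case2": [("184", "184"), ("G", "G")],
                "sib": [("180", "184"), ("A", "G")],
            },
        )
        verdict = ps.verify_ibd(
            matrix, ped, region_chr1(start=1000, end=1000)
        )
        assert verdict.verdict == "uninformative"

    def test_unknown_chromosome_rejected(self, small_sim):
        _, pedigree, matrix, _ = small_sim
        bad = ps.CandidateRegion(
            chromosome="99", first_marker_id="x", last_marker_id="x",
            start_bp=1, end_bp=2, n_markers=1,
            shared_case_alleles={}, control_frequency=0.0,
        )
        with pytest.raises(ValueError, match="99"):
            ps.verify_ibd(matrix, pedigree, bad)


class TestVerdictSoundnessOnSimulations:
    """Exact guarantees at genotyping error rate 0, checked against the
    generator's founder-origin truth over candidate span plus flanks."""

    def test_truth_ibd_never_rejected_and_not_ibd_never_wrong(self):
        flank = 1_000_000
        n_verdicts = 0
        for seed in range(6):
            ped = ps.build_fig1_pedigree()
            cfg = ps.SimConfig(seed=700 + seed)
            genes = candidate_regions_for_simulation(
                cfg.causal_locus, cfg.chromosome_names
            )
            cfg.microsatellite_positions = targeted_microsatellite_positions(
                genes, cfg.chromosome_names, cfg.chromosome_length_bp
            )
            matrix, truth = ps.simulate(cfg, ped)
            decisions = ps.recessive_marker_filter(matrix, ped)
            decisions = ps.exclude_unaffected_homozygotes(
                matrix, ped, decisions
            )
            candidates = ps.extract_candidate_regions(
                decisions, matrix.marker_map, ps.FilterParams(), genes
            )
            case_ids = [c.id for c in ped.affected]
            for region in candidates:
                verdict = ps.verify_ibd(matrix, ped, region, flank)
                n_verdicts += 1
                truth_ibd = truth.ibd_over_span(
                    region.chromosome,
                    max(1, region.start_bp - flank),
                    min(cfg.chromosome_length_bp, region.end_bp + flank),
                    case_ids,
                )
                if truth_ibd:
                    # a truly IBD extended span can never be rejected
                    assert verdict.verdict != "not_ibd"
                if verdict.verdict == "not_ibd":
                    assert not truth_ibd
        assert n_verdicts >= 6
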