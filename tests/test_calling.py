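import math

import numpy as np
import pytest

from degradomap.calling import (
    CleavageSiteCaller,
    PeptideObservation,
    RatioRecord,
    SiteCall,
    aggregate_observations,
    annotate_tryptic_status,
    call_cleavage_sites,
    compare_site_sets,
    compute_ratios,
    compute_zscores,
    find_spanning_evidence,
    localize_records,
    select_candidates,
)
from degradomap.sequence import ProteinRecord
from degradomap.simulate import DegradomeSimConfig, make_substrate, simulate_degradome

LOG2_100 = math.log2(100.0)


def both(peptide, a, c, prec="K", foll="G"):
    return PeptideObservation(peptide, prec, foll, abundance_active=a, abundance_control=c)


class TestAggregate:
    def test_duplicate_rows_summed(self):
        rows = [both("AAAK", 3, 1), both("AAAK", 5, 2)]
        (merged,) = aggregate_observations(rows)
        assert merged.abundance_active == 8
        assert merged.abundance_control == 3

    def test_zero_counts_as_absent(self):
        rows = [PeptideObservation("AAAK", "K", "G", abundance_active=0.0,
                                   abundance_control=7.0)]
        (merged,) = aggregate_observations(rows)
        assert merged.abundance_active is None

    def test_empty_input(self):
        assert aggregate_observations([]) == []


class TestRatios:
    def test_both_group_ratio(self):
        (rec,) = compute_ratios([both("AAAK", 200, 100)])
        assert rec.detection_class == "both"
        assert rec.ratio == 2.0 and rec.log2_ratio == 1.0
        assert rec.ratio_converse == 0.5

    def test_active_singleton_convention(self):
        (rec,) = compute_ratios([PeptideObservation("AAAK", "K", "G", abundance_active=5.0)])
        assert rec.detection_class == "active_only"
        assert rec.ratio == 100.0
        assert round(rec.log2_ratio, 2) == 6.64
        assert rec.ratio_converse is None

    def test_control_singleton_converse_scale(self):
        (rec,) = compute_ratios([PeptideObservation("AAAK", "K", "G", abundance_control=5.0)])
        assert rec.detection_class == "control_only"
        assert rec.ratio is None
        assert rec.ratio_converse == 100.0


class TestZScores:
    def make_population(self, log2_values):
        return [both(f"PEP{i}K", 100 * 2.0 ** x, 100.0) for i, x in enumerate(log2_values)]

    def test_singleton_z_on_five_point_population(self):
        """Both-group log2 ratios {-2,-1,0,1,2} (sample sd 1.5811): a singleton
        at log2(100) lands 4.202 sd above the mean."""
        records = compute_ratios(
            self.make_population([-2, -1, 0, 1, 2])
            + [PeptideObservation("SINGK", "K", "G", abundance_active=1.0)]
        )
        compute_zscores(records, scope="active")
        singleton = next(r for r in records if r.detection_class == "active_only")
        assert singleton.z == pytest.approx(LOG2_100 / math.sqrt(2.5), abs=5e-4)
        assert singleton.z == pytest.approx(4.202, abs=1e-3)

    def test_degenerate_sd_errors(self):
        records = compute_ratios(self.make_population([1, 1, 1]))
        with pytest.raises(ValueError, match="degenerate"):
            compute_zscores(records, scope="active")

    def test_too_few_both_group_errors(self):
        records = compute_ratios(self.make_population([1]))
        with pytest.raises(ValueError, match=">= 2 both-group"):
            compute_zscores(records, scope="active")

    def test_z_affine_in_log2_ratio(self):
        rng = np.random.default_rng(7)
        records = compute_ratios(self.make_population(rng.normal(0, 2, size=30)))
        stats = compute_zscores(records, scope="active")
        mean, sd = stats["active"]
        for r1 in records[:5]:
            for r2 in records[5:10]:
                assert (r1.z - r2.z) * sd == pytest.approx(r1.log2_ratio - r2.log2_ratio)

    def test_population_sd(self):
        records = compute_ratios(self.make_population([-1, 0, 1, 2]))
        sample = compute_zscores(records, scope="active", ddof=1)["active"][1]
        compute_zscores(records, scope="active", ddof=0)
        population = np.std([-1, 0, 1, 2])
        assert sample > population


class TestSelection:
    def annotated(self, observations):
        records = compute_ratios(observations)
        annotate_tryptic_status(records)
        return records

    def test_singleton_selected_regardless_of_z(self):
        records = self.annotated(
            [PeptideObservation("AAAG", "K", "G", abundance_active=1.0)]
        )
        candidates, _ = select_candidates(records)
        assert len(candidates) == 1

    @pytest.mark.parametrize("z,selected", [(1.5, 0), (2.0, 0), (2.4, 1)])
    def test_strict_threshold_on_both_group(self, z, selected):
        rec = RatioRecord("AAAG", "K", "G", "both", 10.0, 1.0, tryptic_status="semi",
                          nontryptic_side="C", z=z)
        candidates, _ = select_candidates([rec])
        assert len(candidates) == selected

    def test_nontryptic_flagged_separately(self):
        records = self.annotated(
            [PeptideObservation("AAAG", "G", "G", abundance_active=1.0)]
        )
        candidates, nontryptic = select_candidates(records)
        assert candidates == [] and len(nontryptic) == 1


class TestSiteCalling:
    protein = ProteinRecord("SUB", "GGKNTVMESAVLDKRWQPG")

    def candidates(self, observations):
        records = compute_ratios(observations)
        annotate_tryptic_status(records)
        localize_records(records, self.protein)
        return records

    def test_nontryptic_c_terminus_defines_site(self):
        # NTVMES at 4-9, preceded by K, followed by A: cleavage S9-A10
        records = self.candidates(
            [PeptideObservation("NTVMES", "K", "A", abundance_active=1.0)]
        )
        (site,) = call_cleavage_sites(records, self.protein)
        assert (site.p1_position, site.p1_residue, site.p1prime_residue) == (9, "S", "A")
        assert site.p1prime_position == 10
        assert site.label == "S9-A10"

    def test_nontryptic_n_terminus_defines_site(self):
        # AVLDK at 10-14 preceded by S: cleavage S9-A10 again
        records = self.candidates(
            [PeptideObservation("AVLDK", "S", "R", abundance_active=1.0)]
        )
        (site,) = call_cleavage_sites(records, self.protein)
        assert site.p1_position == 9

    def test_duplicate_boundary_merged(self):
        records = self.candidates(
            [
                PeptideObservation("NTVMES", "K", "A", abundance_active=1.0),
                PeptideObservation("AVLDK", "S", "R", abundance_active=2.0),
            ]
        )
        sites = call_cleavage_sites(records, self.protein)
        assert len(sites) == 1
        assert len(sites[0].supporting_semitryptic) == 2

    def test_peptide_at_mature_terminus_is_not_evidence(self):
        # a peptide reaching the protein C-terminus has a protein_terminus
        # (not non-tryptic) terminus and therefore is never a site candidate
        short = ProteinRecord("SUB2", "GGKNTVMES")
        records = compute_ratios(
            [PeptideObservation("NTVMES", "K", "-", abundance_active=1.0)]
        )
        annotate_tryptic_status(records)
        assert records[0].tryptic_status == "fully"

    def test_boundary_at_protein_terminus_rejected(self):
        short = ProteinRecord("SUB2", "GGKNTVMES")
        rec = RatioRecord("NTVMES", "K", "-", "active_only", 1.0, None,
                          tryptic_status="semi", nontryptic_side="C")
        localize_records([rec], short)
        assert rec.span.end == len(short)
        with pytest.warns(UserWarning, match="terminus"):
            assert call_cleavage_sites([rec], short) == []

    def test_fully_tryptic_candidate_rejected(self):
        records = self.candidates(
            [PeptideObservation("NTVMESAVLDK", "K", "R", abundance_active=1.0)]
        )
        with pytest.warns(UserWarning):
            assert call_cleavage_sites(records, self.protein) == []


class TestSpanningEvidence:
    protein = ProteinRecord("SUB", "GGKNTVMESAVLDKRWQPG")

    def run(self, spanning_obs):
        semi = PeptideObservation("NTVMES", "K", "A", abundance_active=1.0)
        records = compute_ratios([semi] + spanning_obs)
        annotate_tryptic_status(records)
        localize_records(records, self.protein)
        (site,) = call_cleavage_sites(
            [r for r in records if r.tryptic_status == "semi"], self.protein
        )
        return find_spanning_evidence(site, records, self.protein)

    def test_control_only_spanning_corroborates(self):
        # NTVMESAVLDK spans 4-14, strictly contains the 9|10 boundary
        site = self.run([PeptideObservation("NTVMESAVLDK", "K", "R", abundance_control=3.0)])
        ((record, corroborating),) = site.spanning_tryptic
        assert record.peptide == "NTVMESAVLDK"
        assert corroborating

    def test_strict_containment_of_the_boundary(self):
        # NTVMESAVLDK occupies 4-14: it spans bond 13|14 but neither bond
        # 14|15 (ends exactly at P1) nor bond 3|4 (starts exactly at P1')
        records = compute_ratios(
            [PeptideObservation("NTVMESAVLDK", "K", "R", abundance_control=3.0)]
        )
        annotate_tryptic_status(records)
        localize_records(records, self.protein)
        inside = find_spanning_evidence(SiteCall("SUB", 13, "D", "K"), records, self.protein)
        assert len(inside.spanning_tryptic) == 1
        at_end = find_spanning_evidence(SiteCall("SUB", 14, "K", "R"), records, self.protein)
        assert at_end.spanning_tryptic == []
        at_start = find_spanning_evidence(SiteCall("SUB", 3, "K", "N"), records, self.protein)
        assert at_start.spanning_tryptic == []

    def test_no_spanning_evidence_site_retained(self):
        site = self.run([])
        assert site.spanning_tryptic == [] and site.p1_position == 9


class TestCompareSiteSets:
    def make(self, positions, accession="SUB"):
        return [SiteCall(accession, p, "A", "G") for p in positions]

    def test_partition(self):
        shared, only_a, only_b = compare_site_sets(
            self.make([10, 20, 30]), self.make([20, 30, 40])
        )
        assert [s.p1_position for s in shared] == [20, 30]
        assert [s.p1_position for s in only_a] == [10]
        assert [s.p1_position for s in only_b] == [40]

    def test_identical_and_disjoint(self):
        a = self.make([1, 2])
        assert [s.p1_position for s in compare_site_sets(a, a)[0]] == [1, 2]
        shared, only_a, only_b = compare_site_sets(self.make([1]), self.make([2]))
        assert shared == [] and len(only_a) == len(only_b) == 1

    def test_accession_mismatch_raises(self):
        with pytest.raises(ValueError, match="different substrates"):
            compare_site_sets(self.make([1], "A"), self.make([1], "B"))


class TestCallerEquivalence:
    def brute_force_sites(self, records, protein, z_threshold=2.0):
        """Independent oracle: check every residue boundary of the substrate
        against the selection rule, without the caller's grouping logic."""
        called = set()
        for p1 in range(1, len(protein)):
            for rec in records:
                if rec.tryptic_status != "semi" or rec.span is None:
                    continue
                significant = rec.detection_class == "active_only" or (
                    rec.z is not None and rec.z > z_threshold
                )
                if not significant:
                    continue
                boundary = (
                    rec.span.start - 1 if rec.nontryptic_side == "N" else rec.span.end
                )
                if boundary == p1:
                    called.add(p1)
        return called

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_caller_matches_boundary_enumeration(self, seed):
        config = DegradomeSimConfig(both_group_log2_sd=1.0, seed=seed)
        observations, _ = simulate_degradome(config)
        protein = make_substrate(config.length, seed=seed + 1)
        caller = CleavageSiteCaller().fit(observations, protein)
        expected = self.brute_force_sites(caller.records_, protein)
        assert set(caller.site_positions()) == expected
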