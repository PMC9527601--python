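"""Transmission model: gamete distributions, pollen acceptance, crosses."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsicross.errors import DomainError, MissingLocusError, UnsupportedPloidyError
from gsicross.si_core import (
    Compatibility,
    Haplotype,
    PlantGenotype,
    PollenClass,
    RecombinationMap,
    SAllele,
    TraitAllele,
    brute_force_cross,
    cf_predicate,
    cross,
    expected_trait_fraction,
    gamete_distribution,
    pollen_accepted,
)
from conftest import KSN_COPIA, KSN_FUNCTIONAL, diploid, hap

TOL = 1e-12


class TestGameteDistribution:
    def test_diploid_one_linked_locus(self):
        """Parental classes at (1-r)/2, recombinant classes at r/2."""
        parent = diploid("p", hap("S1", KSN_COPIA), hap("S3", KSN_FUNCTIONAL))
        classes = {
            pc.haplotypes[0].label(): pc.probability
            for pc in gamete_distribution(parent, {"KSN": 0.2})
        }
        assert classes == pytest.approx(
            {"S1-ksn_copia": 0.4, "S3-KSN_W": 0.4, "S3-ksn_copia": 0.1, "S1-KSN_W": 0.1}
        )

    def test_complete_linkage_gives_parental_classes_only(self):
        parent = diploid("p", hap("S1", KSN_COPIA), hap("S3", KSN_FUNCTIONAL))
        classes = gamete_distribution(parent, {"KSN": 0.0})
        labels = {pc.haplotypes[0].label(): pc.probability for pc in classes}
        assert labels == pytest.approx({"S1-ksn_copia": 0.5, "S3-KSN_W": 0.5})

    def test_r_half_makes_locus_independent_of_s(self):
        parent = diploid("p", hap("S1", KSN_COPIA), hap("S3", KSN_FUNCTIONAL))
        classes = gamete_distribution(parent, {"KSN": 0.5})
        joint = {
            (pc.haplotypes[0].s.id, pc.haplotypes[0].trait("KSN").allele): pc.probability
            for pc in classes
        }
        for s in ("S1", "S3"):
            for allele in ("ksn_copia", "KSN_W"):
                assert joint[(s, allele)] == pytest.approx(0.25, abs=TOL)

    def test_tetraploid_six_unordered_pairs_equiprobable(self):
        """Oracle: enumerate bivalent pairings x chromatid choices by hand."""
        parent = PlantGenotype(
            "t", 4, tuple(hap(f"S{i}") for i in range(1, 5))
        )
        classes = gamete_distribution(parent)
        expected = {
            tuple(sorted((f"S{i}", f"S{j}"))): 0.0 for i in range(1, 5) for j in range(i + 1, 5)
        }
        # oracle: three pairings, each bivalent transmits either chromosome
        for pairing in (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))):
            for a, b in itertools.product(*pairing):
                key = tuple(sorted((f"S{a + 1}", f"S{b + 1}")))
                expected[key] += (1 / 3) * (1 / 4)
        observed = {
            tuple(sorted(s.id for s in pc.s_alleles)): pc.probability for pc in classes
        }
        assert observed == pytest.approx(expected, abs=TOL)
        assert all(p == pytest.approx(1 / 6) for p in observed.values())

    def test_probabilities_sum_to_one(self):
        parent = diploid(
            "p",
            hap("S1", KSN_COPIA, TraitAllele("AP2", "ap2", False)),
            hap("S2", KSN_FUNCTIONAL, TraitAllele("AP2", "AP2_W", True)),
        )
        classes = gamete_distribution(parent, {"KSN": 0.13, "AP2": 0.4})
        assert sum(pc.probability for pc in classes) == pytest.approx(1.0, abs=TOL)
        assert len(classes) == 8  # 2 S origins x 2 KSN x 2 AP2 outcomes

    def test_triploid_rejected(self):
        parent = PlantGenotype("tri", 3, tuple(hap(f"S{i}") for i in range(1, 4)))
        with pytest.raises(UnsupportedPloidyError):
            gamete_distribution(parent)

    def test_r_out_of_domain_rejected(self):
        parent = diploid("p", hap("S1", KSN_COPIA), hap("S2", KSN_FUNCTIONAL))
        with pytest.raises(DomainError):
            gamete_distribution(parent, {"KSN": 0.7})


class TestPollenAcceptance:
    def test_matching_haploid_pollen_rejected(self):
        pistil = diploid("m", hap("Sx", anonymous=True), hap("S_C1"))
        assert not pollen_accepted(PollenClass((hap("S_C1"),), 1.0), pistil)

    def test_anonymous_pollen_accepted(self):
        pistil = diploid("m", hap("Sx", anonymous=True), hap("S_C1"))
        assert pollen_accepted(PollenClass((hap("Sy", anonymous=True),), 1.0), pistil)

    def test_anonymous_alleles_never_match_each_other(self):
        pistil = diploid("m", hap("Sx", anonymous=True), hap("S_C1"))
        # same anonymous label on pollen side still does not match
        assert pollen_accepted(PollenClass((hap("Sx", anonymous=True),), 1.0), pistil)

    def test_heteroallelic_diploid_pollen_always_accepted(self):
        """SI breakdown in tetraploids: two distinct S-alleles escape rejection."""
        pistil = diploid("m", hap("S1"), hap("S2"))
        assert pollen_accepted(PollenClass((hap("S1"), hap("S2")), 1.0), pistil)

    def test_homoallelic_diploid_pollen_treated_as_haploid(self):
        pistil = diploid("m", hap("S1"), hap("S2"))
        assert not pollen_accepted(PollenClass((hap("S1"), hap("S1")), 1.0), pistil)
        other = diploid("m2", hap("S3"), hap("S4"))
        assert pollen_accepted(PollenClass((hap("S1"), hap("S1")), 1.0), other)


class TestCross:
    def test_half_compatible_cross_classes(self):
        mother = diploid("m", hap("Sx", anonymous=True), hap("S_C1"))
        father = diploid("f", hap("S_C1"), hap("Sy", anonymous=True))
        result = cross(mother, father)
        assert result.compatibility is Compatibility.HALF_COMPATIBLE
        assert result.accepted_fraction == pytest.approx(0.5)
        genotypes = result.offspring_s_genotypes()
        assert genotypes == pytest.approx(
            {("S_C1", "Sy"): 0.5, ("Sx", "Sy"): 0.5}
        )
        # the shared allele never arrives via pollen
        for pc in result.pollen_distribution:
            assert pc.haplotypes[0].s.id != "S_C1"

    def test_selfing_is_incompatible(self):
        plant = diploid("p", hap("S1"), hap("S2"))
        result = cross(plant, plant)
        assert result.compatibility is Compatibility.INCOMPATIBLE
        assert result.accepted_fraction == 0.0
        assert result.offspring == {}

    def test_fully_compatible_four_classes(self):
        mother = diploid("m", hap("S1"), hap("S2"))
        father = diploid("f", hap("S3"), hap("S4"))
        result = cross(mother, father)
        assert result.compatibility is Compatibility.FULLY_COMPATIBLE
        assert result.accepted_fraction == 1.0
        assert all(
            p == pytest.approx(0.25) for p in result.offspring_s_genotypes().values()
        )

    def test_offspring_distribution_sums_to_one(self, cf_seed_parent, ksn_carrier_pollen_parent):
        result = cross(cf_seed_parent, ksn_carrier_pollen_parent, {"KSN": 0.2})
        assert sum(result.offspring.values()) == pytest.approx(1.0, abs=TOL)
        assert sum(pc.probability for pc in result.pollen_distribution) == pytest.approx(
            1.0, abs=TOL
        )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        s_mother=st.tuples(st.sampled_from("ABCD"), st.sampled_from("ABCD")),
        s_father=st.tuples(st.sampled_from("ABCD"), st.sampled_from("ABCD")),
        r=st.floats(0.0, 0.5),
        ksn_mother=st.tuples(st.booleans(), st.booleans()),
        ksn_father=st.tuples(st.booleans(), st.booleans()),
    )
    def test_cross_equals_brute_force_enumeration(
        self, s_mother, s_father, r, ksn_mother, ksn_father
    ):
        """Engine aggregation equals exhaustive ovule x pollen enumeration."""

        def mk(pid, s_pair, ksn_pair):
            return diploid(
                pid,
                hap(s_pair[0], KSN_FUNCTIONAL if ksn_pair[0] else KSN_COPIA),
                hap(s_pair[1], KSN_FUNCTIONAL if ksn_pair[1] else KSN_COPIA),
            )

        mother = mk("m", s_mother, ksn_mother)
        father = mk("f", s_father, ksn_father)
        result = cross(mother, father, {"KSN": r})
        oracle = brute_force_cross(mother, father, {"KSN": r})
        assert set(result.offspring) == set(oracle)
        for key in oracle:
            assert result.offspring[key] == pytest.approx(oracle[key], abs=1e-9)

    def test_anonymity_does_not_change_compatibility_class(self):
        """Replacing a concrete non-shared allele by an anonymous label is neutral."""
        configs = [
            (("S1", "S2"), ("S2", "S3")),  # half-compatible
            (("S1", "S2"), ("S3", "S4")),  # fully compatible
        ]
        for (m1, m2), (f1, f2) in configs:
            base = cross(diploid("m", hap(m1), hap(m2)), diploid("f", hap(f1), hap(f2)))
            # S1 and the father's non-shared allele are non-shared: anonymise them
            anon = cross(
                diploid("m", hap("Sx", anonymous=True), hap(m2)),
                diploid("f", hap(f1), hap("Sy", anonymous=True))
                if f2 not in (m1, m2)
                else diploid("f", hap(f1), hap(f2)),
            )
            assert anon.compatibility is base.compatibility


class TestExpectedTraitFraction:
    def test_cf_seed_parent_fraction_equals_r(self, cf_seed_parent, ksn_carrier_pollen_parent):
        """ksn-homozygous mother x shared-S carrier father: CF share = r."""
        result = cross(cf_seed_parent, ksn_carrier_pollen_parent, {"KSN": 0.2})
        assert expected_trait_fraction(result, "KSN", cf_predicate) == pytest.approx(0.20)

    def test_heterozygous_seed_parent_fraction(self, ksn_carrier_pollen_parent):
        """Both parents ksn/KSN heterozygous: CF share = r/2 (oracle-derived)."""
        mother = diploid("m", hap("S1", KSN_COPIA), hap("S2", KSN_FUNCTIONAL))
        result = cross(mother, ksn_carrier_pollen_parent, {"KSN": 0.2})
        assert expected_trait_fraction(result, "KSN", cf_predicate) == pytest.approx(0.10)

    def test_always_true_predicate_gives_one(self, cf_seed_parent, ksn_carrier_pollen_parent):
        result = cross(cf_seed_parent, ksn_carrier_pollen_parent, {"KSN": 0.2})
        assert expected_trait_fraction(result, "KSN", lambda _: True) == pytest.approx(
            1.0, abs=TOL
        )

    def test_missing_locus_raises(self, cf_seed_parent, ksn_carrier_pollen_parent):
        result = cross(cf_seed_parent, ksn_carrier_pollen_parent, {"KSN": 0.2})
        with pytest.raises(MissingLocusError):
            expected_trait_fraction(result, "AP2", cf_predicate)

    @pytest.mark.parametrize("r_lo,r_hi", [(0.05, 0.1), (0.1, 0.3), (0.3, 0.5)])
    def test_cf_fraction_strictly_increasing_in_r(
        self, cf_seed_parent, ksn_carrier_pollen_parent, r_lo, r_hi
    ):
        lo = expected_trait_fraction(
            cross(cf_seed_parent, ksn_carrier_pollen_parent, {"KSN": r_lo}),
            "KSN",
            cf_predicate,
        )
        hi = expected_trait_fraction(
            cross(cf_seed_parent, ksn_carrier_pollen_parent, {"KSN": r_hi}),
            "KSN",
            cf_predicate,
        )
        assert lo < hi


class TestTypes:
    def test_plant_requires_matching_haplotype_count(self):
        with pytest.raises(ValueError):
            PlantGenotype("p", 2, (hap("S1"),))

    def test_haplotype_rejects_duplicate_locus(self):
        with pytest.raises(ValueError):
            Haplotype(SAllele("S1"), (KSN_COPIA, KSN_FUNCTIONAL))

    def test_s_question_labels_are_anonymous(self):
        assert SAllele("S?1").anonymous
        assert not SAllele("S?1").matches(SAllele("S?1"))

    def test_rmap_defaults_unlinked(self):
        assert RecombinationMap({})["anything"] == 0.5
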