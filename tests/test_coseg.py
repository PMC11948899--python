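"""Genotype classification, repeat masking, and the co-segregation filter."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from intervaltree import IntervalTree

from cosegscan.cross import (
    CrossDesign,
    DesignError,
    GenotypeClass,
    MissingPolicy,
    Orientation,
    Role,
    SampleSpec,
)
from cosegscan.variants import (
    Variant,
    apply_repeat_mask,
    classify_cosegregation,
    classify_gt,
    combine_families,
    load_variants,
)

from conftest import write_vcf_text

CLASSES = [
    GenotypeClass.HOM_REF,
    GenotypeClass.HET,
    GenotypeClass.HOM_ALT,
    GenotypeClass.MISSING,
]


def make_variant(genotypes, pos=100):
    return Variant(
        scaffold="s1",
        pos=pos,
        ref_allele="A",
        alt_alleles=["T"],
        alt_index=0,
        genotypes=genotypes,
    )


class TestGenotypeClassification:
    def test_gt_to_class_matches_enumeration_oracle(self):
        """Brute-force oracle over every diploid pair of 3 alleles (+missing),
        for both alt splits of a tri-allelic record."""
        alleles = [-1, 0, 1, 2]
        for a, b in itertools.product(alleles, repeat=2):
            for alt_index in (0, 1):
                split = alt_index + 1
                if a < 0 or b < 0:
                    expected = GenotypeClass.MISSING
                elif a == 0 and b == 0:
                    expected = GenotypeClass.HOM_REF
                elif a == b == split:
                    expected = GenotypeClass.HOM_ALT
                else:
                    expected = GenotypeClass.HET
                assert classify_gt((a, b), alt_index) is expected, (a, b, alt_index)

    def test_vcf_record_maps_directly(self, one_family_design, tmp_path):
        path = write_vcf_text(
            tmp_path / "t.vcf",
            one_family_design.sample_ids,
            [("s1", 100, "A", "T", ["0/0", "0/1", "0/0", "1/0"])],
        )
        (v,) = load_variants(path, one_family_design)
        assert [v.genotypes[s] for s in one_family_design.sample_ids] == [
            GenotypeClass.HOM_REF,
            GenotypeClass.HET,
            GenotypeClass.HOM_REF,
            GenotypeClass.HET,
        ]

    def test_multiallelic_record_splits_per_alt(self, one_family_design, tmp_path):
        path = write_vcf_text(
            tmp_path / "t.vcf",
            one_family_design.sample_ids,
            [("s1", 100, "G", "A,T", ["0/0", "1/2", "2/2", "0/1"])],
        )
        v0, v1 = load_variants(path, one_family_design)
        assert (v0.alt_index, v1.alt_index) == (0, 1)
        # 1/2 carries a non-reference allele under either split -> het
        assert v0.genotypes["car_parent"] is GenotypeClass.HET
        assert v1.genotypes["car_parent"] is GenotypeClass.HET
        # 2/2 is hom_alt only for its own split
        assert v0.genotypes["aff_pool"] is GenotypeClass.HET
        assert v1.genotypes["aff_pool"] is GenotypeClass.HOM_ALT

    def test_missing_and_phased_genotypes(self, one_family_design, tmp_path):
        path = write_vcf_text(
            tmp_path / "t.vcf",
            one_family_design.sample_ids,
            [("s1", 100, "A", "T", ["./.", "0|1", "1|1", "0/0"])],
        )
        (v,) = load_variants(path, one_family_design)
        assert v.genotypes["aff_parent"] is GenotypeClass.MISSING
        assert v.genotypes["car_parent"] is GenotypeClass.HET
        assert v.genotypes["aff_pool"] is GenotypeClass.HOM_ALT

    def test_design_sample_absent_from_header_is_an_error(
        self, one_family_design, tmp_path
    ):
        path = write_vcf_text(
            tmp_path / "t.vcf", ["aff_parent"], [("s1", 1, "A", "T", ["0/0"])]
        )
        with pytest.raises(DesignError, match="car_parent"):
            load_variants(path, one_family_design)


class TestRepeatMask:
    def test_bed_coordinate_convention(self):
        # BED [99,100) covers 1-based position 100
        v = make_variant({}, pos=100)
        tree = IntervalTree()
        tree.addi(99, 100)
        (out,) = apply_repeat_mask([v], {"s1": tree})
        assert out.in_repeat

    def test_empty_bed_flags_nothing(self):
        variants = [make_variant({}, pos=p) for p in range(1, 11)]
        assert not any(v.in_repeat for v in apply_repeat_mask(variants, {}))

    def test_interval_flags_exactly_covered_positions(self):
        # BED [0,5) covers 1-based positions 1..5 of 1..10
        tree = IntervalTree()
        tree.addi(0, 5)
        variants = apply_repeat_mask(
            [make_variant({}, pos=p) for p in range(1, 11)], {"s1": tree}
        )
        assert [v.pos for v in variants if v.in_repeat] == [1, 2, 3, 4, 5]

    def test_unknown_bed_scaffold_warns_not_raises(self):
        tree = IntervalTree()
        tree.addi(0, 10)
        with pytest.warns(UserWarning, match="sX"):
            apply_repeat_mask([make_variant({}, pos=1)], {"sX": tree})

    @given(
        positions=st.lists(st.integers(1, 200), min_size=1, max_size=20),
        intervals=st.lists(
            st.tuples(st.integers(0, 199), st.integers(1, 50)), max_size=8
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_masking_idempotent_and_order_independent(self, positions, intervals):
        def build(order):
            tree = IntervalTree()
            for start, width in order:
                tree.addi(start, start + width)
            return {"s1": tree}

        variants = [make_variant({}, pos=p) for p in positions]
        once = [v.in_repeat for v in apply_repeat_mask(variants, build(intervals))]
        twice = [v.in_repeat for v in apply_repeat_mask(variants, build(intervals))]
        rev = [v.in_repeat for v in apply_repeat_mask(variants, build(intervals[::-1]))]
        assert once == twice == rev


class TestCosegregationFilter:
    def _enumeration_oracle(self, classes, orientation):
        aff = orientation.affected_class
        a_par, c_par, a_pool, c_pool = classes
        return (
            a_par is aff
            and a_pool is aff
            and c_par is GenotypeClass.HET
            and c_pool is GenotypeClass.HET
        )

    @pytest.mark.parametrize("orientation", list(Orientation))
    def test_matches_exhaustive_enumeration_over_256_assignments(
        self, one_family_design, orientation
    ):
        """The filter agrees with brute-force enumeration on all 4^4 class
        assignments of a 2-affected/2-carrier family; exactly one passes."""
        design = CrossDesign(
            samples=one_family_design.samples, orientation=orientation
        )
        sample_order = ["aff_parent", "car_parent", "aff_pool", "car_pool"]
        n_true = 0
        for classes in itertools.product(CLASSES, repeat=4):
            v = make_variant(dict(zip(sample_order, classes)))
            got = classify_cosegregation(v, design, "fam1")
            assert got == self._enumeration_oracle(classes, orientation)
            n_true += got
        assert n_true == 1

    def test_canonical_recessive_pattern_cosegregates(self, one_family_design):
        v = make_variant(
            {
                "aff_parent": GenotypeClass.HOM_REF,
                "aff_pool": GenotypeClass.HOM_REF,
                "car_parent": GenotypeClass.HET,
                "car_pool": GenotypeClass.HET,
            }
        )
        assert classify_cosegregation(v, one_family_design, "fam1")

    def test_missing_genotype_fails_variant_by_default(self, one_family_design):
        v = make_variant(
            {
                "aff_parent": GenotypeClass.MISSING,
                "aff_pool": GenotypeClass.HOM_REF,
                "car_parent": GenotypeClass.HET,
                "car_pool": GenotypeClass.HET,
            }
        )
        assert not classify_cosegregation(v, one_family_design, "fam1")
        lenient = CrossDesign(
            samples=one_family_design.samples,
            missing_policy=MissingPolicy.IGNORE_SAMPLE,
        )
        assert classify_cosegregation(v, lenient, "fam1")

    def test_combined_is_conjunction_of_families(self, two_family_design):
        good = {
            "f1_ap": GenotypeClass.HOM_REF,
            "f1_cp": GenotypeClass.HET,
            "f1_apool": GenotypeClass.HOM_REF,
            "f1_cpool": GenotypeClass.HET,
        }
        bad2 = {
            "f2_ap": GenotypeClass.HET,
            "f2_cp": GenotypeClass.HET,
            "f2_apool": GenotypeClass.HOM_REF,
            "f2_cpool": GenotypeClass.HET,
        }
        good2 = {k: GenotypeClass.HOM_REF if k.endswith(("ap", "apool")) else GenotypeClass.HET for k in bad2}
        v_mixed = make_variant(good | bad2)
        verdict = combine_families(v_mixed, two_family_design)
        assert verdict.per_family == {"fam1": True, "fam2": False}
        assert not verdict.combined
        v_both = make_variant(good | good2)
        assert combine_families(v_both, two_family_design).combined

    @given(st.lists(st.sampled_from(CLASSES), min_size=8, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_adding_a_family_never_gains_combined_status(
        self, classes
    ):
        """Monotonicity: a variant combined-co-segregating for two families
        is co-segregating for the first family alone."""
        two_fam = CrossDesign(
            samples=[
                SampleSpec("f1_ap", "fam1", Role.AFFECTED_PARENT),
                SampleSpec("f1_cp", "fam1", Role.CARRIER_PARENT),
                SampleSpec("f1_apool", "fam1", Role.AFFECTED_POOL),
                SampleSpec("f1_cpool", "fam1", Role.CARRIER_POOL),
                SampleSpec("f2_ap", "fam2", Role.AFFECTED_PARENT),
                SampleSpec("f2_cp", "fam2", Role.CARRIER_PARENT),
                SampleSpec("f2_apool", "fam2", Role.AFFECTED_POOL),
                SampleSpec("f2_cpool", "fam2", Role.CARRIER_POOL),
            ]
        )
        one_fam = CrossDesign(samples=two_fam.samples[:4])
        sids = [s.sample_id for s in two_fam.samples]
        v = make_variant(dict(zip(sids, classes)))
        if combine_families(v, two_fam).combined:
            assert combine_families(v, one_fam).combined

    def test_design_requires_both_roles_per_family(self):
        with pytest.raises(DesignError, match="no carrier"):
            CrossDesign(samples=[SampleSpec("a", "f", Role.AFFECTED_PARENT)])
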