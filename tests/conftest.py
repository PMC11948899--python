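import pytest

from cosegscan.cross import CrossDesign, Role, SampleSpec
from cosegscan.fixtures import package_fixtures


@pytest.fixture(scope="session")
def fixture_set():
    return package_fixtures()


@pytest.fixture
def one_family_design():
    """Minimal one-family design: two parents, two pools."""
    return CrossDesign(
        samples=[
            SampleSpec("aff_parent", "fam1", Role.AFFECTED_PARENT),
            SampleSpec("car_parent", "fam1", Role.CARRIER_PARENT),
            SampleSpec("aff_pool", "fam1", Role.AFFECTED_POOL),
            SampleSpec("car_pool", "fam1", Role.CARRIER_POOL),
        ]
    )


@pytest.fixture
def two_family_design():
    return CrossDesign(
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


def write_vcf_text(path, samples, records):
    """records: list of (chrom, pos, ref, alt_csv, gt_list)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = {r[0] for r in records} or {"s1"}
        for c in sorted(chroms):
            fh.write(f"##contig=<ID={c},length=100000000>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, gts in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path
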