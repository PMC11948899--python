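"""Variant loading, repeat masking, and the genotype co-segregation filter.

Variants are read from a multi-sample VCF, split per alternate allele, and
each (record, alt) pair is classified against the genotype pattern a
recessive mono-locus cross predicts: affected samples homozygous (in the
orientation the reference assembly implies), carrier samples heterozygous.
Variants inside repeat-masked regions are excluded before classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .cross import CrossDesign, DesignError, GenotypeClass

log = logging.getLogger(__name__)


@dataclass
class Variant:
    """One bi-allelic split of a VCF record.

    ``pos`` is 1-based (VCF convention); ``alt_index`` is the 0-based index
    of the alternate allele this split refers to.
    """

    scaffold: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    alt_index: int
    genotypes: dict[str, GenotypeClass]
    in_repeat: bool = False
    filter_pass: bool = True

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.scaffold, self.pos, self.alt_index)


@dataclass
class CosegVerdict:
    """Per-family and combined co-segregation verdict for one variant."""

    variant_key: tuple[str, int, int]
    per_family: dict[str, bool]
    combined: bool = field(default=False)

    def __post_init__(self) -> None:
        assert not self.combined or all(self.per_family.values())


class VariantParseError(ValueError):
    """Raised for a malformed genotype in a VCF record."""


def classify_gt(alleles: tuple[int, int], alt_index: int) -> GenotypeClass:
    """Map an unphased diploid allele pair to a class for one alt split.

    ``alleles`` holds VCF allele indices (0 = ref, 1 = first alt, ...; -1 =
    missing).  A genotype carrying any non-reference allele other than the
    split alt is classed ``het`` for that split, preserving the
    homozygous-vs-heterozygous dichotomy without discarding the site.
    """
    a, b = alleles
    split = alt_index + 1
    if a < 0 or b < 0:
        return GenotypeClass.MISSING
    if a == 0 and b == 0:
        return GenotypeClass.HOM_REF
    if a == split and b == split:
        return GenotypeClass.HOM_ALT
    return GenotypeClass.HET


def load_variants(vcf_source: str | Path, design: CrossDesign) -> list[Variant]:
    """Read a VCF and return one :class:`Variant` per (record, alt allele).

    Genotype classes are computed relative to each alternate allele after
    multi-allelic splitting.  Samples present in the VCF but absent from the
    design are ignored; a design sample missing from the VCF header is a
    configuration error.
    """
    vcf = VCF(str(vcf_source), gts012=False)
    header_samples = list(vcf.samples)
    missing = [s for s in design.sample_ids if s not in header_samples]
    if missing:
        raise DesignError(
            f"design sample(s) absent from VCF header: {', '.join(sorted(missing))}"
        )
    col = {s: header_samples.index(s) for s in design.sample_ids}

    out: list[Variant] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a, b, phased], ...]
        pairs: dict[str, tuple[int, int]] = {}
        for sid, i in col.items():
            g = gts[i]
            if len(g) < 2:
                raise VariantParseError(
                    f"{rec.CHROM}:{rec.POS} sample {sid}: non-diploid GT {g!r}"
                )
            pairs[sid] = (int(g[0]), int(g[1]))
        passed = rec.FILTER is None  # cyvcf2: None means PASS/'.'
        for alt_index, _alt in enumerate(rec.ALT):
            out.append(
                Variant(
                    scaffold=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_alleles=list(rec.ALT),
                    alt_index=alt_index,
                    genotypes={
                        sid: classify_gt(p, alt_index) for sid, p in pairs.items()
                    },
                    filter_pass=passed,
                )
            )
    if design.pass_only:
        out = [v for v in out if v.filter_pass]
    return out


def read_mask_bed(bed_path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED3 file of masked regions into per-scaffold interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def apply_repeat_mask(
    variants: Iterable[Variant],
    mask: dict[str, IntervalTree] | str | Path,
) -> list[Variant]:
    """Flag variants whose position falls in a masked interval.

    BED intervals are 0-based half-open; a variant at 1-based ``pos`` is
    masked when ``pos - 1`` lies inside an interval.  Scaffolds present only
    in the BED produce a warning, not an error.  Idempotent and independent
    of BED interval order.
    """
    if not isinstance(mask, dict):
        mask = read_mask_bed(mask)
    variants = list(variants)
    seen_scaffolds = {v.scaffold for v in variants}
    for chrom in set(mask) - seen_scaffolds:
        warnings.warn(f"mask scaffold {chrom!r} has no variants", stacklevel=2)
    for v in variants:
        tree = mask.get(v.scaffold)
        v.in_repeat = bool(tree is not None and tree.overlaps(v.pos - 1))
    return variants


def classify_cosegregation(
    variant: Variant, design: CrossDesign, family_id: str
) -> bool:
    """Does this variant co-segregate with the recessive trait in one family?

    True iff every affected-role sample shows the orientation-expected
    homozygous class and every carrier-role sample is heterozygous.  Under
    ``missing_policy=fail_variant`` any missing required genotype makes the
    variant non-co-segregating; under ``ignore_sample`` missing samples are
    skipped (a family with all genotypes missing does not co-segregate).
    """
    members = design.family_samples(family_id)
    ignore = design.missing_policy.value == "ignore_sample"
    n_checked = 0
    for spec in members:
        cls = variant.genotypes.get(spec.sample_id, GenotypeClass.MISSING)
        if cls is GenotypeClass.MISSING:
            if ignore:
                continue
            return False
        if cls is not design.expected_class(spec.role):
            return False
        n_checked += 1
    return n_checked > 0


def combine_families(variant: Variant, design: CrossDesign) -> CosegVerdict:
    """Per-family verdicts plus their conjunction across all families.

    A parent shared between families (sequenced as one library per family)
    contributes once per family.
    """
    per_family = {
        fam: classify_cosegregation(variant, design, fam) for fam in design.family_ids
    }
    return CosegVerdict(
        variant_key=variant.key,
        per_family=per_family,
        combined=all(per_family.values()),
    )


def cosegregation_table(
    variants: Iterable[Variant], design: CrossDesign, skip_masked: bool = True
) -> pd.DataFrame:
    """Classify every variant; returns one row per (scaffold, pos, alt).

    Masked variants are excluded by default (they never enter the filter).
    Columns: scaffold, pos, alt_index, ``coseg_<family>`` per family,
    ``coseg_combined``.
    """
    rows = []
    for v in variants:
        if skip_masked and v.in_repeat:
            continue
        verdict = combine_families(v, design)
        row: dict = {"scaffold": v.scaffold, "pos": v.pos, "alt_index": v.alt_index}
        for fam, ok in verdict.per_family.items():
            row[f"coseg_{fam}"] = ok
        row["coseg_combined"] = verdict.combined
        rows.append(row)
    cols = ["scaffold", "pos", "alt_index"] + [
        f"coseg_{f}" for f in design.family_ids
    ] + ["coseg_combined"]
    return pd.DataFrame(rows, columns=cols)
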