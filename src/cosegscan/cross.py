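"""Cross designs for recessive-trait mapping-by-sequencing.

A mapping cross consists, per family, of an affected parent, a carrier
parent, and pooled offspring libraries of each phenotype class, each
sequenced and genotyped as a single diploid sample.  Under a recessive
mono-locus model, a variant co-segregates with the trait when every
affected-role sample is homozygous (for the allele phase implied by the
reference individual) and every carrier-role sample is heterozygous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class Role(str, enum.Enum):
    AFFECTED_PARENT = "affected_parent"
    CARRIER_PARENT = "carrier_parent"
    AFFECTED_POOL = "affected_pool"
    CARRIER_POOL = "carrier_pool"

    @property
    def is_affected(self) -> bool:
        return self in (Role.AFFECTED_PARENT, Role.AFFECTED_POOL)


class GenotypeClass(str, enum.Enum):
    """Unphased diploid genotype class relative to one alt allele.

    ``0/1`` and ``1/0`` are equivalent; phased separators are reduced to
    unphased classes.
    """

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Orientation(str, enum.Enum):
    """Which allele phase the reference assembly carries at the locus.

    When the reference individual is heterozygous for the mutant allele
    (``reference_carries_mutant``), affected samples are expected to be
    homozygous *reference* (0/0) at diagnostic sites; otherwise homozygous
    alternate.  Carrier samples expect ``het`` under either orientation.
    """

    REFERENCE_CARRIES_MUTANT = "reference_carries_mutant"
    REFERENCE_CARRIES_WILDTYPE = "reference_carries_wildtype"

    @property
    def affected_class(self) -> GenotypeClass:
        if self is Orientation.REFERENCE_CARRIES_MUTANT:
            return GenotypeClass.HOM_REF
        return GenotypeClass.HOM_ALT


class MissingPolicy(str, enum.Enum):
    FAIL_VARIANT = "fail_variant"
    IGNORE_SAMPLE = "ignore_sample"


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    family_id: str
    role: Role


class DesignError(ValueError):
    """Raised for an invalid or inconsistent cross design."""


@dataclass
class CrossDesign:
    samples: list[SampleSpec]
    orientation: Orientation = Orientation.REFERENCE_CARRIES_MUTANT
    missing_policy: MissingPolicy = MissingPolicy.FAIL_VARIANT
    pass_only: bool = False

    _by_family: dict[str, list[SampleSpec]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.orientation = Orientation(self.orientation)
        self.missing_policy = MissingPolicy(self.missing_policy)
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise DesignError(f"duplicate sample_id {s.sample_id!r} in design")
            seen.add(s.sample_id)
            self._by_family.setdefault(s.family_id, []).append(s)
        for fam, members in self._by_family.items():
            roles = {m.role for m in members}
            if not any(r.is_affected for r in roles):
                raise DesignError(f"family {fam!r} has no affected-role sample")
            if not any(not r.is_affected for r in roles):
                raise DesignError(f"family {fam!r} has no carrier-role sample")

    @property
    def family_ids(self) -> list[str]:
        return list(self._by_family)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def family_samples(self, family_id: str) -> list[SampleSpec]:
        try:
            return self._by_family[family_id]
        except KeyError:
            raise DesignError(f"unknown family {family_id!r}") from None

    def expected_class(self, role: Role) -> GenotypeClass:
        return self.orientation.affected_class if role.is_affected else GenotypeClass.HET

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CrossDesign":
        """Load a design from a YAML file.

        Expected layout::

            orientation: reference_carries_mutant
            missing_policy: fail_variant
            samples:
              - {sample_id: f1_father, family_id: fam1, role: carrier_parent}
              ...
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "samples" not in raw:
            raise DesignError(f"{path}: design file must define a 'samples' list")
        samples = [
            SampleSpec(
                sample_id=str(s["sample_id"]),
                family_id=str(s["family_id"]),
                role=Role(s["role"]),
            )
            for s in raw["samples"]
        ]
        return cls(
            samples=samples,
            orientation=Orientation(raw.get("orientation", "reference_carries_mutant")),
            missing_policy=MissingPolicy(raw.get("missing_policy", "fail_variant")),
            pass_only=bool(raw.get("pass_only", False)),
        )

    def to_dict(self) -> dict:
        return {
            "orientation": self.orientation.value,
            "missing_policy": self.missing_policy.value,
            "pass_only": self.pass_only,
            "samples": [
                {"sample_id": s.sample_id, "family_id": s.family_id, "role": s.role.value}
                for s in self.samples
            ],
        }
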