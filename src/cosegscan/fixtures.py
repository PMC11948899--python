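"""Synthetic stand-ins for the CLCN2/retroelement worked-example sequences.

The real wild-type and Stripe CLCN2 transcripts, the 5832-bp Copia
LTR-retrotransposon, and the paired CLCN2/OCA2 element inserts are not
redistributable here, so this module constructs synthetic sequences with
the same structural anatomy, deterministically and in code:

* a 2643-bp coding sequence translating to an 880-aa protein;
* a 397-bp insert placed after CDS position 605 (the transcript carrying
  it has the insert between positions 605 and 1002) whose reading frame
  introduces four novel residues past the exon-5 junction followed by a
  premature stop, truncating the protein to 205 aa;
* a 5832-bp retroelement containing the three fragments that splice into
  the 397-bp insert;
* a second element copy differing from the first by exactly one
  nucleotide substitution.

Every downstream number (protein lengths, novel residues, substitution
counts) is computed by the package's own operations, never asserted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .consequence import STOP_CODONS, TranscriptInsertion
from .junction import JunctionModel

_FIXTURE_SEED = 58_320  # frozen; fixtures are part of the package surface

WT_CDS_LENGTH = 2643
INSERT_LENGTH = 397
INSERT_AFTER = 605  # 1-based CDS position of the last base before the insert
ELEMENT_LENGTH = 5832
FRAGMENT_LENGTHS = (132, 140, 125)  # three spliced fragments, summing to 397
FRAGMENT_STARTS = (500, 2200, 4600)  # fragment positions within the element
SUBSTITUTION_POS = 2911  # 0-based; the single CLCN2-vs-OCA2 insert difference

_NON_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class FixtureSet:
    """Synthetic worked-example sequences (see module docstring)."""

    wildtype_cds: str
    insert_seq: str
    insert_after: int
    element_clcn2: str
    element_oca2: str
    stripe_transcript: str
    junction: JunctionModel

    @property
    def transcript_insertion(self) -> TranscriptInsertion:
        return TranscriptInsertion(
            wildtype_cds=self.wildtype_cds,
            insert_seq=self.insert_seq,
            insert_after=self.insert_after,
        )

    def as_dict(self) -> dict[str, str]:
        return {
            "wildtype_cds_synthetic": self.wildtype_cds,
            "stripe_insert_synthetic": self.insert_seq,
            "element_clcn2_synthetic": self.element_clcn2,
            "element_oca2_synthetic": self.element_oca2,
            "stripe_transcript_synthetic": self.stripe_transcript,
        }


def _random_codons(n: int, rng: np.random.Generator) -> str:
    return "".join(_NON_STOP[i] for i in rng.integers(0, len(_NON_STOP), size=n))


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def package_fixtures() -> FixtureSet:
    """Build the deterministic synthetic fixture set."""
    rng = np.random.default_rng(_FIXTURE_SEED)

    # CDS: ATG + 879 internal non-stop codons + TAA = 2643 bp, 880 aa.
    internal = _random_codons((WT_CDS_LENGTH - 6) // 3, rng)
    # pin the final residue (Ala) so it differs from the insert-encoded
    # terminal residue below
    internal = internal[:-3] + "GCT"
    # pin the codon the insertion interrupts (codon 202, internal index 200)
    # so its first two bases cannot combine with the insert into a stop
    internal = internal[:600] + "CTT" + internal[603:]
    wildtype_cds = "ATG" + internal + "TAA"

    # Insert anatomy relative to the reading frame: CDS position 605 splits
    # codon 202 after its second base, so insert base 1 completes codon 202
    # and bases 2-10 encode three further residues before a TAA stop at
    # codon 206 -> four novel residues, 205-aa protein.
    head = "G"  # codon 202 becomes cds[603:605] + 'G' (never a stop)
    novel_codons = _random_codons(2, rng) + "TGG"  # last novel residue: Trp
    stop = "TAA"
    tail = _random_bases(INSERT_LENGTH - len(head) - len(novel_codons) - len(stop), rng)
    insert_seq = head + novel_codons + stop + tail
    assert len(insert_seq) == INSERT_LENGTH

    # Element: random background carrying the three insert fragments in
    # order at fixed positions.
    fragments = []
    offset = 0
    for length in FRAGMENT_LENGTHS:
        fragments.append(insert_seq[offset : offset + length])
        offset += length
    element = list(_random_bases(ELEMENT_LENGTH, rng))
    for start, frag in zip(FRAGMENT_STARTS, fragments):
        element[start : start + len(frag)] = frag
    element_clcn2 = "".join(element)

    # Second insert copy: exactly one substitution.
    original = element_clcn2[SUBSTITUTION_POS]
    replacement = {"A": "G", "G": "A", "C": "T", "T": "C"}[original]
    element_oca2 = (
        element_clcn2[:SUBSTITUTION_POS]
        + replacement
        + element_clcn2[SUBSTITUTION_POS + 1 :]
    )

    stripe_transcript = (
        wildtype_cds[:INSERT_AFTER] + insert_seq + wildtype_cds[INSERT_AFTER:]
    )
    junction = JunctionModel(
        reference_id="CLCN2_stripe_synthetic",
        upstream_junction=INSERT_AFTER,
        downstream_junction=INSERT_AFTER + INSERT_LENGTH,
    )
    return FixtureSet(
        wildtype_cds=wildtype_cds,
        insert_seq=insert_seq,
        insert_after=INSERT_AFTER,
        element_clcn2=element_clcn2,
        element_oca2=element_oca2,
        stripe_transcript=stripe_transcript,
        junction=junction,
    )


def pairwise_substitutions(a: str, b: str) -> tuple[int, int]:
    """(substitutions, indel columns) in a global alignment of two sequences."""
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="path")
    subs = indels = 0
    n = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            n += ch
        else:
            length = int(n)
            n = ""
            if ch == "X":
                subs += length
            elif ch in "ID":
                indels += length
    return subs, indels
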