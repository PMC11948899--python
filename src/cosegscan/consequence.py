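"""Coding consequence of a transcript insertion.

Splices an insert into a wild-type CDS at a given position, translates the
result in the original reading frame, and reports truncation by a premature
stop together with the number of novel residues introduced past the
junction (residues that do not simply continue the wild-type protein).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranscriptInsertion:
    """An insert placed after 1-based CDS position ``insert_after``."""

    wildtype_cds: str
    insert_seq: str
    insert_after: int

    def __post_init__(self) -> None:
        cds = self.wildtype_cds.upper()
        if not 0 <= self.insert_after <= len(cds):
            raise ValueError("insert_after outside the CDS")
        if len(cds) % 3:
            raise ValueError("wild-type CDS length not divisible by 3")
        if cds[:3] != "ATG":
            raise ValueError("wild-type CDS must start with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise ValueError("wild-type CDS must end with a stop codon")


@dataclass
class ConsequenceReport:
    mutant_cds: str
    protein: str
    truncated: bool
    protein_length: int
    novel_aa_after_junction: int
    stop_loss: bool = False

    def to_dict(self) -> dict:
        return {
            "protein_length": self.protein_length,
            "truncated": self.truncated,
            "novel_aa_after_junction": self.novel_aa_after_junction,
            "stop_loss": self.stop_loss,
            "protein": self.protein,
            "mutant_cds": self.mutant_cds,
        }


def splice_insertion(ti: TranscriptInsertion) -> str:
    """Mutant CDS = wild type with the insert placed after ``insert_after``.

    Which genomic fragments splice into the realized insert is not
    predicted here; the insert sequence is an input.
    """
    cds = ti.wildtype_cds.upper()
    ins = ti.insert_seq.upper()
    return cds[: ti.insert_after] + ins + cds[ti.insert_after :]


def _translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate frame 1 up to (excluding) the first stop; flags stop seen."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    if stop == -1:
        return aa, False
    return aa[:stop], True


def annotate_consequence(ti: TranscriptInsertion) -> ConsequenceReport:
    """Translate the spliced CDS and report the coding consequence.

    ``novel_aa_after_junction`` counts the residues past the last complete
    wild-type codon before the insertion (position ``insert_after // 3``)
    that do not match a resumption of the wild-type protein — i.e. the
    mutant residues up to the point where the protein, if it ever does,
    re-joins the wild-type carboxy-terminal sequence.  Standard nuclear
    codon table; an insert removing the stop entirely is flagged
    ``stop_loss`` rather than truncated.
    """
    wt_protein, _ = _translate_to_stop(ti.wildtype_cds.upper())
    mutant = splice_insertion(ti)
    protein, saw_stop = _translate_to_stop(mutant)

    junction_aa = ti.insert_after // 3
    tail_mut = protein[junction_aa:]
    tail_wt = wt_protein[junction_aa:]
    common_suffix = 0
    while (
        common_suffix < len(tail_mut)
        and common_suffix < len(tail_wt)
        and tail_mut[len(tail_mut) - 1 - common_suffix]
        == tail_wt[len(tail_wt) - 1 - common_suffix]
    ):
        common_suffix += 1
    novel = len(tail_mut) - common_suffix

    return ConsequenceReport(
        mutant_cds=mutant,
        protein=protein,
        truncated=saw_stop and len(protein) < len(wt_protein),
        protein_length=len(protein),
        novel_aa_after_junction=novel,
        stop_loss=not saw_stop,
    )
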