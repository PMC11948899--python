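"""Detection of reads spanning a retroelement insertion junction.

Reads are aligned to a junction-bearing reference (the host transcript with
the insertion sequence added).  A read is accepted as junction-spanning
evidence when its alignment starts 80 to 10 bp before a junction boundary
— guaranteeing roughly ten aligned bases on each side for ~100-bp reads —
and its soft-clipped (or hard-clipped) ends are each shorter than 5 bp,
excluding chimeric partial mappings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

QUERY_OPS = set("MIS=X")
REF_OPS = set("MD=XN")

START_WINDOW_DEFAULT = (-80, -10)
MAX_SOFTCLIP_DEFAULT = 5


@dataclass(frozen=True)
class JunctionModel:
    """Insert coordinates on the junction-bearing reference.

    ``upstream_junction`` is the 1-based position of the last host base
    before the insert; ``downstream_junction`` the last base of the insert.
    The insert occupies positions (upstream_junction, downstream_junction].
    """

    reference_id: str
    upstream_junction: int
    downstream_junction: int

    def __post_init__(self) -> None:
        if self.downstream_junction <= self.upstream_junction:
            raise ValueError("downstream_junction must exceed upstream_junction")

    @property
    def insert_length(self) -> int:
        return self.downstream_junction - self.upstream_junction


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record: 1-based start plus a CIGAR."""

    read_id: str
    start: int
    cigar: tuple[tuple[str, int], ...]
    read_length: int

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
        if qlen != self.read_length:
            raise ValueError(
                f"{self.read_id}: query-consuming CIGAR length {qlen} != "
                f"read_length {self.read_length}"
            )
        core = [op for op, _ in self.cigar]
        for i, op in enumerate(core):
            if op in "SH" and not (
                i == 0
                or i == len(core) - 1
                or (i == 1 and core[0] == "H")
                or (i == len(core) - 2 and core[-1] == "H")
            ):
                raise ValueError(f"{self.read_id}: internal clip in CIGAR")

    @property
    def clip_lengths(self) -> tuple[int, int]:
        """(left, right) clipped lengths; hard clips count like soft clips."""
        left = right = 0
        ops = list(self.cigar)
        i = 0
        while i < len(ops) and ops[i][0] in "SH":
            left += ops[i][1]
            i += 1
        j = len(ops) - 1
        while j >= i and ops[j][0] in "SH":
            right += ops[j][1]
            j -= 1
        return left, right

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive reference span [start, aln_end]."""
        ref_len = sum(n for op, n in self.cigar if op in REF_OPS)
        return self.start, self.start + ref_len - 1


@dataclass(frozen=True)
class JunctionHit:
    read_id: str
    junction: str  # "upstream" | "downstream"
    start: int
    left_overhang: int
    right_overhang: int


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    out = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            if not n or ch not in "MIDSH=XNP":
                raise ValueError(f"malformed CIGAR {cigar!r}")
            out.append((ch, int(n)))
            n = ""
    if n:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return tuple(out)


def read_sam(path: str | Path, reference_id: str | None = None) -> list[AlignedRead]:
    """Load mapped reads from a SAM file (optionally one reference only)."""
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigarstring is None:
                continue
            if reference_id is not None and aln.reference_name != reference_id:
                continue
            cigar = parse_cigar(aln.cigarstring)
            qlen = sum(n for op, n in cigar if op in QUERY_OPS)
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    start=aln.reference_start + 1,
                    cigar=cigar,
                    read_length=qlen,
                )
            )
    return reads


def detect_junction_reads(
    reads: Iterable[AlignedRead],
    junction: JunctionModel,
    start_window: tuple[int, int] = START_WINDOW_DEFAULT,
    max_softclip: int = MAX_SOFTCLIP_DEFAULT,
) -> list[JunctionHit]:
    """Apply the alignment-start/soft-clip rule for each junction boundary.

    A read hits junction J (upstream insert boundary or downstream one) iff
    its alignment start lies in [J + start_window[0], J + start_window[1]],
    every clipped end is < ``max_softclip`` bases, and its aligned span
    actually crosses J.  Under the defaults the two start windows are
    disjoint, so a read hits at most one junction; the upstream junction is
    checked first.
    """
    lo_off, hi_off = start_window
    hits: list[JunctionHit] = []
    for read in reads:
        left_clip, right_clip = read.clip_lengths
        if left_clip >= max_softclip or right_clip >= max_softclip:
            continue
        aln_start, aln_end = read.ref_span
        for name, j in (
            ("upstream", junction.upstream_junction),
            ("downstream", junction.downstream_junction),
        ):
            if j + lo_off <= aln_start <= j + hi_off and aln_end > j:
                hits.append(
                    JunctionHit(
                        read_id=read.read_id,
                        junction=name,
                        start=aln_start,
                        left_overhang=j - aln_start + 1,
                        right_overhang=aln_end - j,
                    )
                )
                break
    return hits


def hits_table(hits: Sequence[JunctionHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "junction": h.junction,
                "start": h.start,
                "left_overhang": h.left_overhang,
                "right_overhang": h.right_overhang,
            }
            for h in hits
        ],
        columns=["read_id", "junction", "start", "left_overhang", "right_overhang"],
    )
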