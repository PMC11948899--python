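"""Counting near-identical retroelement copies in a genome.

Seed-and-extend homology search: exact k-mer anchors from the query element
are located in each genome sequence, anchors sharing a diagonal are chained
(two-hit rule), and each chained candidate locus is aligned with a banded
gapped aligner.  A locus counts as a copy when the alignment covers at
least ``min_match_len`` columns at ``min_identity`` identity, identity
being matches over all alignment columns (gaps count against identity).
Overlapping hits collapse to one copy; both strands are searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import edlib
import pandas as pd
from Bio.Seq import reverse_complement

SEED_K_DEFAULT = 31
SEED_STRIDE = 50  # query probe spacing, bp
CHAIN_SLACK = 200  # max diagonal drift allowed within one chain, bp
MIN_SEEDS = 2  # two-hit chaining
FLANK = 300  # extension margin around a chained candidate, bp


@dataclass(frozen=True)
class ElementQuery:
    element_seq: str
    min_match_len: int = 5000
    min_identity: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_match_len > len(self.element_seq):
            raise ValueError("min_match_len exceeds the element length")


@dataclass
class ElementHit:
    scaffold: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+" | "-"
    identity: float
    aligned_columns: int


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(match columns, total columns) from an extended CIGAR (=/X/I/D)."""
    matches = columns = 0
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            length = int(n)
            n = ""
            columns += length
            if ch == "=":
                matches += length
    return matches, columns


def _candidate_regions(seq: str, probes: list[tuple[int, str]], elem_len: int):
    """Chain exact probe matches into candidate (start, end) genome regions."""
    anchors: list[int] = []  # implied element-start positions in the genome
    for offset, probe in probes:
        pos = seq.find(probe)
        while pos != -1:
            anchors.append(pos - offset)
            pos = seq.find(probe, pos + 1)
    anchors.sort()
    regions = []
    i = 0
    while i < len(anchors):
        j = i
        while j + 1 < len(anchors) and anchors[j + 1] - anchors[j] <= CHAIN_SLACK:
            j += 1
        if j - i + 1 >= MIN_SEEDS:
            start = max(0, anchors[i] - FLANK)
            end = min(len(seq), anchors[j] + elem_len + FLANK)
            regions.append((start, end))
        i = j + 1
    # merge overlapping candidate regions
    merged: list[tuple[int, int]] = []
    for start, end in regions:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _align(element: str, window: str) -> tuple[int, int, float, int] | None:
    """Best infix alignment of the element in the window.

    Returns (start, end, identity, columns) in window coordinates, or None
    when no alignment exists.
    """
    res = edlib.align(element, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    matches, columns = _cigar_stats(res["cigar"])
    loc_start, loc_end = res["locations"][0]
    return loc_start, loc_end + 1, matches / columns, columns


def scan_element_copies(
    genome: Mapping[str, str] | Iterable[tuple[str, str]],
    query: ElementQuery,
    seed_k: int = SEED_K_DEFAULT,
) -> list[ElementHit]:
    """Find copies of the query element in a genome, both strands.

    Hits overlapping on the same scaffold are collapsed to the single best
    copy (highest identity).  Sequences are uppercase-normalized.
    """
    element = query.element_seq.upper()
    strands = [("+", element), ("-", reverse_complement(element))]
    items = genome.items() if isinstance(genome, Mapping) else genome

    hits: list[ElementHit] = []
    for name, raw_seq in items:
        seq = str(raw_seq).upper()
        for strand, elem in strands:
            probes = [
                (off, elem[off : off + seed_k])
                for off in range(0, len(elem) - seed_k + 1, SEED_STRIDE)
            ]
            for rstart, rend in _candidate_regions(seq, probes, len(elem)):
                aln = _align(elem, seq[rstart:rend])
                if aln is None:
                    continue
                a_start, a_end, identity, columns = aln
                if columns >= query.min_match_len and identity >= query.min_identity:
                    hits.append(
                        ElementHit(
                            scaffold=name,
                            start=rstart + a_start,
                            end=rstart + a_end,
                            strand=strand,
                            identity=identity,
                            aligned_columns=columns,
                        )
                    )
    return _collapse(hits)


def _collapse(hits: list[ElementHit]) -> list[ElementHit]:
    """Collapse overlapping hits on the same scaffold, keeping the best."""
    out: list[ElementHit] = []
    for h in sorted(hits, key=lambda h: (h.scaffold, h.start, -h.identity)):
        if out and out[-1].scaffold == h.scaffold and h.start < out[-1].end:
            if h.identity > out[-1].identity:
                out[-1] = h
        else:
            out.append(h)
    return out


def hits_gff(hits: Iterable[ElementHit], source: str = "cosegscan") -> pd.DataFrame:
    """GFF3-style feature table for found copies (1-based coordinates)."""
    return pd.DataFrame(
        [
            {
                "seqid": h.scaffold,
                "source": source,
                "type": "mobile_element",
                "start": h.start + 1,
                "end": h.end,
                "score": round(h.identity, 4),
                "strand": h.strand,
                "phase": ".",
                "attributes": f"aligned_columns={h.aligned_columns}",
            }
            for h in hits
        ],
        columns=[
            "seqid",
            "source",
            "type",
            "start",
            "end",
            "score",
            "strand",
            "phase",
            "attributes",
        ],
    )
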