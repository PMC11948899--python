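"""Sliding-window co-segregation proportions and candidate-interval calling.

The mapping signal is summarized as the proportion of co-segregating
variants in overlapping windows (default 1 Mb wide, 100 kb step) along each
scaffold.  The candidate interval is the merged run of near-maximal windows
containing the global peak; it can then be narrowed with individually
genotyped recombinant offspring, whose first phenotype-inconsistent marker
on each side bounds the locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cross import GenotypeClass, Orientation
from .variants import CosegVerdict, Variant

log = logging.getLogger(__name__)

WINDOW_SIZE_DEFAULT = 1_000_000
STEP_DEFAULT = 100_000


@dataclass(frozen=True)
class Window:
    scaffold: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    partial: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class WindowStat:
    window: Window
    n_coseg: int
    n_denom: int

    @property
    def defined(self) -> bool:
        return self.n_denom > 0

    @property
    def proportion(self) -> float:
        return self.n_coseg / self.n_denom if self.defined else 0.0


@dataclass
class IntervalCall:
    scaffold: str | None
    start_bp: int
    end_bp: int
    n_coseg: int
    peak_proportion: float
    no_signal: bool = False

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6

    @property
    def density_per_mb(self) -> int:
        return round_half_away(self.n_coseg / self.length_mb) if self.length_mb else 0

    def to_dict(self) -> dict:
        return {
            "scaffold": self.scaffold,
            "start_bp": self.start_bp,
            "end_bp": self.end_bp,
            "n_coseg": self.n_coseg,
            "length_mb": self.length_mb,
            "density_per_mb": self.density_per_mb,
            "peak_proportion": self.peak_proportion,
            "no_signal": self.no_signal,
        }


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (345/5.7 -> 61)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def scan_windows(
    verdicts: Sequence[CosegVerdict],
    variants: Sequence[Variant],
    window_size: int = WINDOW_SIZE_DEFAULT,
    step: int = STEP_DEFAULT,
    denominator_mode: str = "all_variants",
    scaffold_lengths: Mapping[str, int] | None = None,
    parental_coseg: Mapping[tuple[str, int, int], bool] | None = None,
) -> list[WindowStat]:
    """Per-window co-segregation proportions along every scaffold.

    Windows are anchored at coordinate 0 and advance by ``step``; terminal
    partial windows are kept and flagged.  The numerator counts variants
    co-segregating across all libraries (``combined``).  The denominator is
    either every unmasked variant in the window (``all_variants``) or only
    those co-segregating in the parental libraries (``parental_coseg``,
    requiring the ``parental_coseg`` map).  A variant is counted in every
    window containing it.
    """
    if not (window_size >= step > 0):
        raise ValueError("require window_size >= step > 0")
    if denominator_mode not in ("all_variants", "parental_coseg"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    if denominator_mode == "parental_coseg" and parental_coseg is None:
        raise ValueError("parental_coseg map required for that denominator mode")

    combined = {v.variant_key: v.combined for v in verdicts}
    items = [(v.scaffold, v.pos, v.key) for v in variants if not v.in_repeat]
    if items != sorted(items, key=lambda t: (t[0], t[1])):
        log.info("variants unsorted; sorting internally")
        items.sort(key=lambda t: (t[0], t[1]))

    by_scaffold: dict[str, list[tuple[int, tuple]]] = {}
    for scaf, pos, key in items:
        by_scaffold.setdefault(scaf, []).append((pos, key))
    lengths: dict[str, int] = dict(scaffold_lengths or {})
    for scaf, lst in by_scaffold.items():
        lengths.setdefault(scaf, lst[-1][0])

    stats: list[WindowStat] = []
    for scaf in sorted(lengths):
        length = lengths[scaf]
        positions = by_scaffold.get(scaf, [])
        start = 0
        while start < length:
            end = min(start + window_size, length)
            n_num = n_den = 0
            for pos, key in positions:  # pos is 1-based; window 0-based half-open
                if start < pos <= end:
                    in_denom = (
                        denominator_mode == "all_variants"
                        or parental_coseg.get(key, False)  # type: ignore[union-attr]
                    )
                    if in_denom:
                        n_den += 1
                    if combined.get(key, False):
                        n_num += 1
            stats.append(
                WindowStat(
                    Window(scaf, start, end, partial=(end - start < window_size)),
                    n_coseg=n_num,
                    n_denom=n_den,
                )
            )
            start += step
    return stats


def windows_table(stats: Iterable[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold": s.window.scaffold,
                "start": s.window.start,
                "end": s.window.end,
                "n_coseg": s.n_coseg,
                "n_denom": s.n_denom,
                "proportion": s.proportion,
                "defined": s.defined,
            }
            for s in stats
        ]
    )


def call_interval(
    stats: Sequence[WindowStat],
    verdicts: Sequence[CosegVerdict] | None = None,
    variants: Sequence[Variant] | None = None,
    threshold_fraction: float = 0.9,
) -> IntervalCall:
    """Merge near-maximal windows into the dominant candidate interval.

    Windows with proportion >= ``threshold_fraction`` times the global
    maximum are selected, overlapping/adjacent selected windows on the same
    scaffold are merged, and the merged run containing the global-maximum
    window is returned.  ``n_coseg`` counts combined co-segregating variants
    inside the interval when ``verdicts``/``variants`` are given, else sums
    non-overlapping window counts.  With no defined window an explicit
    no-signal call is returned.
    """
    defined = [s for s in stats if s.defined]
    if not defined:
        return IntervalCall(None, 0, 0, 0, 0.0, no_signal=True)
    peak = max(defined, key=lambda s: s.proportion)
    if peak.proportion == 0.0:
        return IntervalCall(None, 0, 0, 0, 0.0, no_signal=True)
    cutoff = threshold_fraction * peak.proportion
    selected = sorted(
        (s for s in defined if s.proportion >= cutoff),
        key=lambda s: (s.window.scaffold, s.window.start),
    )

    runs: list[list[WindowStat]] = []
    for s in selected:
        if (
            runs
            and runs[-1][-1].window.scaffold == s.window.scaffold
            and s.window.start <= runs[-1][-1].window.end
        ):
            runs[-1].append(s)
        else:
            runs.append([s])
    run = next(r for r in runs if peak in r)
    scaffold = run[0].window.scaffold
    start_bp = min(s.window.start for s in run)
    end_bp = max(s.window.end for s in run)

    if verdicts is not None and variants is not None:
        combined = {v.variant_key: v.combined for v in verdicts}
        n_coseg = sum(
            1
            for v in variants
            if not v.in_repeat
            and v.scaffold == scaffold
            and start_bp < v.pos <= end_bp
            and combined.get(v.key, False)
        )
    else:
        # without variant-level data the peak window's count is the best
        # overlap-free summary available
        n_coseg = peak.n_coseg
    return IntervalCall(scaffold, start_bp, end_bp, n_coseg, peak.proportion)


# ---------------------------------------------------------------------------
# Recombinant-based refinement


@dataclass
class RecombinantCall:
    """Genotypes of one Sanger-typed individual at diagnostic sites.

    ``site_genotypes`` maps 1-based positions (within or flanking the
    candidate interval) to genotype classes.  An affected individual is
    expected to be homozygous (orientation-appropriate) at every fully
    linked site; a carrier heterozygous.  Sites breaking the expectation
    place a recombination breakpoint.
    """

    individual_id: str
    phenotype: str  # "affected" | "carrier"
    site_genotypes: dict[int, GenotypeClass]
    is_recombinant: bool = field(init=False, default=False)
    consistent_segment: tuple[float, float] = field(
        init=False, default=(float("-inf"), float("inf"))
    )

    def evaluate(self, orientation: Orientation) -> None:
        expected = (
            orientation.affected_class
            if self.phenotype == "affected"
            else GenotypeClass.HET
        )
        sites = sorted(self.site_genotypes)
        flags = [self.site_genotypes[p] is expected for p in sites]
        self.is_recombinant = not all(flags)
        if not self.is_recombinant:
            self.consistent_segment = (float("-inf"), float("inf"))
            return
        # maximal run of consistent sites (most sites; first on ties), bounded
        # exclusively by the nearest inconsistent site on each side
        runs: list[tuple[int, int]] = []
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        if not runs:
            self.consistent_segment = (float("nan"), float("nan"))
            return
        best = max(runs, key=lambda r: r[1] - r[0])
        lo = float(sites[best[0] - 1]) if best[0] > 0 else float("-inf")
        hi = float(sites[best[1] + 1]) if best[1] + 1 < len(sites) else float("inf")
        self.consistent_segment = (lo, hi)


class RefinementConflictError(ValueError):
    def __init__(self, individuals: list[str]):
        self.individuals = individuals
        super().__init__(
            "recombinant segments leave an empty interval; conflicting "
            f"individuals: {', '.join(individuals)}"
        )


def refine_with_recombinants(
    interval: IntervalCall,
    calls: Sequence[RecombinantCall],
    orientation: Orientation = Orientation.REFERENCE_CARRIES_MUTANT,
) -> IntervalCall:
    """Intersect the interval with every individual's consistent segment.

    Each inconsistent site bounds the locus exclusively on its side; the
    refined interval is the original intersected with all segments.  The
    result never grows and is independent of the order of ``calls``.  An
    empty intersection raises, naming the individuals whose segments exclude
    the final interval (phenotyping/genotyping error or wrong interval).
    """
    start, end = float(interval.start_bp), float(interval.end_bp)
    constraints: list[tuple[str, float, float]] = []
    for call in calls:
        call.evaluate(orientation)
        if not call.is_recombinant:
            continue
        lo, hi = call.consistent_segment
        if lo != lo:  # all sites inconsistent: individual excludes everything
            raise RefinementConflictError([call.individual_id])
        constraints.append((call.individual_id, lo, hi))
        # exclusive boundaries: site at lo excluded -> start after it;
        # site at hi excluded -> end at it ([start, end) convention)
        start = max(start, lo + 1)
        end = min(end, hi)
    if start >= end:
        conflicting = [
            cid for cid, lo, hi in constraints if lo + 1 >= end or hi <= start
        ] or [cid for cid, _, _ in constraints]
        raise RefinementConflictError(sorted(set(conflicting)))
    return IntervalCall(
        scaffold=interval.scaffold,
        start_bp=int(start),
        end_bp=int(end),
        n_coseg=interval.n_coseg,
        peak_proportion=interval.peak_proportion,
    )


def read_recombinant_sites(path) -> list[RecombinantCall]:
    """Read a sites TSV: individual, phenotype, position, genotype."""
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    required = {"individual", "phenotype", "position", "genotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"sites file must have columns {sorted(required)}")
    calls = []
    for (ind, phen), grp in df.groupby(["individual", "phenotype"], sort=True):
        calls.append(
            RecombinantCall(
                individual_id=str(ind),
                phenotype=str(phen),
                site_genotypes={
                    int(p): GenotypeClass(g)
                    for p, g in zip(grp["position"], grp["genotype"])
                },
            )
        )
    return calls
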