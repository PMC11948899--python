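"""Synthetic crosses, junction read sets, and planted-element genomes.

The cross simulator emulates the study design the mapping filter assumes:
two families of a recessive mono-locus cross (a carrier father shared
between families, affected mothers), each sequenced as one library per
parent plus one pooled library per offspring phenotype class, genotyped as
single diploid samples.  Markers are sites where the carrier parent is
heterozygous with the mutant-linked haplotype carrying the reference
allele (the reference individual being heterozygous for the trait) and the
affected parent homozygous reference; co-segregation at such sites is
decided entirely by the pools, i.e. by linkage of the marker to the causal
locus in the sampled offspring.  All generators are reproducible:
identical seed and configuration give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cross import CrossDesign, GenotypeClass, Role, SampleSpec
from .junction import AlignedRead, JunctionModel
from .variants import Variant

BASES = np.array(list("ACGT"))

GT_STRING = {
    GenotypeClass.HOM_REF: "0/0",
    GenotypeClass.HET: "0/1",
    GenotypeClass.HOM_ALT: "1/1",
    GenotypeClass.MISSING: "./.",
}


@dataclass
class FamilyConfig:
    family_id: str
    n_affected_pool: int
    n_carrier_pool: int

    def __post_init__(self) -> None:
        if self.n_affected_pool <= 0 or self.n_carrier_pool <= 0:
            raise ValueError("pool sizes must be positive")


@dataclass
class SimConfig:
    """Study-condition defaults: two 20-Mb scaffolds, 60 markers/Mb,
    pools of 10/14 and 18/18 offspring, 0.5 crossovers/Mb/meiosis,
    0.5% genotype miscalls, pools called homozygous below a 10%
    minor-haplotype fraction."""

    scaffold_lengths: dict[str, int] = field(
        default_factory=lambda: {"s1": 20_000_000, "s2": 20_000_000}
    )
    marker_density: float = 60.0  # markers per Mb
    causal: tuple[str, int] = ("s1", 12_000_000)
    families: list[FamilyConfig] = field(
        default_factory=lambda: [
            FamilyConfig("fam1", n_affected_pool=10, n_carrier_pool=14),
            FamilyConfig("fam2", n_affected_pool=18, n_carrier_pool=18),
        ]
    )
    recomb_rate: float = 0.5  # crossovers per Mb per meiosis
    miscall_rate: float = 0.005
    pool_hom_threshold: float = 0.10
    seed: int = 1

    def __post_init__(self) -> None:
        scaf, pos = self.causal
        if scaf not in self.scaffold_lengths:
            raise ValueError(f"causal scaffold {scaf!r} not in scaffold_lengths")
        if not 1 <= pos <= self.scaffold_lengths[scaf]:
            raise ValueError("causal position beyond scaffold")
        if not 0 <= self.miscall_rate < 0.5:
            raise ValueError("miscall_rate must be in [0, 0.5)")


@dataclass
class SimTruth:
    """Ground truth of one simulated cross.

    ``paintings`` maps family -> phenotype class -> array (n_offspring x
    n_markers) of booleans, True where the offspring inherited the
    causal-linked parental haplotype from the carrier parent.
    ``per_family_truth`` is the expected co-segregating set, recomputed
    independently from the paintings under the pool-call model (affected
    pool called homozygous, carrier pool heterozygous); ``fully_linked``
    is the stricter set of markers linked to the causal allele in every
    affected offspring, always a subset of the expected set.
    """

    causal: tuple[str, int]
    marker_keys: list[tuple[str, int, int]]
    paintings: dict[str, dict[str, np.ndarray]]
    per_family_truth: dict[str, set[tuple[str, int, int]]]
    fully_linked: dict[str, set[tuple[str, int, int]]]

    @property
    def expected_coseg(self) -> set[tuple[str, int, int]]:
        sets = list(self.per_family_truth.values())
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return out


@dataclass
class SimResult:
    config: SimConfig
    design: CrossDesign
    variants: list[Variant]
    truth: SimTruth

    def to_vcf(self, path: str | Path) -> None:
        write_vcf(path, self.variants, self.design, self.config.scaffold_lengths)


def _marker_positions(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform marker positions per scaffold; the causal site is a marker."""
    out = {}
    for scaf, length in cfg.scaffold_lengths.items():
        n = int(round(cfg.marker_density * length / 1e6))
        pos = np.sort(rng.integers(1, length + 1, size=n))
        pos = np.unique(pos)
        if scaf == cfg.causal[0]:
            pos = np.unique(np.append(pos, cfg.causal[1]))
        out[scaf] = pos
    return out


def _meiosis_painting(
    positions: np.ndarray,
    length: int,
    recomb_per_mb: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotype painting of one transmitted chromosome at marker positions.

    True where the causal-linked (M) haplotype was transmitted.  Crossover
    count is Poisson in the scaffold length, breakpoint positions uniform;
    the starting haplotype is a fair coin.
    """
    n_xo = rng.poisson(recomb_per_mb * length / 1e6)
    breaks = np.sort(rng.uniform(0, length, size=n_xo))
    start_is_m = rng.random() < 0.5
    parity = np.searchsorted(breaks, positions) % 2
    return (parity == 0) == start_is_m


def simulate_cross(cfg: SimConfig) -> SimResult:
    """Simulate the cross and emit variants, design, and ground truth.

    Offspring are drawn by Mendelian segregation until both pools of each
    family are full; an offspring is affected iff it inherited the
    causal-linked haplotype from the carrier parent at the causal position
    (the affected parent being homozygous).  Pool genotypes follow the
    diploid-caller stand-in: homozygous when the minor-haplotype fraction
    in the pool is below ``pool_hom_threshold``, else heterozygous; every
    emitted genotype is then independently miscalled with
    ``miscall_rate``.
    """
    marker_rng = np.random.default_rng([cfg.seed, 0])
    markers = _marker_positions(cfg, marker_rng)
    scaffolds = list(cfg.scaffold_lengths)
    causal_scaf, causal_pos = cfg.causal
    causal_idx = int(np.searchsorted(markers[causal_scaf], causal_pos))

    marker_keys: list[tuple[str, int, int]] = []
    for scaf in scaffolds:
        marker_keys += [(scaf, int(p), 0) for p in markers[scaf]]

    samples: list[SampleSpec] = []
    paintings: dict[str, dict[str, np.ndarray]] = {}
    per_family_truth: dict[str, set] = {}
    fully_linked: dict[str, set] = {}
    genotype_cols: dict[str, list[GenotypeClass]] = {}

    for fidx, fam in enumerate(cfg.families):
        rng = np.random.default_rng([cfg.seed, fidx + 1])
        affected: list[np.ndarray] = []
        carrier: list[np.ndarray] = []
        guard = 0
        while (
            len(affected) < fam.n_affected_pool or len(carrier) < fam.n_carrier_pool
        ):
            guard += 1
            if guard > 200 * (fam.n_affected_pool + fam.n_carrier_pool):
                raise RuntimeError("offspring sampling failed to fill pools")
            paint = np.concatenate(
                [
                    _meiosis_painting(
                        markers[s], cfg.scaffold_lengths[s], cfg.recomb_rate, rng
                    )
                    for s in scaffolds
                ]
            )
            offset = sum(
                len(markers[s]) for s in scaffolds[: scaffolds.index(causal_scaf)]
            )
            is_affected = bool(paint[offset + causal_idx])
            if is_affected and len(affected) < fam.n_affected_pool:
                affected.append(paint)
            elif not is_affected and len(carrier) < fam.n_carrier_pool:
                carrier.append(paint)
        aff = np.vstack(affected)
        car = np.vstack(carrier)
        paintings[fam.family_id] = {"affected_pool": aff, "carrier_pool": car}

        aff_classes = _pool_classes(aff, cfg.pool_hom_threshold)
        car_classes = _pool_classes(car, cfg.pool_hom_threshold)
        per_family_truth[fam.family_id] = {
            marker_keys[i]
            for i in range(len(marker_keys))
            if aff_classes[i] is GenotypeClass.HOM_REF
            and car_classes[i] is GenotypeClass.HET
        }
        fully_linked[fam.family_id] = {
            marker_keys[i] for i in np.flatnonzero(aff.all(axis=0))
        }

        fam_samples = {
            f"{fam.family_id}_affected_parent": _const_classes(
                GenotypeClass.HOM_REF, len(marker_keys)
            ),
            f"{fam.family_id}_carrier_parent": _const_classes(
                GenotypeClass.HET, len(marker_keys)
            ),
            f"{fam.family_id}_affected_pool": aff_classes,
            f"{fam.family_id}_carrier_pool": car_classes,
        }
        for role, sid in (
            (Role.AFFECTED_PARENT, f"{fam.family_id}_affected_parent"),
            (Role.CARRIER_PARENT, f"{fam.family_id}_carrier_parent"),
            (Role.AFFECTED_POOL, f"{fam.family_id}_affected_pool"),
            (Role.CARRIER_POOL, f"{fam.family_id}_carrier_pool"),
        ):
            samples.append(SampleSpec(sid, fam.family_id, role))
        noise_rng = np.random.default_rng([cfg.seed, fidx + 1, 7])
        for sid, classes in fam_samples.items():
            genotype_cols[sid] = _miscall(classes, cfg.miscall_rate, noise_rng)

    design = CrossDesign(samples=samples)
    allele_rng = np.random.default_rng([cfg.seed, 99])
    ref_idx = allele_rng.integers(0, 4, size=len(marker_keys))
    alt_idx = (ref_idx + 1 + allele_rng.integers(0, 3, size=len(marker_keys))) % 4
    refs, alts = BASES[ref_idx], BASES[alt_idx]

    variants = [
        Variant(
            scaffold=key[0],
            pos=key[1],
            ref_allele=str(refs[i]),
            alt_alleles=[str(alts[i])],
            alt_index=0,
            genotypes={sid: genotype_cols[sid][i] for sid in design.sample_ids},
        )
        for i, key in enumerate(marker_keys)
    ]
    truth = SimTruth(
        causal=cfg.causal,
        marker_keys=marker_keys,
        paintings=paintings,
        per_family_truth=per_family_truth,
        fully_linked=fully_linked,
    )
    return SimResult(config=cfg, design=design, variants=variants, truth=truth)


def _const_classes(cls: GenotypeClass, n: int) -> list[GenotypeClass]:
    return [cls] * n


def _pool_classes(paint: np.ndarray, hom_threshold: float) -> list[GenotypeClass]:
    """Diploid-caller stand-in for a pooled library.

    Pool haplotypes are the carrier-parent transmissions (alt allele on the
    wild-type haplotype) plus one reference haplotype per member from the
    affected parent.  The pool is called homozygous when the minor-allele
    fraction is below ``hom_threshold``, heterozygous otherwise.
    """
    n = paint.shape[0]
    alt_frac = (~paint).sum(axis=0) / (2 * n)  # W haplotypes carry the alt
    out = []
    for f in alt_frac:
        if f < hom_threshold:
            out.append(GenotypeClass.HOM_REF)
        elif f > 1 - hom_threshold:
            out.append(GenotypeClass.HOM_ALT)
        else:
            out.append(GenotypeClass.HET)
    return out


_CONCRETE = [GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT]


def _miscall(
    classes: list[GenotypeClass], rate: float, rng: np.random.Generator
) -> list[GenotypeClass]:
    if rate == 0:
        return list(classes)
    flips = rng.random(len(classes)) < rate
    out = list(classes)
    for i in np.flatnonzero(flips):
        alternatives = [c for c in _CONCRETE if c is not out[i]]
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return out


def write_vcf(
    path: str | Path,
    variants: list[Variant],
    design: CrossDesign,
    scaffold_lengths: dict[str, int],
) -> None:
    """Write a minimal multi-sample VCF v4.3 (plain text, deterministic)."""
    sample_ids = design.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf, length in scaffold_lengths.items():
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for v in variants:
            gts = "\t".join(GT_STRING[v.genotypes[s]] for s in sample_ids)
            fh.write(
                f"{v.scaffold}\t{v.pos}\t.\t{v.ref_allele}\t"
                f"{','.join(v.alt_alleles)}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Junction reads


def simulate_junction_reads(
    junction: JunctionModel,
    ref_length: int = 1500,
    read_length: int = 100,
    n_reads: int = 10_000,
    clip_model: dict | None = None,
    seed: int = 7,
) -> tuple[list[AlignedRead], list[bool]]:
    """Uniform read starts over a junction-bearing reference, plus truth.

    ``clip_model`` is ``{"prob": p, "lengths": [...]}``: with probability
    ``p`` per read end, a soft clip of a length drawn from ``lengths`` is
    applied (shortening the aligned span).  The truth label says whether
    the aligned span covers a junction with at least 10 bases on each side.
    """
    if read_length <= 20:
        raise ValueError("read_length must exceed 20")
    rng = np.random.default_rng(seed)
    clip_prob = (clip_model or {}).get("prob", 0.0)
    clip_lengths = (clip_model or {}).get("lengths", [1])

    reads: list[AlignedRead] = []
    labels: list[bool] = []
    for i in range(n_reads):
        start = int(rng.integers(1, ref_length - read_length + 2))
        left = (
            int(clip_lengths[rng.integers(0, len(clip_lengths))])
            if rng.random() < clip_prob
            else 0
        )
        right = (
            int(clip_lengths[rng.integers(0, len(clip_lengths))])
            if rng.random() < clip_prob
            else 0
        )
        m = read_length - left - right
        if m <= 0:
            continue
        cigar = []
        if left:
            cigar.append(("S", left))
        cigar.append(("M", m))
        if right:
            cigar.append(("S", right))
        aln_start = start + left  # clipped leading bases do not consume reference
        read = AlignedRead(
            read_id=f"read{i:06d}",
            start=aln_start,
            cigar=tuple(cigar),
            read_length=read_length,
        )
        aln_end = read.ref_span[1]
        label = any(
            (j - aln_start + 1) >= 10 and (aln_end - j) >= 10
            for j in (junction.upstream_junction, junction.downstream_junction)
        )
        reads.append(read)
        labels.append(label)
    return reads, labels


def write_sam(
    path: str | Path,
    reads: list[AlignedRead],
    reference_id: str,
    ref_length: int,
) -> None:
    """Write reads as a plain-text SAM with a minimal @HD/@SQ header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{reference_id}\tLN:{ref_length}\n")
        for r in reads:
            cigar = "".join(f"{n}{op}" for op, n in r.cigar)
            # POS is the 1-based leftmost *aligned* base
            fh.write(
                f"{r.read_id}\t0\t{reference_id}\t{r.start}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
            )


# ---------------------------------------------------------------------------
# Planted retroelement copies


def plant_element_copies(
    genome_len: int,
    element_seq: str,
    n_copies: int,
    divergence: float = 0.0,
    truncate_list: list[int | None] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[dict]]:
    """Random genome with diverged element copies planted at random strands.

    Copies are substitution-diverged at the given per-base rate (no indels)
    and optionally truncated (``truncate_list[i]`` keeps the first N bases
    of copy i).  Returns the genome and the truth loci
    (0-based half-open coordinates, strand, realized divergence).
    """
    element = element_seq.upper()
    if genome_len <= n_copies * len(element):
        raise ValueError("genome too short for the requested copies")
    rng = np.random.default_rng(seed)
    background = "".join(BASES[rng.integers(0, 4, size=genome_len)])

    truncs = list(truncate_list or [None] * n_copies)
    if len(truncs) != n_copies:
        raise ValueError("truncate_list length must equal n_copies")

    # choose non-overlapping insertion points
    placements: list[tuple[int, int]] = []  # (background offset, copy index)
    occupied: list[tuple[int, int]] = []
    attempts = 0
    for i in range(n_copies):
        size = truncs[i] or len(element)
        while True:
            attempts += 1
            if attempts > 1000 * max(n_copies, 1):
                raise RuntimeError("could not place copies without overlap")
            pos = int(rng.integers(0, genome_len - size))
            if all(pos + size <= s or pos >= e for s, e in occupied):
                occupied.append((pos, pos + size))
                placements.append((pos, i))
                break
    placements.sort()

    truth: list[dict] = []
    parts: list[str] = []
    cursor = 0
    out_pos = 0
    for pos, i in placements:
        parts.append(background[cursor:pos])
        out_pos += pos - cursor
        cursor = pos
        size = truncs[i] or len(element)
        copy = element[:size]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            copy = _revcomp(copy)
        copy, n_sub = _diverge(copy, divergence, rng)
        parts.append(copy)
        truth.append(
            {
                "copy": i,
                "start": out_pos,
                "end": out_pos + size,
                "strand": strand,
                "truncated_to": truncs[i],
                "n_substitutions": n_sub,
            }
        )
        out_pos += size
    parts.append(background[cursor:])
    genome = {"chr1": "".join(parts)}
    truth.sort(key=lambda d: d["copy"])
    return genome, truth


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr), len(hit)


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    """60-column FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")
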