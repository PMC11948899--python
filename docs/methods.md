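# Methods

## Co-segregation filter

A cross design assigns each sequenced library a family and a role
(`affected_parent`, `carrier_parent`, `affected_pool`, `carrier_pool`).
Pools are genotyped as single diploid samples, the same way a variant
caller treats any library. For a fully recessive allele, a variant
co-segregates in a family when every affected-role sample carries the
orientation-expected homozygous class and every carrier-role sample is
heterozygous. The `orientation` switch handles the case where the
reference assembly was built from an individual heterozygous for the
mutant allele, which makes affected samples homozygous *reference* (0/0)
at diagnostic sites; the default assumes this, and the alternative maps
affected samples to 1/1.

Multi-allelic records are split per alternate allele. A genotype carrying
any non-reference allele other than the split alt (e.g. `1/2` when
splitting alt 1) is classed heterozygous for that split: it is not the
homozygous diagnostic class, and discarding the site entirely would lose
information. Phased separators are reduced to unphased classes. Missing
genotypes fail the variant under the default `missing_policy=fail_variant`
(conservative for low-coverage libraries, which otherwise inflate
secondary peaks); `ignore_sample` skips missing samples instead. Variants
are not pre-filtered on the VCF FILTER column unless `pass_only` is set,
since callers differ in how they populate it.

The combined verdict is the conjunction over families, so adding a family
(or a sample) can only shrink the combined set — a monotonicity property
the tests assert on every simulated run.

Repeat masking consumes BED3 (0-based half-open) and flags a variant when
its 1-based position falls inside any interval; masked variants never
enter the filter.

## Window scan and interval call

Windows are anchored at scaffold coordinate 0, default 1 Mb wide with a
100-kb step; terminal partial windows are kept and flagged so tiling is
reproducible without per-scaffold offsets. The numerator of each window is
the count of combined co-segregating variants; the denominator is every
unmasked variant in the window (`all_variants`, default) or only variants
co-segregating in the parental libraries (`parental_coseg`) — both
denominators are implemented because either reading is defensible, and
outputs record which was used. Windows with an empty denominator are
reported as proportion 0 with `defined=false`.

The candidate interval is called by selecting windows with proportion at
least `threshold_fraction` (default 0.9) of the global maximum, merging
overlapping/adjacent selections per scaffold, and returning the merged run
containing the peak window. The 0.9 default recovers a contiguous peak
robustly on simulations; there is no significance model, deliberately —
the statistic is a descriptive proportion. Interval density is reported as
co-segregating variants per Mb, rounded half away from zero. Runs of
assembly gaps are not subtracted from interval length; gap-aware lengths
belong to assembly-specific post-processing.

## Recombinant refinement

Each Sanger-genotyped individual contributes an expectation per site
(homozygous for affected, heterozygous for carrier). An individual with at
least one inconsistent site is a recombinant; its consistent segment is
the maximal run of consistent sites, bounded exclusively by the nearest
inconsistent site on each side. The refined interval is the original
intersected with every segment — order-independent and never larger. An
empty intersection raises an error naming the conflicting individuals,
because it indicates a phenotyping/genotyping error or a wrong interval
rather than a narrower locus.

## Junction-spanning reads

Against a junction-bearing reference (host sequence with the insert
added), a read is accepted for a junction boundary J when its alignment
start lies in [J − 80, J − 10], every soft- or hard-clipped end is
strictly shorter than 5 bp, and the aligned span crosses J. The start
window guarantees roughly ten aligned bases on each side for ~100-bp
reads; the clip rule rejects chimeric partial mappings. Hard clips are
treated like soft clips — leniency there would re-admit the very
alignments the rule exists to exclude. Each read is assigned to at most
one junction (upstream checked first); under the default window the two
junctions' windows cannot overlap for inserts longer than 90 bp. The rule
is intentionally literal: the simulator also emits per-read truth labels
under the plain "≥ 10 aligned bases on each side" definition, and the test
suite compares the two read-by-read, so the (small, edge-window)
difference between the literal rule and the overlap definition is
reported, not hidden.

## Insertion consequence

The mutant CDS is the wild-type CDS with the insert spliced in after a
given position; translation is frame 1 with the standard nuclear codon
table, stopping at the first stop codon. `novel_aa_after_junction` counts
residues past the last complete wild-type codon before the insertion that
do not simply resume the wild-type carboxy terminus (computed by longest
common suffix), so a truncating insert reports exactly the residues
introduced before the premature stop, and an in-frame stop-free insert
reports its own encoded residues. An insert that removes the stop entirely
is flagged `stop_loss`, not truncated. No selenocysteine handling.

## Element copy scan

Copies of a query element are found by seed-and-extend: exact 31-mer
probes taken every 50 bp of the query (each strand) are located in the
genome, probe hits voting for the same implied element start (within
200 bp) are chained, and chains with at least two hits (two-hit rule) are
aligned with a banded gapped aligner over the candidate region plus
300-bp flanks. A hit is a copy when the alignment covers at least
`min_match_len` columns (default 5000) at `min_identity` (default 0.95),
identity being matches over all alignment columns so gaps count against
it. Overlapping hits on a scaffold collapse to the single best copy.
31-mer probes at 5% divergence survive with probability ≈ 0.2 each, so a
full-length copy at the identity threshold still yields tens of clean
probes; at the tested 2% divergence recall on full-length planted copies
is total, and a 31-bp exact match in random sequence is expected ≈ 10⁻¹⁰
times per position, which keeps element-free genomes hit-free (verified
across 20 seeded genomes). This is a threshold-faithful scan, not a
re-implementation of any particular aligner's scoring.

## Synthetic data

`simulate_cross` emulates the mapping study design: two families sharing a
carrier father, affected mothers, pooled offspring of 10/14 and 18/18
(affected/carrier), two 20-Mb scaffolds, 60 markers/Mb, causal locus at
s1:12 Mb, 0.5 crossovers/Mb/meiosis (Poisson, no interference), 0.5%
genotype miscalls. Markers model the informative subset the filter
operates on: the carrier parent heterozygous with the mutant-linked
haplotype carrying the reference allele, the affected parent homozygous
reference — so co-segregation at a marker is decided purely by linkage to
the causal locus among the sampled offspring, which is the signal the
method exploits. The causal site itself is included as a marker, as it
would be in a real callset. Pool genotypes use a stand-in for a diploid
caller applied to a pooled library: homozygous when the minor-haplotype
fraction in the pool is below 0.10, heterozygous otherwise. The ground
truth (`SimTruth`) stores per-offspring haplotype paintings, and the
expected co-segregating set is recomputed independently from those
paintings under the same pool-call model; the strictly fully-linked set is
stored separately and is provably a subset.

What the simulator does **not** model: read-level sequencing error and
coverage variation, reference bias, linkage disequilibrium structure in
the parental backgrounds, indel markers, and real repeat content. Passing
recovery tests therefore demonstrate correctness of the filtering/scanning
machinery under the assumed genetic model, not robustness to artifacts of
real short-read data.

Per-family random streams are derived from the master seed, so removing a
family leaves the other families' data unchanged — that is what makes the
"adding a family never grows the combined set" check meaningful across
separate simulations.

`simulate_junction_reads` draws uniform read starts over a 1.5-kb
junction-bearing reference with optional soft clips; truth labels use the
coverage definition above. `plant_element_copies` inserts
substitution-diverged (optionally truncated, random-strand) element copies
at non-overlapping positions in uniform random background; substitutions
only by default, so identity accounting for truth labels is exact.

## Fixture sequences

The packaged worked-example sequences are synthetic stand-ins generated
deterministically in code (`fixtures.py`), engineered to the documented
anatomy: a 2643-bp CDS (880-aa protein); a 397-bp insert after CDS
position 605 whose frame introduces four novel residues then a premature
stop, truncating translation to 205 aa; a 5832-bp element carrying the
three fragments that splice into the insert; and a paired element copy
differing by exactly one substitution. The test suite and acceptance
script recompute all of those numbers by translation and alignment — the
fixtures pin the anatomy, never the answers.

## Problem sizes and numerical choices

The acceptance computations use 100 simulated crosses (seeds derived from
the CLI seed), 10,000 simulated junction reads, 200-kb planted-element
genomes, and 20 element-free genomes — sizes at which every measured rate
is stable while the whole script completes in well under a minute on one
CPU. Mapping resolution at the default marker density is
recombination-limited (~28 informative meioses give a fully linked region
of a few hundred kb) and the called interval is additionally floored by
the 1-Mb window, so the density-doubling resolution trend is measured at
sparse densities (1–4 markers/Mb), where marker spacing dominates and the
trend is a genuine property of the method. Ties in window proportions
resolve to the first (leftmost) peak; interval boundaries are half-open
`[start, end)`; densities round half away from zero.

## Known limitations

* The per-junction read rule does not require evidence at both junctions
  of the same insert; requiring both is a caller-level policy choice.
* The pool genotype model is a stand-in for how a diploid caller behaves
  on pooled libraries, not a coverage-aware likelihood model.
* The element scan reports collapsed, non-overlapping copies; tandem
  copies closer than the chaining slack may merge.
* `parental_coseg` denominators equal `all_variants` on simulator output
  (every simulated marker passes the parental checks); distinguishing the
  two requires data with parent-discordant sites.
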