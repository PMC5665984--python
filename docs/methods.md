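# Methods

## The mapping design

All inference rests on one property of the doubled-haploid (DH) design:
every offspring is the doubled genome of a single gamete from one XY
father, hence fully homozygous, and its genotype at any locus reveals
which grandparental haplotype that gamete carried. The two DH
grandparents of the father are sequenced alongside the panel so that the
two segregating alleles are identifiable at every informative site:
sites where the grandparents are opposite homozygotes are phased (A =
grandmother's allele, B = grandfather's), all other sites are dropped.
The Y chromosome rides on the grandfather's haplotype, so a gamete
carrying haplotype B across the sex-determination region becomes a YY
supermale after doubling, and one carrying haplotype A becomes an XX
female.

Observed heterozygous calls in DH progeny are therefore genotyping
error, which is why the SNP filters bound the heterozygous-call count
(> 4 of 77 samples removed — the XY father is genuinely heterozygous at
every informative site and accounts for one call).

## SNP filtering

`variant_qc.filter_snps` applies eight rules with strict inequalities at
the stated values: average population depth < 1; indel; > 2 alleles;
non-reference reads < 5 across the panel (het-call depth is apportioned
half to each allele); site quality score < 900; > 4 heterozygous calls;
combined depth < 120 or > 500. Records at the boundary (depth exactly
120 or 500, quality 900, 4 het calls) are retained. The tally attributes
each removed record to every rule it violates and separately reports the
unique removed count, since a site often fails several rules at once.
The quality score is treated as a site-level value (the VCF QUAL field);
per-sample GQ aggregation would need information the call format does
not carry here.

## Consensus, binning, grouping, ordering

*Consensus* (`call_consensus`): per contig and individual, the majority
genotype class among non-missing SNP calls must exceed a 0.90 share
(strictly); 9 of 10 is not enough, 19 of 19 with one missing is. A
heterozygous consensus cannot be phased and reports missing.

*Binning* (`cluster_patterns`): contigs are visited in sorted-id order;
a contig joins the existing bin with the largest informative overlap
among bins it matches with zero mismatches at mutually informative
positions and overlap ≥ `min_overlap` (default 20 individuals),
otherwise it founds a new bin. Bin patterns are per-position majorities
over members (ties report missing). On conflict-free inputs this greedy
procedure equals the all-pairs compatibility closure, which the test
suite checks by brute force on instances of ≤ 50 contigs.

*Grouping* (`group_linkage`): single-linkage clustering joins bins when
their recombination fraction — the mismatch share over mutually
informative progeny, well-defined because phases are absolute — is
below 0.25. Bins with no measurable rf against any other bin are left
unplaced unless they are themselves informative enough (≥ `min_overlap`
non-missing cells) to stand as singleton groups. Groups are reported
largest first.

*Ordering* (`order_bins`): the published map was curated by hand, so the
ordering algorithm here is the package's own choice: a greedy
nearest-neighbour chain seeded at the minimum-rf pair, refined by 2-opt
segment reversal until the total adjacent rf stops decreasing (the
objective never increases), oriented with the lowest-id bin first. Map
positions are cumulative Haldane distances, d = −50 ln(1 − 2r) cM, with
r capped at 0.49; undefined adjacent rf is costed at 0.5.

*Iterative construction* (`build_map_iterative`): pass 1 builds a
preliminary map from contigs with > 100 informative SNPs (falling back
to all contigs with a warning when none qualify). Every contig's SNPs
are then assigned to preliminary loci by best pattern match (mismatch
fraction ≤ 0.2, overlap ≥ `min_overlap`), and the chimera rule cuts a
contig between two adjacent runs of ≥ 5 consecutive assigned SNPs at
loci strictly > 5 cM apart or on different groups; unassigned SNPs do
not break runs, and the ≥ 5-SNP requirement applies to both sides of the
cut. The final map re-clusters all (split) contigs in one pass, which is
equivalent to progressively adding the smaller contigs by compatibility
given the deterministic greedy binning.

With 74 progeny, the rf between truly unlinked bins is distributed
Binomial(74, ½)/74, whose lower tail crosses the 0.25 grouping threshold
with probability ~6 × 10⁻⁶ per pair; across the hundreds of bins of a
whole-genome map, a chance merge of two chromosomes therefore occurs in
a small fraction of panels. This is a property of the design's panel
size, not of the implementation, and the recovery tests assert 10 groups
in ≥ 95% of seeded replicates rather than in all of them.

## Depth of coverage as a segregating trait

Hemizygous (Y-specific) sequence has no X counterpart, carries no
heterozygous SNPs in the father, and cannot be SNP-mapped; but its
per-individual coverage segregates. `normalize_depth` scales each
individual by its median contig depth — the median over all contigs
stands in for the autosomal baseline because the hemizygous fraction of
the genome is small — making the profile invariant to sequencing-effort
differences. `call_presence` maps normalized depth to a tri-state call:
< 0.2 absent, > 0.6 present, otherwise ambiguous. The thresholds are the
package's own: at ×3.5, an absent contig's normalized depth is ~0 and a
present one's ~1, and the band between the thresholds absorbs the
Poisson noise of averaging ~20 sites; both are configurable.

`map_depth_segregating` places a presence pattern on the SNP map exactly
as pattern clustering would (zero mismatches at mutually informative
positions, both polarities tried); a pattern constant across informative
progeny is reported uninformative. `find_sex_linked` returns the
elements whose pattern contradicts neither sex polarity in at most
`max_mismatch` individuals (default 0 — perfect cosegregation), and
`delimit_region` reports the union bp span of the anchored sex-linked
contigs, listing unanchored ones separately. Gene-level hemizygosity is
called from the median normalized depth across XX females (< 0.2 →
hemizygous). Coordinates are BED-convention (0-based, half-open)
internally and 1-based in human-readable reports.

## Mutant classification

Coverage ratios divide a mutant's normalized per-gene depth by an
unmutated XY control's. In an XY background a hemizygous gene has one
copy against a diploid baseline (normalized ~0.5 in both mutant and
control), so the ratio is ~1 when the gene is retained and ~0 when
deleted; the deletion cutoff is ratio ≤ 0.1 (the observed coverage over
deleted regions is essentially zero; the cutoff is configurable). The
phenotype prediction encodes the two-gene model as a lookup: everything
deleted → female; exactly the female suppressor (*SOFF*) deleted →
hermaphrodite; nothing deleted → male; any other subset is reported as a
deletion call with phenotype hermaphrodite only when *SOFF* is lost and
*aspTDF1* retained, else undetermined — no claim is made about
combinations the model does not cover.

`detect_frameshift` compares an observed CDS against its codon-complete
reference by global alignment at unit edit costs (Biopython's
`PairwiseAligner`), then left-shifts each indel maximally so placement
is deterministic and leftmost. The net frame offset is the summed indel
length mod 3; the observed sequence is translated from its start with
the standard genetic code and a first stop strictly before the
reference's terminal codon is reported as premature, with the truncated
protein length.

## The synthetic-data generator

`simulate_panel` emulates the study conditions: 74 DH progeny (35 XX, 39
YY) plus the XY father and two DH grandparents — 77 sequenced samples —
on ten 100-cM chromosomes with 30 contigs of 20 SNPs each, ×3.5 mean
depth for the panel and ×10 for mutants, 1% genotyping error, 5%
missingness. Where the design leaves a choice, the generator uses the
simplest standard model, fixed once:

- **Meiosis**: crossover count per gamete ~ Poisson(map length/100 cM),
  uniform placement, no interference; breakpoints inside the Y region
  are redrawn, enforcing suppressed recombination. The sex counts are
  exact by construction: the gamete's haplotype origin is anchored at
  the Y region to the assigned sex and propagated outward through the
  breakpoints.
- **Depth**: per-individual mean depth is lognormal around the target
  (σ = 0.15, emulating library-size variation); per-site depth is
  Poisson at that mean scaled by copy number/2; contig- and gene-level
  depth is the mean over their sites. Hemizygous contigs have copy 2 in
  YY, 1 in XY, 0 in XX (plus an optional contamination rate, default 0).
- **Genotype observation**: zero-depth or randomly dropped calls are
  missing; miscalls go half to a heterozygous call and half to the
  opposite homozygote. Site quality scores are drawn high (mean 1500)
  with a small low-quality fraction so the quality filter is exercised.
- **Region content**: 13 genes, 12 hemizygous and 1 shared, including
  *SOFF* and *aspTDF1*; CDS sequences are random non-stop codons between
  ATG and TAA, by default 300 nt.

The generator does **not** emulate read-level artifacts (mapping bias,
base quality, paralogy), linked-site error correlation, segregation
distortion, or structural variation beyond the planted hemizygous
region and mutant deletions. Passing recovery tests therefore show the
algorithms are correct under the design's statistical assumptions, not
that real resequencing data meets those assumptions. The planted region
spans 10 cM of a 100-cM chromosome so that several contigs fall inside
it at desk scale; its bp fraction of the chromosome is correspondingly
larger than a real ~1 Mb region on a 132.4 Mb chromosome, and the
region-fraction arithmetic is checked separately at the real numbers.

## Determinism and numerical choices

Everything derives from a single integer seed through one generator per
simulation; ties break to the lowest identifier everywhere (bin joining,
locus assignment, chain extension); iteration orders are fixed by sorted
ids; pipeline reports are JSON with sorted keys, so identical config and
seed give byte-identical outputs. Region fractions are reported at full
precision and truncated (not rounded) to two decimals, matching how such
percentages are printed. Degenerate inputs — empty consensus matrices,
contigs with no informative SNPs, individuals with zero depth, genes
with no female observations — raise typed errors or are excluded with a
warning rather than propagating NaNs.

## Problem sizes

Tests and the acceptance script run the full design (74 progeny, 10
chromosomes, 300 contigs, ~5,900 SNPs) in about a second per replicate;
multi-seed properties use 20 replicates. These sizes are the package's
chosen desk-scale defaults; the algorithms are vectorized (mismatch
counting via signed-pattern matrix products) and scale to considerably
larger panels.

## Known limitations

- Single-linkage grouping can chain two chromosomes through one chance
  low-rf bin pair (see above); robust alternatives (average linkage,
  LOD-based grouping) are not implemented.
- Bin ordering is a heuristic (greedy + 2-opt) and can return a local
  optimum on noisy groups; orders are only defined up to reversal.
- The chimera scan assigns single SNPs to loci and is conservative on
  noisy data: a lone misassigned SNP interrupts a run and can mask a
  true chimeric join.
- `map_depth_segregating` requires exact pattern compatibility; a
  presence pattern at a locus with no exactly-matching bin (e.g., a
  hemizygous contig recombinationally separated from every SNP contig)
  is reported unplaced rather than force-assigned.
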