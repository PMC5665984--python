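# dhsexmap

Locating a young Y chromosome's non-recombining sex-determination region
from a doubled-haploid (DH) mapping population, and classifying
sex-conversion deletion mutants from read coverage.

Garden asparagus (*Asparagus officinalis*) is dioecious with homomorphic
X/Y chromosomes: YY "supermales" are viable, so anther culture of a single
XY male yields a panel of fully homozygous DH offspring — XX females and
YY supermales — each reporting one recombinant gamete of the father. This
package implements the computational analysis such a design supports:

1. **SNP filtering** of low-coverage (~×3.5) resequencing calls for the
   74 DH progeny, the XY parent and its two DH grandparents (77 samples):
   sites are removed when average depth across the population < 1, the
   variant is an indel or shows > 2 alleles, non-reference reads < 5, the
   site genotype-quality score < 900, heterozygous calls > 4 of 77, or
   combined read depth < 120 or > 500 (all inequalities strict).
2. **Linkage mapping**: genotypes are phased to grandparent origin,
   collapsed to one consensus call per contig per individual (assigned
   when > 90% of its non-missing SNP calls agree), contigs sharing a
   segregation pattern are merged into recombination bins, bins are
   grouped by single-linkage clustering on the two-point recombination
   fraction *r* (join when *r* < 0.25), ordered by a greedy chain with
   2-opt refinement, and spaced with Haldane distances
   *d* = −50 ln(1 − 2*r*) cM. Chimeric contigs — runs of ≥ 5 consecutive
   SNPs mapping to loci > 5 cM apart — are detected against a preliminary
   map built from SNP-rich (> 100 SNP) contigs and split.
3. **Depth-of-coverage as a segregating trait**: Y-specific (hemizygous)
   sequence carries no SNPs but segregates for presence/absence of
   coverage. Normalized depth below 0.2 of an individual's median calls
   absence, above 0.6 presence. Contigs whose presence pattern
   cosegregates perfectly with sex delimit the non-recombining region,
   and genes with ~zero median female depth are classified hemizygous.
4. **Mutant classification**: gamma-irradiated XY plants resequenced at
   ~×10 are compared against an XY control by per-gene coverage ratio.
   All region genes at ratio ≤ 0.1 → full-region deletion (male→female
   conversion); only the female suppressor *SOFF* lost with the
   male-promoting *aspTDF1* retained → single-gene deletion
   (male→hermaphrodite). A CDS comparison detects frameshift point
   mutants: a 1-bp deletion shifts the reading frame and introduces a
   premature stop codon.

A synthetic-data generator (`dhsexmap.simulate`) reproduces the design's
statistical structure — Poisson crossovers with recombination suppressed
inside the planted Y region, per-site Poisson depth, symmetric genotyping
error and missingness — so every stage is testable without sequencing
data.

## Worked example

```sh
dhsexmap run --seed 11 --out-dir demo/
```

prints

```
map: 259 bins in 10 linkage groups; 4 sex-linked contigs
```

and writes `demo/report.json`, from which:

- `filter`: 5,920 simulated SNPs in, 5,881 retained — the filters remove
  the small fraction of sites with low quality scores or depth outside
  the window.
- `map`: 296 phased contigs collapse into 259 distinct recombination
  patterns assembled into exactly 10 linkage groups, matching the 10
  simulated chromosomes.
- `sexregion`: the 4 contigs whose presence/absence pattern cosegregates
  perfectly with sex are exactly the planted hemizygous contigs on
  chromosome 1; of the 13 region genes, 12 are classified hemizygous and
  1 shared, as configured.
- `classify`: three independent full-region deletion mutants are all
  called `full_region_deletion` (predicted female) and the *SOFF*-only
  deletion is called `single_gene_deletion` (predicted hermaphrodite);
  the 1-bp deletion at CDS position 30 of *SOFF* gives frame offset 2
  and a premature stop at codon 22, truncating the 99-aa protein to 21
  residues.

The same stages are available individually (`dhsexmap simulate | filter |
map | sexregion | classify-mutant | frameshift`) and as library functions
(`simulate_panel`, `filter_snps`, `build_map_iterative`,
`find_sex_linked`, `classify_mutant`, `detect_frameshift`, ...).

The packaged table of the 13 non-recombining-region genes (7 anchored to
the optical map, 6 not) loads with `dhsexmap.load_gene_table()`.

## Documentation

`docs/methods.md` describes the model, the defaults and their rationale,
what the simulator does and does not emulate, and known limitations.
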