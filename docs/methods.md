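# Methods

`bsamap` reimplements, on synthetic data, the computational chain of a
bulked-segregant fine-mapping study of a single dominant locus — here the
fuzzless seed trait of a diploid cotton mutant: segregation testing,
pooled genome scans, recombinant-marker narrowing, differential-expression
filtering and variant-consequence evidence. This note records the models,
the defaults and the reasoning behind the genuinely open design choices.

## Genetic model and simulator

Individuals are assembled from parental gametes. Each F1 gamete receives a
Poisson number of crossovers with expectation `chrom_length × cm_per_mb /
100` (Haldane model: no interference, uniform breakpoint placement); an F2
individual is two F1 gametes, a BC1 individual one F1 gamete plus one
recurrent-parent gamete. The phenotype follows from the mutant-allele
dosage at the causal position; the mutant (fuzzless) allele is dominant by
default. Phenotype pools are random draws within each phenotype class —
for a binary trait there is no "extremeness" beyond class membership.

Sequencing is modelled at the allele-frequency level: at each site the
pool's mutant-allele frequency f is the mean dosage of pooled individuals
over two, the observed frequency is `f(1−e) + (1−f)e` for per-read error
e, the total depth is Poisson with the configured mean, and alt reads are
binomial. Parents are fixed opposite homozygotes at every emitted site
(informative-site model); sites sit on a regular grid with the causal
position always included.

A key consequence of dominance with phenotype-selected F2 pools: the
fuzzy pool is homozygous wild at the causal site (frequency 0) while the
fuzzless class mixes heterozygotes and mutant homozygotes 2:1 (frequency
2/3). The ΔSNP-index therefore peaks at 2/3, not 1, and the scan must
detect peaks of that height.

### Map density: the chromosome is a compressed genome

More generally, at map distance m Morgans from the causal site the
expected ΔSNP-index of dominant F2 phenotype pools has the closed form

    E[ΔSNP](m) = (2/3) · e^(−2m)        (Haldane recombination fraction
                                         r = (1 − e^(−2m)) / 2)

so the signal decays over a *genetic* length of half a Morgan. A real
scan spans a whole genome (order 1,500 cM for the cotton A genome), in
which almost every site is unlinked to the locus and the background of
the statistic is flat near zero — the regime the `median + 3·SD`
threshold rule assumes. A 10 Mb simulated sequence at a physical cotton
rate of ~1 cM/Mb would span only 10 cM: every site would sit within
r ≤ 0.1 of the locus, the ΔSNP-index would exceed 0.55 everywhere, and
the threshold would land above the global maximum, calling nothing.
The simulated chromosome is therefore a genome stand-in: its default map
density is `cm_per_mb = 150`, making the 10 Mb sequence span 1,500 cM.
With that choice the signal decay length is 50/150 ≈ 0.33 Mb, the
background is flat, and the threshold rule behaves as it does on real
genome scans (thresholds around 0.4–0.5, comfortably below the 2/3
ceiling). Physical-scale questions (recombinant narrowing inside a
candidate region) use a physical map density instead; see below.

### Defaults

| parameter | default | why |
|---|---|---|
| `n_individuals` | 4,010 (F2) | the mapping population size of the study design |
| `pool_size` | 30 + 30 | the study's bulk sizes |
| `chrom_length` / `n_sites` | 10 Mb / 5,000 | a tractable genome stand-in at ~2 kb marker spacing |
| `mean_depth` | 50× | pooled re-sequencing depth scale |
| `seq_error` | 0.001 | Illumina-scale per-read error |
| `cm_per_mb` | 150 | genome compression, derivation above |
| `indel_fraction` | 0.13 | the observed SNP:InDel ratio (~354k : ~51k) |

## Genome scan

Per informative site (parents consistent opposite homozygotes at alt
fraction ≥ 0.9 / ≤ 0.1 with depth ≥ 10; both pools at depth ≥ 10):

* **SNP-index** — alt fraction of a pool, alt being the mutant-parent
  allele; **ΔSNP-index** — fuzzless minus fuzzy, so the causal peak is
  positive.
* **ED** — Euclidean distance between the pools' allele-frequency
  vectors (4 nucleotides for SNPs, {ref, alt} for InDels), optionally
  raised to a power (`ed_power`, default 1). For a biallelic site
  ED = √2·|Δf| ∈ [0, √2].

Raw tracks are smoothed by a tricube-weighted local mean (degree-0 local
regression) over a base-pair window, truncated at chromosome ends. The
window default is 500 kb: it must sit between the site spacing (2 kb) and
the signal decay length (~0.33 Mb at the default map density); wider
windows flatten the peak toward the threshold, narrower ones let
pool-composition noise through. The threshold is `median + 3 × sample SD
(n−1)` of all fitted values, computed per statistic (and per variant
class when SNPs and InDels are scanned separately); candidate regions are
maximal runs of fitted values at or above the threshold, with runs closer
than `merge_gap` (default 100 kb) bridged, and the final candidate region
is the intersection across statistics. ΔSNP-index regions are called on
signed values by default (`two_sided` exists for unknown parental
orientation). Sites failing depth filters are dropped, not imputed.

Under the defaults the intersected region contains the causal position in
effectively every run (≥ 95% across 200 replicates) at a median width of
~0.35 Mb. The width is *linkage-dominated*: it is set by the decay of the
expected signal and by which individuals entered the 30-member pools, so
it is nearly invariant to read depth (20× → 100×) and to marker density —
read depth only shrinks read-sampling noise, which is already subdominant
at 20×. Tighter regions require larger pools, not deeper sequencing.

## Recombinant narrowing

Markers are point loci; the interval between two markers is
`[min(pos), max(pos)]` with length defined as the position difference
(under which the published SSR82–InDel9 pair spans 70,110 bp ≈ 70 kb, and
the published scan endpoints 76,294–2,305,623 measure 2.23 Mb).

`narrow_by_recombinants` evaluates each *slot* between adjacent markers
as a candidate placement of the causal locus. For a given slot, an
individual's causal genotype is inferred from its nearest non-missing
marker calls on the two sides, assuming at most one crossover between
adjacent markers: agreeing flanks fix the genotype, which must then be
consistent with the phenotype under single-locus dominance; disagreeing
flanks mean the individual recombined within the slot and constrains
nothing there (likewise one-sided information). The surviving slots form
a contiguous run and the markers immediately outside it are the tightest
flanking pair. This slot formulation is robust at any marker density —
a per-marker "zero recombinants" rule would fail as soon as any marker
showed a single recombinant — and the slot containing the true locus can
only be eliminated by genotyping error or a double crossover between its
flanks (adjacent A/B calls, which the function counts and reports as a
warning). If no slot survives, the function raises: the data contradict
a single-locus dominant model.

Narrowing operates at the physical scale of a candidate region, where a
physical map density (~1–2 cM/Mb) is appropriate; the pipeline's refine
stage therefore simulates its backcross population at 2 cM/Mb rather
than the scan stage's compressed-genome density, at which a 70 kb slot
would span ~10 cM and double crossovers would break the ≤ 1-crossover
inference.

Genes are assigned to the interval by *full containment* (start and end
both inside), matching the count of seven ORFs strictly between the
flanking markers. Candidates are ranked in four tiers: differential
expression plus a coding/promoter variant; differential expression only;
variant only; neither — ordered by position within tiers.

## Expression analysis

FPKM is `fragments × 10⁹ / (library_total × gene_length)`. The
differential rule is applied directly to FPKM tables: per gene and stage,
a two-sample t-test on log2(FPKM + pseudo) between genotypes (pseudo = 1
stabilizes ratios at 2 replicates), Benjamini–Hochberg adjustment across
genes within the stage, and significance when FDR < 0.01 **and**
|log2 ratio| ≥ 1, the boundary ratio included. Genes with zero variance
and equal means in both groups are non-significant by definition. A
count-model method (as the original Cuffdiff-based analysis used) is
deliberately not re-implemented, and real-data DEG counts are not
reproduction targets.

Two consequences of the two-replicate design are worth recording. First,
a t-test with df = 2 can only clear an FDR of 0.01 when log-scale noise
is small (high counts, low dispersion) and several genes cross the
step-up line jointly; the filter is honest but low-powered, which is the
statistical reality of two replicates. Second, the simulated gene panel
is a small window on a transcriptome, so `simulate_expression` balances
true DEGs between up- and down-regulation (`frac_up = 0.5`) and can carry
an explicit whole-library total (`library_size`) as the FPKM denominator
— normalizing a small panel by its own column sums lets a handful of
strong DEGs shift every null gene's apparent ratio, an artifact real
25M-fragment libraries do not show at this magnitude.

The negative-binomial simulator draws gene means from a log-normal,
applies the genotype effect at designated stages (default: the earliest
stage only, mirroring a trait whose expression differences precede the
visible phenotype), and returns truth labels for recovery measurement.
qPCR quantification implements 2^−ΔΔCt against a reference gene and
calibrator sample; Venn partitioning counts all membership regions of up
to four per-stage DEG sets.

## Variant consequences

A coding insertion is a frameshift iff its length is not a multiple of
three; codon-boundary in-frame insertions are translated with the
standard nuclear code to name the inserted residues (the motivating case:
a TTG insertion adding a leucine), and in-frame insertions creating a
premature stop are flagged nonsense. Mid-codon insertions of length 3k
are reported in-frame with a composite codon-replacement description. The
promoter window is the 2,000 bp upstream of the annotated gene start
(strand-mirrored); the window is configurable because "promoter region"
has no canonical extent. `diff_sequences` converts a global alignment
(match +1, mismatch −1, gap open −2, gap extend −1) into simple
substitution/insertion/deletion records whose application reconstructs
the second sequence exactly.

## Scope and limitations

* No read-level simulation (FASTQ), mapping bias or variant-calling
  error model; depths are drawn directly at the site level, so the
  informative-site filter sees cleaner data than a real caller would
  emit.
* One chromosome stands in for a genome; multi-chromosome joint
  thresholds reduce to the per-statistic pooled rule.
* The t-test/BH stage is a stated-filter replacement, not a count model;
  its power at two replicates is intentionally left as it is.
* Phenotyping is error-free; `narrow_by_recombinants` reports
  single-crossover violations but does not model misphenotyped
  individuals.
* Linkage-map construction (cM estimation, marker ordering) and
  gene-function claims are out of scope.
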