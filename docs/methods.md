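# Methods

## The mapping statistic

For a SNP with per-bulk read counts over the four nucleotides, each bulk's
composition is the vector of read frequencies (A, C, G, T), and

ED_SNP = ‖f_mut − f_wt‖₂,  0 ≤ ED_SNP ≤ √2.

ED is computed from read-depth frequencies, not genotype calls: the
statistic is defined on nucleotide frequencies and pooled sequencing has no
per-individual genotypes to call. Before the scan, SNPs are filtered to
coverage ≥ 3 in **both** bulks and pooled non-reference read frequency
≥ 0.05 (both thresholds configurable; a per-bulk frequency mode exists for
stricter use). The frequency filter is pooled by default because only a
single "minimum variant frequency" is meaningful for a pair of pools
derived from the same cross.

Windows contain a fixed number of consecutive SNPs (default 100) rather
than a fixed number of base pairs, so marker-dense and marker-sparse
regions carry equal statistical weight. ED is the **sum** of the window's
ED_SNP values and ED⁴ its fourth power. The window slides one SNP at a time
by default (`step` configurable): sliding maximises positional resolution
and produces the dense per-chromosome scatter users expect from this
method. A window is anchored at its median SNP's position (lower median for
even window sizes); interval bounds use the first/last member SNP.

Windows with ED⁴ strictly above the threshold (default 4.0, a plain
configurable constant — no permutation or quantile rule is implied) are
merged per chromosome whenever their spans overlap or lie within
`merge_gap_bp` (default 1 Mb, generous because a true single-locus signal
spans tens of Mb of linked windows). Each merged interval reports its span,
peak ED⁴ and member-window count; output ordering is (chromosome, start),
and peak ranking breaks ties leftmost.

A note on the threshold's scale: with bulks of 30 plants at ~20× depth,
binomial sampling alone gives background ED_SNP ≈ 0.2, so a 100-SNP window
sum sits around 20 and background ED⁴ around 10⁵. A cutoff of 4.0 on the
sum-then-power statistic therefore selects nearly every window, and
interval calling degenerates toward per-chromosome spans; what separates
the causal region is the *magnitude* of ED⁴ (the causal peak is ~400× the
background median). The package keeps the published sum-and-power
definition and cutoff as defaults and exposes both; users who want sparse
intervals should raise the threshold (e.g. to a high quantile of their own
scan) — the top-ranked interval is unaffected either way.

## Segregation analysis

Two-class counts are tested against an expected ratio with the plain
Pearson statistic, E_i = N·r_i/(r₁+r₂), df = 1, critical value
χ²₀.₀₅ = 3.84. No continuity correction is applied by default; Yates is
available behind a flag. For the motivating counts this gives
χ²(165:67 vs 3:1) = 324/174 ≈ 1.8621 and χ²(69:28) = 56.25/72.75 ≈ 0.7732.
Published analyses of these counts sometimes print slightly different χ²
values (2.074 and 0.822) whose exact formula is not recoverable from
Pearson, Yates or likelihood-ratio recomputation; this package reports the
textbook Pearson statistic and leaves the discrepancy documented here. All
variants agree on the inference (both well under 3.84).

The inheritance model is a single biallelic locus, fully recessive and
**sporophyte-determined**: ear phenotype is a function of the genotype of
the plant bearing the ear, never of the kernel. Hence the reciprocal-cross
signature (reversed kernels on an rk1/rk1 mother despite heterozygous F1
kernels) and the 3:1 normal:reversed ratio among selfed-heterozygote
offspring, which the simulator reproduces by independent random union of
parental gametes.

## The synthetic experiment

`simulate_f2_population` models an F2 from two fully informative inbred
parents: parent A carries the reference base and parent B the alternate
base at every marker, with the recessive mutant allele on the parent-B
haplotype. Recombination is Haldane (no interference): crossovers per
gamete and chromosome are Poisson with mean = genetic length in Morgans,
positions uniform on the genetic map, and the physical↔genetic map is
linear within a chromosome. This is the simplest model that makes no
assumption the analysis depends on; interference changes local crossover
spacing but not the allele-frequency gradient the scan detects.

Defaults mirror the target study design: bulks of 30 reversed-ear and 30
normal-ear plants, mean 20× depth per bulk, 2,000 markers per chromosome
across the 10 maize chromosomes, causal locus chr9:106,000,000 (the
midpoint of the region the motivating study mapped). Chromosome physical
lengths approximate the B73 genome; genetic lengths default to a flat
150 cM each (maize consensus ≈ 1500 cM). The F2 population size (default
240) is not part of the published design; it is set so both 30-plant bulks
fill with high probability. Phenotyping is fully penetrant by default, with
a `misassignment_rate` for robustness experiments.

Read sampling: per marker and bulk, depth ~ Poisson(20); each read draws a
true base from the bulk's exact allele frequency and is miscalled to a
uniformly chosen other base with probability `error_rate` (default 10⁻³).
Error reads landing on a third base extend the VCF record's ALT list so
`AD` accounts for every read and files round-trip exactly. Real BSA data
additionally contain partially informative markers, mapping artefacts and
depth overdispersion; passing tests on this generator therefore validate
the statistic and its implementation, not robustness to those artefacts.

The DEG generator assigns distinct gene ids to each region of the
three-stage Venn diagram, making every pairwise and triple intersection
exact by construction; log₂ fold changes are ±Uniform(0.58, 4) (at least
1.5-fold) and adjusted p-values Uniform(0, 0.05). Default region sizes give
stage totals 2918/827/1651 and a triple intersection of 307. The stage-V
total follows the published up+down component counts (804 + 847 = 1651),
which disagree by one with the printed stage total (1652); the component
counts are taken as authoritative. Pairwise-only overlap sizes are not
published and are set to plausible values (150, 300, 100) consistent with
the totals.

## Candidate genes

A gene is paired with an interval when they share at least one base pair,
computed in 0-based half-open space after converting the 1-based inclusive
VCF/GFF3 coordinates; strict containment is available as an option.
Candidacy requires membership in the intersection of all stage DEG sets —
direction of change is not required, matching how the stage sets are
intersected undirected. Gene identity is the gene_id string; no
cross-annotation ID mapping is attempted.

## Numerical and design choices

* Windowing uses a cumulative sum; window sums match brute-force slice sums
  to 1e-9 absolute in tests.
* ED⁴ is monotone in ED, so rankings by either are identical (tested).
* Determinism: every simulation takes one integer seed and uses a single
  `numpy` Generator stream per call; the read sampler derives a child
  stream from (seed, 17) so population and reads are independently
  reproducible. Scan outputs are byte-identical across reruns.
* Degenerate inputs: empty post-filter SNP sets produce empty outputs with
  a warning (not an error); zero-depth bulks are rejected by the ED profile
  with an instruction to filter first; unsorted SNP input is a hard error.
* Problem sizes in the test suite (e.g. 100 replicates of the default
  10-chromosome scan, 10⁴-plant Mendelian checks, 60-replicate ED-decay
  averages) were chosen to hold sampling error well below the tested
  effects while keeping a full run around a minute.

## Known limitations

* Single-locus, fully recessive, fully penetrant trait model only; no
  multi-locus or quantitative extensions.
* The simulator's markers are all fully informative; real crosses yield
  many uninformative or partially informative sites, effectively thinning
  the marker map.
* No SNP-index/Δ(SNP-index) or G′ statistics; only the ED/ED⁴ procedure.
* The significance cutoff is a constant, not a calibrated genome-wide
  error rate (see the threshold note above).
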