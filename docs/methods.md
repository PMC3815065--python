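# Methods

This note records the models implemented in hapclock, the parameters that
matter, the numerical conventions, and the choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates, coding and missing data

All genomic coordinates are 1-based inclusive (lengths are
`end − start + 1`; the C+D dating region is 127,419 nt). Alleles are coded
against the annotated ancestral state: 0 ancestral, 1 derived, −1 missing.
Missing is an explicit third state and is never imputed; each operation
states its policy (classification treats missing as compatible with either
allele, network construction drops chromosomes missing at retained sites
and records the count, modal/difference computations skip missing calls
site-wise). Sites are strictly biallelic; multiallelic records are
rejected. Alleles are taken as written in the annotation — the analysis is
coordinate-local, so no strand/reverse-complement logic exists. A site may
carry an unknown ancestral state (`?`), in which case its 0/1 coding is
arbitrary but fixed and the site is excluded from rooting decisions while
keeping its place in edge labels.

The shipped core-SNP annotation uses synthetic, evenly spaced positions
inside block C: per-SNP coordinates are not part of the published tables
the fixtures mirror. Everything positional about the shipped worked
examples (e.g. crossover interval widths) is therefore illustrative;
analyses of real panels take positions from the user's annotation.

## Block partitioning

Blocks are delimited by maximal runs of recombination-map intervals with
rate above a primary threshold (default 5 cM/Mb). The published source
coordinates imply a boundary nucleotide inside each hotspot but not the
rule that chose it; we place the cut at the run midpoint, rounded down,
and ship the published coordinates as a fixture so downstream results
never depend on this convention. Runs exceeding only a secondary threshold
(default 0.5 cM/Mb) are reported as candidate sub-boundaries and split
blocks only on request, because that situation arose exactly once in the
source analysis (the C/D boundary at ~0.8 cM/Mb).

## Classification

A haplotype definition is the set of sites carrying the derived allele
(the all-ancestral class has the empty set). A chromosome matching exactly
one definition at every non-missing site gets that name; several
compatible definitions yield an explicit ambiguity class (`C6/C7`), never
a frequency-based resolution — resolving such pairs requires external
genotypes, which can be supplied as an auxiliary input upstream. Named
classes take precedence over the residual classes `other-d`/`other-a`,
which split unmatched chromosomes by the key functional site (c11 =
rs1426654; `other-d/other-a` when that site is missing). Every chromosome
receives exactly one label, so counts always conserve. Ambiguity classes
are reported as their own count rows; published tables brace such cells
into adjacent rows, and the shipped count fixture keeps them as explicit
`C2/C3` and `C6/C7` rows instead.

## Network construction

Sites are filtered at a pooled minor-allele frequency threshold (default
1%), identical allele strings collapse into weighted nodes, and components
are joined greedily: repeatedly connect the two components whose closest
node pair has minimal Hamming distance, breaking ties by the
lexicographically smallest sorted pair of allele strings, then by pair
count descending. This is the minimal deterministic reading of a
"nearest-neighbor" rule and reduces to a minimum spanning tree on
tree-like data. The root is the observed all-ancestral string, else the
observed string closest to it (unknown-ancestral sites ignored). Nodes
below the display threshold (default 0.5%) stay in the graph flagged
`displayed=False`. Edges carry the set of differing sites; a site on two
or more edges is reported as a recurrent transition — under infinite sites
on a recombination-free genealogy this set is empty, so non-empty output
flags recombination (or genuine recurrent mutation). No unobserved
(median) nodes are inferred, and alternative resolutions of early-branching
polytomies are left to the user; `shared_derived_counts` scores candidate
splits by the number of sites whose derived allele is carried by exactly
that node set.

## Crossover reconstruction

Only single crossovers are modeled, with zero mismatch tolerance: any
residual difference is treated as a separate mutation event (as with the
A111T mutation arising after the crossover that created C11's precursor).
A child is explained by an ordered parent pair when its alleles follow the
left parent at every informative site (where the parents differ) up to
some point and the right parent after; the breakpoint interval is the
position pair of the two informative sites flanking the switch, which is
the finest localization the data admit. Both orders are tried; the
narrower interval wins. Pure-parent matches are reported as trivial
hypotheses with a degenerate interval at the region edge and rank last in
scans (their minimum one-sided support is zero). The reciprocal product
joins the right parent's left segment to the left parent's right segment
at the same interval. Whether crossover preceded or followed a focal
mutation is not decided algorithmically; frequency comparisons between
candidate intermediates are descriptive output only.

## Clock dating

* **Calibration.** μ = D / (L_aln · 2 · T_div), with D and L_aln counted
  after excluding alignment columns containing a gap or within 4 columns
  of one (misalignment guard), and T_div = 6,000,000 years by default (the
  midpoint of published human–chimpanzee divergence estimates). The
  unrounded rate is carried through all downstream arithmetic.
* **Point estimate.** T̂ = d̄/(μ·L_reg) with d̄ the mean Hamming distance
  to the modal haplotype and L_reg the *full* region length (127,419 nt
  for C+D). Using the full length with the unrounded rate is the only
  combination that reproduces all published per-population dates from
  their own printed inputs, even though calibration divides by the smaller
  aligned length; the acceptance tests verify this arithmetic. Modal ties
  resolve to the ancestral allele (conservative — never inflates derived
  counts); the tie rule is a parameter. The estimator is invariant under
  duplicating chromosomes, which is the point: duplicated lineages bias
  site-counting estimators but not the per-chromosome average.
* **Effective sample size.** Resample carrier identities with replacement
  until one repeats; count the draws before the duplicating draw; take the
  median over 10,000 replicates. The lower median is returned as an
  integer (the sample median of an even replicate count is otherwise a
  half-integer). Carrier identity is the full allele string over the dated
  region, the strictest reading; the identity function is a parameter.
* **Confidence limits.** k = ESS·d̄ is treated as Poisson and bounded by
  the exact Garwood interval via chi-square quantiles, which generalizes
  smoothly to non-integer k; bounds are rescaled by T̂/k. k = 0 yields a
  degenerate (0, ∞) interval with a warning. Published intervals for this
  analysis are not exactly reproducible under any standard Poisson recipe
  we tried, so intervals are validated by empirical coverage on
  simulations (the exact interval is conservative), not by matching
  printed ranges.
* **Undercount correction.** factor = Σᵢ(Aᵢ/Pᵢ)/ΣᵢAᵢ over the variant
  spectrum (Aᵢ sites observed i times) and detection-power curve
  (0 < Pᵢ ≤ 1); it multiplies the point estimate and both bounds. The
  shipped factor for the C11+D4 spectrum at ~5× coverage is 1.58. The
  calculation ignores occurrence-count misassignment and assumes
  genome-wide power applies locally.
* **Spectrum homogeneity.** Substitution-class spectra (carrier variants
  vs. the interspecies alignment) are compared by a standard 2×C
  chi-square homogeneity test with empty classes pooled out; homogeneity
  justifies using one pooled rate across classes.

## Synthetic data

The generators produce panels with exactly the structure the estimators
assume, so every stage is testable without external data. Defaults mirror
the dated sweep's regime: L = 127,419 nt, μ = 8.145×10⁻¹⁰ /site/year, and
T = 8,000 y, putting μ·L·T ≈ 0.83 — the per-chromosome difference scale
observed in the real carrier sample (822/1013). One RNG substream is
spawned per chromosome, so panels are bit-reproducible and adding
chromosomes never perturbs earlier ones.

* **star** — the sweep limit: every chromosome carries K ~ Poisson(μ·L·T)
  private mutations at globally distinct sites. Infinite sites is enforced
  by rejection (and the configuration is refused when expected mutations
  exceed 10% of the region), matching a clock that counts every difference
  as one event rather than modeling back-mutation.
* **tree** — a random genealogy in which every ancestor haplotype remains
  sampled: each new chromosome copies a uniformly chosen existing one and
  adds Poisson private mutations. With all internal haplotypes observed,
  the tree metric is additive and the greedy minimum-distance network
  provably equals the true tree, making this a sharp oracle for network
  recovery; it emulates the empirical situation where ancestral haplotypes
  persist at high frequency alongside their descendants. A genealogy whose
  internal haplotypes are *unobserved* is deliberately not generated: on
  such data a pairwise network need not reproduce the tree, which is a
  limitation of network inference, not of the generator.
* **recombinant** — copies of two parents plus single-crossover products
  at a known breakpoint; ground truth for breakpoint containment.
* **classified** — chromosomes instantiated exactly from a label ×
  population count table over named definitions, with optional missing-data
  injection to create ambiguity classes; the classification round-trip
  oracle.

What passing on synthetic data does not show: robustness to phasing error,
genotyping error, gene conversion, double crossovers, or ascertainment
differences between cohorts — none of which are modeled.

## Problem sizes and seeds

The validation suite uses 200 sweep replicates of 200 chromosomes for
recovery, 1,000 replicates of 50 independent lineages for interval
coverage, 10,000 resampling replicates for the effective sample size
(mirroring the production default), and 8–25 seeded replicates for the
tree and crossover oracles; the analysis drivers use 100/500 replicates
for the same checks. These sizes leave Monte-Carlo error well inside the
asserted tolerances (e.g. the standard error of the recovery mean is
≈0.6% of the truth). All seeds are fixed in the scripts; the acceptance
script derives every stream from its `--seed` argument.

## Known limitations

* Ambiguity classes are counted as separate rows; published tables that
  brace them into named rows differ by those cells.
* The network reports observed haplotypes only; no median-joining or
  ancestral-state reconstruction of unobserved nodes.
* Crossover search is single-breakpoint; gene conversion and double
  crossovers are out of scope.
* The dating pipeline assumes neutrality of post-founder mutations and a
  constant clock; if recent human mutation rates are lower than the
  interspecies calibration implies, true ages are older.
* The undercount correction trusts an externally supplied power curve.
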