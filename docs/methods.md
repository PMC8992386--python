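# Methods

`ilqtl` implements the analysis chain used for agronomic-trait introgression
line (IL) libraries in rice: rule-based donor-segment calling from SSR
genotypes, library characterization, a many-to-one phenotype screen against
the recurrent parent, and a binomial donor-allele enrichment scan that
nominates trait-linked marker loci across multiple donor species. A forward
breeding-scheme simulator supplies libraries with known truth so that every
stage can be validated quantitatively.

## Segment calling and donor proportion

Genotype calls come from codominant SSR markers and take four values:
homozygous recurrent (R), homozygous donor (D), heterozygous (H), missing
(NA). The estimator is the classic weighted graphical-genotype rule:

* an interval between two donor-type markers (DD) is fully introgressed,
  weight 1.0;
* an interval flanked by one donor-type and one recurrent-type marker (DR)
  is counted at weight 0.5, since the true breakpoint lies somewhere inside
  it and 0.5 is its expected donor content for a uniformly placed breakpoint;
* an RR interval contributes nothing.

Donor genome proportion is Σ(weight × interval length) / genome size, and
background recovery is its complement. Three conventions complete the rule,
where the underlying protocol is silent:

* **Chromosome ends.** The interval between a terminal donor marker and the
  chromosome end is treated like DR (weight 0.5): the end behaves as a
  marker of unknown genotype, giving a symmetric treatment of uncertainty on
  both sides of a donor run.
* **Missing markers** are deleted before the rules are applied, so intervals
  are defined by nearest informative neighbours. This is the only reading
  under which the interval rules remain well defined.
* **Heterozygous calls** are donor-carrying by default (`het="donor"`): an
  H–D or H–H interval has weight 1.0 and an H adjacent to R forms a 0.5
  flank. ILs are advanced by selfing, so H is rare, and an H interval does
  physically carry donor chromatin. `het="ignore"` treats H as missing.

A consequence of `het="donor"` worth knowing: true donor *dosage* of a
heterozygous interval is 0.5, so the estimate exceeds the truth by half the
residual heterozygous fraction. At BC₂F₂ (het ≈ 6% of the genome) this is
about +0.03; it halves with every further selfing generation and is below
+0.01 from F₄ on. The dense-marker recovery experiment therefore uses F₄
lines, matching the practice of genotyping lines that have been selfed to
stability; the bias is a property of the published weighting rule, not of
this implementation.

"Number of segments" counts one merged segment per contiguous donor run
with its flanks folded in; the flat per-piece table (weights included) is
also written, so either convention can be recomputed. Coverage of a
chromosome is the length of the union of all segments of any positive
weight across the library, divided by chromosome length. Percentages are
rounded half-up to two decimals only in reports; internal values keep full
precision. 1 Mb = 1,000,000 bp exactly.

Marker polymorphism summaries support two means because published summary
rows mix them: *weighted* (total polymorphic / total markers) and *simple*
(arithmetic mean of per-chromosome rates). Both are always reported rather
than guessing one intent.

## Phenotype screen (Dunnett)

Lines are compared with the recurrent parent per trait and per environment
by Dunnett's many-to-one procedure on replicate means, two-sided, with the
classic pooled within-group variance (ν = N − k − 1 degrees of freedom).
The family-wise adjusted p-value for comparison i is
1 − P(max_j |T_j| ≤ |t_i|) under the central equicorrelated multivariate t
with corr(T_i, T_j) = λ_i λ_j, λ_i = √(n_i/(n_i + n₀)). Conditioning on the
shared normal factor and on the pooled-SD χ factor reduces the
k-dimensional probability to a smooth 2-D integral, evaluated with 64-node
Gauss–Hermite × 48-node Gauss–Legendre quadrature; for balanced designs all
λ coincide, the product collapses to a power, and the cost is independent
of k. Accuracy is ~1e-5 against both the closed-form k = 1 reduction and an
independent reference implementation at small k; hundreds of comparison
groups take well under a second.

Screening defaults: α = 1e-4 (a deliberately strict family-wise level for a
library-scale screen), environments analyzed separately. A line enters the
QTL scan if significant in at least one environment, with its direction
(increase/decrease) taken from the significant environment(s); lines
significant in opposite directions in different environments are excluded
from direction-specific scans and logged. An unequal-variance option (Welch
per-comparison tests with a Šidák family adjustment — a conservative
approximation, clearly weaker than the exact pooled procedure) exists but
is off by default. Zero pooled variance with unequal means reports p = 0
with a warning; all-equal constant data report p = 1.

## Binomial enrichment scan

Among the n trait-significant lines with an informative call at a marker,
let k carry the donor allele (D or H, consistent with segment calling). The
score is the one-sided binomial tail P(X ≥ k), X ~ Bin(n, p₀); a marker is
"linked" when the tail probability falls below the threshold (default
1e-3). No across-locus correction is applied by default — raw p-values are
reported with an optional Benjamini–Hochberg column — because the scoring
rule itself is defined on the raw tail.

The null rate p₀ has three modes:

* `empirical_locus` (default): the donor-carrier frequency at that marker
  over the *whole* genotyped library of that donor. Trait-based selection
  during line development distorts pedigree expectations locus by locus, so
  the locus's own library frequency is the appropriate null.
* `empirical_genome`: one genome-wide mean frequency.
* `theoretical`: the pedigree expectation 2^−(b+1) after b backcrosses.

Empirical frequencies of exactly 0 or 1 are clamped to [1/(2N), 1 − 1/(2N)]
with a warning. Scans run separately on increase- and decrease-direction
sets; linked results are grouped by (marker, trait) across donors, counted
by number of distinct donor species, and classified as increase-only,
decrease-only, or both. Loci are marker-anchored; an optional merge of
map-adjacent linked markers (anchored at the smallest p) is available for
figure-style reporting.

Novelty annotation: a consolidated locus is "known" if it lies inside a
known-locus interval with a matching trait tag, or strictly closer than the
window (default 2.5 Mb ≈ one marker interval) to one; a marker exactly one
window beyond an interval end is novel. Known loci are read from BED
(0-based half-open) and converted to the internal 1-based closed convention
on ingest.

## Breeding-scheme simulator

The simulator emulates the BC₂–BC₆ backcross + selfing scheme that produced
the libraries. Physical→genetic distance is linear at a configurable
density (default 4 cM/Mb, a rice-like genome-wide average); meiosis follows
the Haldane model — Poisson crossover counts with mean equal to the map
length in Morgans, positions uniform, no interference, random starting
haplotype. F₁ = donor × recurrent; each backcross crosses a gamete against
the fully inbred recurrent parent; selfing draws two independent gametes
from the same plant. The expected donor genome fraction after b backcrosses
is 2^−(b+1), unchanged by selfing.

Phenotype: value = baseline + Σ_QTL additive × dosage/2 (+ dominance for
dosage 1) + environment effect + N(0, σ). Defaults emulate grain length in
mm: baseline 7.0, residual SD 0.2, 3 replicates per line, 10 for the
control, two environments offset by 0.15. Genotyping calls D/R/H from the
true diplotype at each marker, with an optional independent symmetric
miscall rate (the call is replaced by one of the other two states,
uniformly).

Selection, when enabled, is truncation on a single simulated phenotype
draw: a plant survives if |value − baseline| exceeds a threshold (default
2.0) in residual-SD units, emulating advancing only plants with a visible
agronomic difference; selection intensities of the real program are
unknown, so they are exposed as free parameters. Without selection each
output line descends through its own single-plant lineage, making lines
independent Monte-Carlo draws (which the standard-error arguments in the
validation experiments require); with selection a per-generation population
of configurable size is maintained and parents are drawn from the selected
fraction. All randomness flows from the single config seed; identical
configs give byte-identical output.

What the simulator does *not* model: interspecific hybrid sterility,
female-only transmission, embryo rescue, segregation distortion, crossover
interference, field/block structure (replicates are exchangeable), marker
ascertainment bias. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated genetic model, not robustness to
those real-data complications.

## Validation experiments and problem sizes

The default experiment genome is 3 chromosomes of 30/25/20 Mb with markers
every 2.5 Mb (mirroring the ~2.2 Mb mean marker interval of a 168-marker
rice panel); a 12-chromosome rice-scale configuration is bundled
(`data/rice12.yaml`). Sizes were chosen so the full suite runs in a few
minutes on one core while leaving the Monte-Carlo checks well powered:

* segment caller vs brute-force per-interval classifier: 1,000 random
  matrices (≤5 chromosomes × ≤30 markers, all four call codes, both het
  policies), exact agreement required;
* binomial tail vs exhaustive enumeration: all n ≤ 12, error < 1e-12;
* Dunnett k = 1 vs pooled t-test: max |Δp| < 1e-3 (observed ~2e-5); the
  family-wise error rate over 2,000 null libraries of 50 lines stays below
  0.065 at α = 0.05;
* pedigree expectation: mean donor fraction within 3 Monte-Carlo SE of
  2^−(b+1) for b ∈ {2, 6} at 2,000 independent lines;
* donor-proportion recovery at 1 Mb markers, 500 BC₂F₄ lines: |mean bias| ≤
  0.02 and Pearson r ≥ 0.95 against truth;
* end-to-end: one planted QTL dominating trait variance, 200 lines — the
  marker nearest the QTL is flagged in ≥90% of 100 replicates; 500 no-QTL
  libraries (lines selected purely on phenotype, which is then independent
  of genotype) yield ≤0.3% flagged loci at threshold 1e-3.

## Known limitations

* The weighted estimator's heterozygosity bias (above) matters for lines
  genotyped before fixation.
* The equicorrelated Dunnett evaluation assumes the one-factor correlation
  structure exact for a common control group; it does not cover covariate
  adjustment or blocked designs.
* `empirical_locus` p₀ is estimated from the same library that supplies the
  significant set; for very small libraries the two are weakly coupled.
* The scan nominates marker loci, not intervals; resolution is bounded by
  marker spacing, and nearby QTLs inside one interval are indistinguishable.
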