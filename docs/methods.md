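# Methods

This note records the statistical model behind each stage of `specdelim`, the
defaults and why they were chosen, and the limits of what the synthetic tests
demonstrate.

## Distances

Two distance models are provided. The uncorrected p-distance is the
proportion of differing sites among comparable sites for a pair; it is the
input to every K/θ quantity because the 4X rule is defined on raw
divergences. Corrected distances use the Tamura–Nei (TN93) model with gamma
rate heterogeneity,

    d = a · [k1·(w1^(−1/a) − 1) + k2·(w2^(−1/a) − 1) + k3·(w3^(−1/a) − 1)],

where the k's are functions of base frequencies estimated from the sequence
pair, the w's are linear in the two transition proportions and the
transversion proportion, and a is the gamma shape (default 1, the value used
for the crayfish analyses this package reproduces). When a w term is
non-positive the pair is saturated beyond the model's reach and the distance
is reported as infinite with a warning, never silently clamped. The
implementation is cross-checked in the test suite against frozen reference
values computed with R's `ape::dist.dna(model = "TN93", gamma = 1)` on
two-sequence fixtures (for a pair, `ape`'s whole-alignment base frequencies
coincide with the pairwise frequencies used here).

Deletion policies: `complete` removes every column containing `-` or `N` in
any sequence before anything else is computed; `pairwise` keeps columns per
pair. `N` and `-` are treated identically — both make a site incomparable.
Complete deletion is the default everywhere because it is the only deletion
behaviour the reproduced workflow states; pairwise deletion is exposed as a
flag since the original K/θ computation's policy is not documented.

Group summaries: within-group mean d_X (0 by convention for singleton
groups, with a warning — single-specimen lineages must keep a computable net
distance), between-group mean d_XY, and the net distance
net = d_XY − (d_X + d_Y)/2, which may legitimately be negative and is not
clamped. Bootstrap standard errors resample columns of the post-deletion
alignment with replacement (matching the convention of operating on the
analysed sites), recompute the statistic per replicate, and report the
standard deviation across replicates; failed replicates are dropped and
counted.

The "Maximum Composite Likelihood" distances of the original MEGA-based
workflow are not reproduced: MCL's composite parameter estimation is internal
to MEGA, and none of the decision-bearing statistics here (K/θ, the φ_CT
plateau, the gap order condition) depend on it. TN93+Γ (shape 1) is the
documented stand-in wherever a corrected distance is wanted.

## AMOVA and the φ_CT plateau

The nested decomposition is the standard three-level AMOVA: with squared
molecular distances δ²_ij between individuals (default: the count of
differing sites, so that the analysis reflects both haplotype frequency and
divergence), sums of squares are

    SSD(total) = Σ_{i<j} δ²_ij / N,   SSD(WP), SSD(WG) analogously per stratum,

and the variance components σ²_c, σ²_b, σ²_a are solved from the mean-square
expectation system with the unequal-sample-size coefficients

    n1 = (N − Σ_g Σ_{p∈g} n_p²/n_g) / (P − G)
    n2 = (Σ_g Σ_{p∈g} n_p²/n_g − Σ_p n_p²/N) / (G − 1)
    n3 = (N − Σ_g n_g²/N) / (G − 1).

Negative component estimates are retained and flagged (standard practice;
truncation would make the φ arithmetic opaque). φ_CT is NaN for a single
group; φ_SC is NaN when σ²_b + σ²_c = 0 (the 0/0 case of pure among-group
variation). AMOVA runs on all specimens rather than collapsed haplotypes
(the haplotype-frequency information is part of the statistic). An optional
seeded permutation p-value for φ_CT (whole populations permuted among
groups, 999 permutations) is offered as a diagnostic only. φ_CT > 0.95 is
reported as a boolean benchmark flag but never drives selection — lineage
number is chosen by the plateau, not a fixed cutoff.

The plateau criterion formalises "adding lineages stops appreciably
increasing φ_CT": the selected k is the smallest candidate such that every
larger candidate k′ satisfies (φ_CT(k′) − φ_CT(k))/(k′ − k) < τ. The default
τ = 0.02 per added lineage reproduces the six-lineage selection on the
published Queensland φ_CT series for both COI and 16S while rejecting the
five-group arrangement (whose next step gains ≈ 0.116); because the original
judgment was made visually from the curve, τ is exposed as a flag. The
largest candidate satisfies the condition only vacuously, so when no smaller
candidate qualifies it is returned with an explicit no-plateau flag. A joint
selection across loci requires the same k everywhere, otherwise the result
is flagged discordant. Candidate arrangements are accepted as data (a TSV of
group labels per population, or nested partition levels, validated for
refinement); they are not inferred from a tree, since tree inference is
outside this package's scope.

## Barcoding gap

The gap decision is purely the order condition max(intra) < min(inter) on
haplotype-collapsed distances (duplicate sequences would otherwise pad the
intra set with zeros). No 10×-mean-intraspecific threshold is applied:
divergence rates vary too much across taxa and markers for a universal
multiplier, and the reproduced workflow explicitly declined it. Excluding a
lineage pair removes that pair's cross distances and both lineages' intra
distances while keeping their comparisons with every other lineage — the
diagnostic used to show that a single recent split is what destroys an
otherwise clean gap. When the sets overlap, the overlap magnitude and the
fraction of classified distances inside [min_inter, max_intra] are reported.
Histogram binning in the plots is cosmetic; decisions use raw distances.

## K/θ

π = d·n/(n−1) with d the mean within-clade p-distance; θ = π/(1 − 4π/3),
finite only for π < 3/4. When a clade is monomorphic (d = 0) the fallback
π = 2/(L·(n−1)) is used and flagged, L being the number of sites analysed;
the alternative reading 2/(L·n·(n−1)) is selectable by flag because the
source typography is ambiguous, but the default follows the stated symbol
gloss. The ratio uses the larger θ of the pair (conservative: a large
denominator makes the test harder to pass) and the verdict is ratio > 4.
A clade of one specimen has no defined θ at all (the fallback divides by
zero); such comparisons use the sister's θ as the maximum and carry a
`singleton_theta` flag. Sister clades come from the lineage hypothesis, with
polytomies resolved by minimum net K among candidates (ties broken by clade
id order, with a warning).

## Synthetic data

The generator "sprinkles" Jukes–Cantor substitutions along a star phylogeny:
each branch substitutes each site independently with probability q, replacing
the base with a uniformly chosen different base. Expected observed
p-distances then compose across branches as a ⊕ b = a + b − (4/3)ab
(equivalently, 1 − (4/3)·E[p] is multiplicative), which makes the generator
exactly calibratable in expectation: specimen branches solve m ⊕ m = π_w·r
for the within-population target, and lineage branches solve, in log space,
the star-tree least-squares system for ancestor divergences
A_ij = D_ij·r / (1 − (4/3)·c̄) so that the NET between-lineage distance —
not the raw between mean — hits D_ij·r. The calibration is exact for
two-lineage designs and constant divergence matrices with equal π_w (and
exact-in-expectation generally up to star-realisability of D); the test
suite verifies unbiasedness within 3 Monte-Carlo standard errors over 100
seeds at D = 0.08, π_w = 0.005, L = 600.

Defaults emulate the structure of the crayfish study system: unequal sample
sizes per population, two fast mitochondrial-style loci (644 and 449 sites)
and one nuclear-style locus at one fifth their rate (mitochondrial markers
accumulate substitutions several times faster owing to their smaller
effective population size), within-lineage diversity π_w = 0.005, net
divergence 0.08 within a region and 0.16 between regions, a 1% population
offset and 10% missing loci. What the simulator does not emulate:
recombination, migration/admixture between lineages, selection, indels
(alignments are gap-free; missingness enters as whole-locus dropout), rate
variation among sites, and non-star lineage histories. Passing recovery
tests therefore show that the statistics behave correctly when lineages are
genuinely isolated and well sampled — they do not show robustness to gene
flow, incomplete lineage sorting or alignment error on real data.

A deliberate consequence of population offsets: private population
divergence inflates within-lineage means, so with offsets comparable to the
lineage signal the populations-as-lineages arrangement becomes a genuine
competitor under the plateau rule. The recovery properties are therefore
stated (and tested) at the generator default of no population offset, with
a separate pipeline test at a small nonzero offset.

## Pipeline and concordance

Unplaced specimens (those missing from the hypothesis, e.g. localities absent
from a combined tree) join the lineage with the smallest mean distance to its
members; the margin to the runner-up is reported and exact ties are left
unassigned with a warning. Validation support is operationalised per lineage
and locus against its nearest lineage (minimum net K): barcoding support
means every cross distance exceeds both clades' intra maxima; K/θ support
means ratio > 4. A hypothesized split supported by neither method on any
locus is flagged "unsupported split" but retained — the original workflow
resolved exactly this situation (two recently diverged lineages failing K/θ)
by judgment, so the package surfaces the flag rather than inventing a merge
rule. The concordance table records, per population, the hypothesis lineage,
per-method support, a support level (both methods / one method / discovery
only) and the final lineage; final lineages always partition the populations.

Problem sizes in the shipped tests and acceptance script (alignments of
300–650 sites, 10–110 specimens, 25–200 replicates) were chosen as the
smallest designs at which the Monte-Carlo bands above are meaningful.

## Known limitations

* AMOVA is per-locus; no joint multi-locus AMOVA is attempted.
* The TN93+Γ stand-in means corrected distances differ in the third decimal
  from MCL-based published tables; order statistics (gaps, argmin sisters)
  are insensitive to this in all tested regimes, but exact corrected-distance
  reproduction is out of scope.
* Candidate arrangements and the lineage hypothesis are inputs; the package
  neither infers trees nor proposes arrangements from them.
* The permutation test permutes whole populations among groups only (the
  φ_CT null); within-group permutation schemes for φ_SC are not implemented.
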