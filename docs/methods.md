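# Methods

This note records the statistical conventions, model assumptions and
design choices behind `volesurf`, in the spirit of the methods sections
of mature population-genetics packages. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model

Microsatellite data are diploid calls per individual × locus with
integer allele labels (fragment sizes or repeat counts); a call
containing a 0-encoded allele is treated as wholly missing, because
half-calls cannot enter frequency estimates. GenePop files with 2- or
3-digit allele coding are auto-detected; site ids come from the
trailing individual label of each POP block (overridable), since the
format has no site-name field.

mtDNA data are stored as (haplotype, site) → count, not per-individual
assignments: published haplotype tables report occurrence counts, and
every statistic here is computed with count weights, exactly equal to
computing on the count-expanded list of sequences. Haplogroup
membership is an input mapping, never inferred — tree inference is out
of scope.

## Diversity statistics

* H_e is reported both biased (1 − Σp², the GENALEX convention) and
  unbiased (2n/(2n−1) correction). Downstream surfing regressions use
  the biased form for comparability with the bulk of the microsatellite
  literature.
* Allelic richness uses hypergeometric rarefaction on **gene copies**
  (default g = 14, i.e. 7 diploids), the HP-Rare convention; "minimum
  sample size 14" in field studies almost always counts genes, and
  rarefaction never extrapolates — sites with fewer than g copies get
  an undefined A_r with a warning.
* Per-site means over loci are unweighted; whether field studies weight
  them by sample size is usually unstated, and unweighted means are the
  common default.
* Rare alleles use the 0.05 frequency threshold throughout; the
  rare-to-common scan pools frequencies at cluster level.

## Hardy–Weinberg testing

A Monte-Carlo exact test on gene-copy pairings replaces the classical
score tests: the site × locus gene-copy pool is randomly re-paired, the
two-sided statistic is |H − E[H]| for the heterozygote count H, with
the exact random-pairing expectation
E[H] = n·(1 − Σ_a C(N_a,2)/C(2n,2)), and the p-value carries +1/+1
continuity. This is assumption-free and exactly matched by an
enumeration over perfect matchings in the test suite. Bonferroni
correction is applied across site × locus tests.

## Differentiation

Pairwise F_ST is Weir & Cockerham's (1984) θ: per locus and allele the
among-population (a), among-individual (b) and within-individual (c)
variance components are computed for the two sites, summed over alleles
and loci, and the ratio Σa/Σ(a+b+c) is taken. Negative estimates are
retained (they are part of the estimator's sampling distribution and
keep downstream averages unbiased); transforms that require θ < 1
exclude offending pairs instead of clamping. Loci with fewer than two
genotyped individuals in either member of a pair are dropped for that
pair with a warning.

Nei's D_a = 1 − (1/L) Σ_l Σ_a √(x_a y_a) feeds a Saitou–Nei
neighbour-joining tree (scikit-bio's implementation; negative branch
lengths clamped to zero).

AMOVA uses the number-of-different-alleles distance between gene
copies, computed locus by locus and summed — the F_ST-like convention,
not the allele-size (R_ST-like) one. Variance components follow the
standard nested expectations with unequal sample-size coefficients;
p-values permute individuals among sites (Φ_ST), individuals among
sites within clusters (Φ_SC), and whole sites among clusters (Φ_CT).
A 3-level design requires every cluster to hold ≥2 sites; otherwise the
2-level design applies.

## Sequence statistics

Columns containing a gap or an ambiguous base are excluded from π, k,
the mismatch distribution and all neutrality tests. The segregating-
site count S can optionally include indel events, with each maximal run
of contiguous gap columns counted as one event when its
presence/absence pattern varies — the convention of the standard
sequence-polymorphism software this mirrors.

* Hd = n/(n−1)(1 − Σp²) over haplotype frequencies.
* Tajima's D uses the standard a₁…e₂ constants with S from gap-free
  substitution sites; D is undefined (flagged NaN) at S = 0, never 0.
  The implementation agrees with an independent library to 1e-9 and
  its null mean over 500 constant-size coalescent samples is close to
  the slightly negative finite-sample expectation.
* Fu & Li's D* and F* use the outgroup-free (starred) statistics with
  the corrected variance constants of Simonsen et al. (1995); η counts
  mutations (distinct bases − 1 per site) and η_s counts bases carried
  by exactly one sequence.
* Fu's F_s sets θ = k (mean pairwise differences) and computes
  S′ = P(K ≥ k_obs) under the Ewens sampling distribution with unsigned
  Stirling numbers of the first kind evaluated in log space (stable to
  n in the hundreds); F_s = ln(S′/(1−S′)).

## Mismatch distribution and the sudden-expansion model

The expected mismatch under a sudden expansion (present scaled size θ₁
for τ mutational units, θ₀ before) is

F_j = F̂_j(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_{i≤j} (τ^i/i!)[F̂_{j−i}(θ₀) − F̂_{j−i}(θ₁)],

with the geometric equilibrium F̂_j(θ) = θ^j/(1+θ)^{j+1} (derived from
the two-epoch pairwise coalescent). Fitting minimises
SSD = Σ(obs − exp)² by Nelder–Mead from a multi-start grid over
τ ∈ [0, 50] and θ ∈ [0, 100] plus a moment start at the observed mean —
the SSD surface is multimodal in τ, and single-start optimisation is
unreliable. Goodness-of-fit p-values come from a parametric bootstrap:
coalescent samples of the observed size are simulated under the fitted
model (msprime two-epoch demography, infinite sites), each replicate is
**refitted**, and p is the proportion of replicates with SSD (or
raggedness) at least the observed value.

Harpending's raggedness is r = Σ_{i=1}^{d+1} (x_i − x_{i−1})² over the
observed classes 0..d with an implicit zero class at d+1 — the original
convention (software differs here, so it is stated explicitly; the
difference only moves r by boundary terms).

## Surfing inference

* IBD regresses θ/(1−θ) on ln(km) over unordered site pairs
  (great-circle distances, Earth radius 6371.0088 km). Pairs with
  θ ≥ 1 or zero distance are excluded with warnings. A Mantel
  permutation p-value is available alongside the parametric one.
* Start/arrival sites: for an ordered cluster route, each source site's
  vector of pairwise θ to all target-cluster sites enters a one-way
  ANOVA with Tukey HSD follow-up; the focal site minimises the mean and
  is flagged significant only if it differs from **every** other source
  site at α = 0.05. Ties within 1e-12 are reported, never silently
  broken. The starting designation is annotated with whether the site
  also maximises A_r; a failed check is a warning, not a failure —
  in real expansions the source-edge deme need not be the most diverse.
  The F_ST vectors entering the ANOVA are treated as independent
  observations, a known approximation inherited from the method.
* Cline regressions use θ to the focal site as the distance proxy
  (field systems often lack within-cluster IBD, making geographic
  distance a poor dispersal measure); the geographic variant remains
  available. The focal site itself is excluded by default — its θ to
  itself is 0 by construction and is not an independent observation.
  Allele-frequency clines report signed Pearson r, R², p with
  significance stars (ns/*/**), uncorrected as is conventional for
  these scans, plus a Benjamini–Hochberg column for honest reporting.
* Rare-to-common: an allele is listed when its pooled source-cluster
  frequency is < 0.05 and either some derived-cluster site reaches
  ≥ 0.25 or the pooled derived frequency reaches ≥ 0.10. The 0.25
  "common" threshold is a package choice (no standard exists); both
  evidence columns are emitted so any threshold can be re-applied.

## The simulator

`simulate_expansion` is a forward-time, discrete-generation model on a
chain of demes: diploid Wright–Fisher reproduction with logistic
regulation to K, symmetric nearest-neighbour migration at rate m
between occupied demes, and colonisation of the next empty deme by F
founders drawn (emigrated) from the frontier once it reaches a fraction
of K. Microsatellites mutate stepwise (±1 repeat, reflecting at 5 and
60 repeats); every individual carries a maternally inherited sequence
locus under finite-sites mutation (at most one new mutation per
individual per generation — a negligible approximation at realistic
rates). Individuals are sexed at birth (ratio 0.5) and mtDNA follows
mothers.

Default conditions (chosen once to produce the qualitative signatures
the inference must detect, since no demographic parameters exist for
the study system): 12 demes, K = 200, F = 8, m = 0.01, 12 loci at
μ = 5×10⁻⁴, 500-bp mtDNA at 5×10⁻⁶/site, 50-generation burn-in, 250
generations, 50 sampled per deme. The origin is initialised from a
rich allele pool (discretised normal, sd 2.5 repeats) so that
source-region H_e sits in the 0.55–0.75 range typical of colonial
rodent microsatellite surveys; the mtDNA starts from two divergent
matrilines, reproducing the two-dominant-haplotype, star-like pattern
of intraspecific control-region data. The 23-site "paper-like" profile
uses gentler founder events (F = 40, m = 0.05) so that diversity and
F_ST stay in the empirically typical range across a route three times
longer; the "surf-heavy" profile (F = 4, m = 0.005) maximises surfing.

Mutation–drift equilibrium cannot be reached affordably at the default
K within a test budget, so the equilibrium check runs a small-K
configuration (K = 50, μ = 2.5×10⁻³, 500-generation burn-in) where the
stepwise-model prediction H_e = 1 − 1/√(1+2θ), θ = 4Kμ, is matched
within 10%.

What the simulator does **not** emulate: overlapping generations and
seasonal outbreak dynamics, landscape heterogeneity beyond chain
topology, genotyping error and null alleles, mutation-rate
heterogeneity among loci or sites, and selection. Passing tests
therefore demonstrate that the inference recovers serial-founder
structure under a clean stepping-stone history — not that it is robust
to those real-data complications.

## Problem sizes and numerical choices

Replicate-based validation uses 20 simulated expansions per claim (the
compact 12-deme configuration keeps each replicate under a second) and
one 23-site study-scale dataset for the summary statistics; bootstrap
and permutation counts default to 1000 (AMOVA and mismatch) and 10000
(HWE) in the API, with smaller counts used in tests and the acceptance
script where the quantity being checked is a rate rather than a tail
probability. All Monte-Carlo p-values carry +1/+1 continuity and every
stochastic routine takes an explicit seed; the pipeline derives
stage-keyed substreams from one master seed so stages rerun
identically in isolation.

## Known limitations

* The cross-cluster ANOVA treats pairwise F_ST values as independent
  observations (inherited approximation; flagged above).
* The mismatch SSD is computed over the observed support without
  renormalising the expected tail mass beyond it; for strongly
  truncated distributions the fitted θ₁ absorbs this.
* Fu's F_s evaluates Stirling numbers by an O(n²) log-space recurrence;
  beyond n of a few thousand this becomes the dominant cost.
* The deposited-data checks (segregating sites, haplotype diversity,
  Tajima's D, raggedness of the vole D-loop data) require a one-time
  download of the GenBank haplotypes and manual transcription of the
  published count table; they cannot run in a fully offline build.
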