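# volesurf

Population-genetic analysis of range expansion and **genetic surfing**,
built around the study system of Brandt's vole (*Lasiopodomys
brandtii*): colonial steppe rodents that spread from an ancestral region
through serial founder events, leaving a gradient of eroding diversity
and occasional rare alleles "surfing" to high frequency on the wave
front.

The package takes diploid microsatellite genotypes (GenePop), aligned
mtDNA D-loop sequences (FASTA with a per-site haplotype count table),
and site metadata (coordinates + cluster labels), and computes:

* **Diversity** — allele frequencies, N_a, H_o, H_e = 1 − Σp²,
  unbiased H_e, rarefied allelic richness
  A_r(g) = Σ_i [1 − C(N−N_i, g)/C(N, g)] at a standard sample of g gene
  copies, private and rare (<0.05) alleles, Monte-Carlo
  Hardy–Weinberg tests.
* **Differentiation** — pairwise Weir–Cockerham θ (variance components
  a, b, c summed over alleles and loci), Nei's D_a with a
  neighbour-joining tree, and hierarchical AMOVA
  (cluster > site > individual) with permutation p-values.
* **Sequence statistics** — haplotype diversity
  Hd = n/(n−1)·(1 − Σp²), nucleotide diversity π, segregating sites
  (indel events optional), Tajima's D, Fu & Li's D*/F*, Fu's F_s, the
  mismatch distribution with a Rogers–Harpending sudden-expansion fit
  (τ, θ₀, θ₁; SSD and Harpending's raggedness r with parametric
  bootstrap p-values).
* **Surfing inference** — isolation by distance as F_ST/(1−F_ST) vs
  ln(km); start/arrival-site identification from cross-cluster mean
  F_ST (ANOVA + Tukey HSD); H_e/A_r and allele-frequency cline
  regressions against F_ST to the focal site; a rare-to-common allele
  scan between source and derived clusters.
* **A forward-time simulator** — stepping-stone range expansion with
  serial founder events, stepwise-mutating microsatellites and a
  maternally inherited sequence locus, emitting full ground truth so
  every inference above can be validated against a known origin.

## Worked example

Simulate an expansion with a known origin and run the full inference:

```python
from volesurf.simulate import SimConfig, simulate_expansion
from volesurf.msat import pairwise_fst, diversity_summary
from volesurf.surfing import cross_cluster_mean_fst, diversity_cline

clusters = ["SE"] * 4 + ["NE"] * 4 + ["W"] * 4
gt, hd, meta, truth = simulate_expansion(
    SimConfig(seed=7, origin=3, clusters=clusters))

fst = pairwise_fst(gt)
div = diversity_summary(gt, meta)          # rarefied at g=14 gene copies
focal = cross_cluster_mean_fst(fst, meta, "SE", "NE")
print(truth.origin, focal.focal, round(focal.anova_p, 4))
cline = diversity_cline(div, fst, focal.focal, "SE", meta)
print(round(cline.he.slope, 3), round(cline.he.p_value, 4))
```

prints

```
3 s03 0.0766
-0.631 0.0921
```

— the site with the lowest mean F_ST to the derived cluster (`s03`) is
exactly the true origin deme, and expected heterozygosity declines with
F_ST to it (the short 3-site within-cluster regression is suggestive;
across all 12 demes the decline is strongly significant — this is the
serial-founder signature the method is designed to detect).

The same analyses are scriptable from the shell:

```bash
volesurf simulate --seed 7 --out sim/
volesurf fst --genepop sim/genotypes.gen --out out/
volesurf focal --genepop sim/genotypes.gen --meta sim/sites.tsv \
    --route SE,NE,W --out out/
volesurf run --config config.yaml --out out/
```

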