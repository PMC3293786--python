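# phyloniche

Phylogeography statistics and presence-only ecological niche modelling for
studies that ask *how* a species complex diverged: did lineages split behind
geographic barriers while keeping the same ecological niche (allopatry with
niche conservatism), or did divergent selection pull them into different
environments (niche divergence)?

The package implements, as one tested pipeline, the two analytical halves
such studies combine:

**Sequence side (`phyloniche.popgen`)** — from haplotype alignments with a
two-level sampling design (groups ⊃ populations):

- nucleotide diversity π and haplotype diversity
  Hd = n/(n−1)·(1 − Σpᵢ²);
- Tajima's D = (π − S/a₁)/√(e₁S + e₂S(S−1)) and Fu's
  Fs = ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens sampling
  distribution at θ̂ = π — both negative after population expansion;
- pairwise distances (p, JC69, TN93, optional gamma rate heterogeneity);
- hierarchical AMOVA with Φ_CT, Φ_SC, Φ_ST and the three standard
  permutation schemes;
- minimum-spanning haplotype networks with equally parsimonious
  alternative edges;
- a configurable north/south split of populations by latitude.

**Environment side (`phyloniche.enfa`, `phyloniche.divergence`)** — from
co-registered raster predictors and geo-referenced presences per lineage:

- Box-Cox normalisation and an |r| > 0.90 collinearity filter;
- Ecological Niche Factor Analysis: one marginality axis (direction from the
  global mean environment to the presence mean; M = ‖m‖/1.96) plus
  specialization axes with eigenvalues λ (global-to-presence variance
  ratios), retained by MacArthur's broken-stick rule;
- habitat-suitability maps (HS 0–100, median algorithm) binarized at the
  minimum training presence;
- the niche-divergence suite: omission error, leave-one-population-out
  representativeness, interpredictivity (ANOVA on arcsin-√ transformed HS
  with Tukey HSD), lumped-vs-split overprediction and false-positive rates,
  binary-map overlap, and minimum-convex-polygon contact zones.

A first-class synthetic-data module (`phyloniche.synthetic`) generates
haplotype samples (Kingman coalescent or star genealogies, known
between-group divergence) and smoothed-noise landscapes with Gaussian
niches, so every stage has parameter-recovery and discrimination tests with
known ground truth.

## Worked example

```python
import numpy as np
from phyloniche import popgen as pg, synthetic as syn, enfa as en, divergence as dv

cfg = syn.HaplotypeSimConfig(n_groups=2, pops_per_group=2, n_per_pop=12,
                             theta=4.0, divergence_mutations=12,
                             seq_length=600, seed=42)
aln, struct = syn.simulate_haplotypes(cfg)
stats = pg.neutrality_summary(aln)
print(f"n={stats.n}  S={stats.S}  pi={stats.pi_per_site:.4f}  "
      f"Hd={stats.haplotype_diversity:.3f}  D={stats.tajimas_d:.3f}  "
      f"Fs={stats.fus_fs:.3f}")

dist = pg.pairwise_distance(aln) * aln.length       # counts of differences
res = pg.amova(dist, aln.ids, struct, n_permutations=999, seed=1)
print(f"Phi_CT={res.phi_ct:.3f} (p={res.p_phi_ct:.3f})  "
      f"Phi_SC={res.phi_sc:.3f} (p={res.p_phi_sc:.3f})  "
      f"Phi_ST={res.phi_st:.3f} (p={res.p_phi_st:.3f})")

stack = syn.simulate_landscape(syn.LandscapeSimConfig(seed=7))
pa, pb = syn.simulate_lineage_scenario("divergent", stack, 15, seed=8)
model = en.fit_enfa(stack, pa)
print(f"marginality M={model.marginality:.2f}  retained factors={model.retained}  "
      f"first-two variance={en.variance_captured(model, 2):.0f}%")
hs = en.habitat_suitability(model, stack)
binary = en.binarize(hs, pa)
print(f"minimum training presence threshold={binary.threshold:.1f}  "
      f"suitable cells={binary.area}")
comp = dv.lumped_split_overprediction(stack, pa, pb)
print(f"lumped-vs-split overprediction={comp.overprediction_pct:.1f}%")
```

prints

```
n=48  S=49  pi=0.0166  Hd=0.958  D=-0.345  Fs=-1.979
Phi_CT=0.742 (p=0.326)  Phi_SC=0.360 (p=0.001)  Phi_ST=0.835 (p=0.001)
marginality M=0.40  retained factors=[0, 1]  first-two variance=88%
minimum training presence threshold=13.3  suitable cells=17353
lumped-vs-split overprediction=27.9%
```

Reading it: the simulated sample carries 49 segregating sites and high
haplotype diversity; the 12 fixed differences planted between the two
groups drive most of the molecular variance among groups (Φ_CT = 0.74), yet
its permutation p-value is large because permuting only 4 whole populations
among 2 groups allows just a handful of distinct rearrangements — exactly
the behaviour expected of the population-level permutation scheme at small
designs. The fitted niche model is marginal (M = 0.40) and concentrates 88%
of its variation in the first two factors; the lumped model for the two
deliberately divergent lineages predicts 28% more suitable area than their
overlaid split models.

A `phyloniche` command-line interface mirrors the library
(`simulate | popgen | enfa | diverge | report`); each stage writes outputs
the next one consumes and reruns byte-identically under the same seeds.

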