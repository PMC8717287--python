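# mimicline

Analysis toolkit for a Müllerian-mimicry color transition zone in the
bumble bee *Bombus melanopygus*, where a northern ferruginous form and
a southern black form — each ancestrally carrying its own mitochondrial
COI haplogroup — meet along a north–south transect and exchange genes
asymmetrically.  The package is aimed at population geneticists who
want the whole desk side of such a hybrid-zone study as tested,
reusable code:

- **Transect projection** of specimen coordinates onto a 1D latitudinal
  axis (km from the southernmost specimen).
- **Color-allele frequencies under dominance with haplodiploidy**: for
  diploid females the black-allele frequency is the Hardy–Weinberg
  inversion `b = √(proportion of black females)` (black is recessive,
  so only `bb` is phenotypically unambiguous); haploid males give `b`
  directly as a proportion; sexes combine treating individuals
  equally.  A chi-square test of independence checks temporal change
  per locality.
- **Equilibrium geographic clines** `p(x) = pmin + (pmax−pmin)·(1 +
  tanh(2(x−c)/w))/2` with three model classes (fixed/free scaling,
  optional exponential tails), fitted to individual-level data by
  Metropolis–Hastings MCMC, compared by AICc, and contrasted across
  traits (`compare_clines` gives the mito-nuclear center shift with a
  posterior).
- **Mito-nuclear discordance tests**: two df = 1 goodness-of-fit
  constructions comparing haplogroup counts with color-allele
  frequencies inside the hybrid zone.
- **COI statistics and haplotype networks**: variable and
  parsimony-informative sites, p-distance divergence, fixed
  inter-haplogroup differences, divergence time at a COI clock
  (1.5%/Myr), gap coding, and a minimum-spanning haplotype network
  with reticulation.
- **NUMT-aware SNP filtering**: quality → structural → tiered interval
  exclusion, a fixed-SNP scan between haplogroup sample groups, and
  clustering diagnostics that expose nuclear-mitochondrial insertions
  (NUMTs) as tight clusters of spuriously fixed SNPs.
- **Nuclear structure**: allele-sharing distances, neighbor joining,
  LD pruning (r² > 0.5 in 5 kb), PCA, and sNMF-style ancestry via
  simplex-constrained matrix factorization with cross-entropy K
  selection.
- A **synthetic hybrid-zone generator** that plants all of the above
  structure (clines, haplogroups, NUMTs, admixture gradient) so every
  stage is testable without downloads.

See `docs/methods.md` for the models, assumptions and numerical
choices.

## Worked example

Simulate a small zone, then test for mito-nuclear discordance and
summarize the COI haplotype network:

```
$ printf 'n_specimens: 300\nn_snps: 500\n' > sim.yaml
$ mimicline simulate --config sim.yaml --outdir fixtures --seed 1
$ mimicline discordance --in fixtures/specimens.tsv
{
  "window_km": [563.85, 712.75],
  "n_north": 23,
  "n_south": 12,
  "f_alleles": 29.0,
  "b_alleles": 33.0,
  "haplotype_vs_colorallele": {"chi2": 5.043, "df": 1, "p": 0.0247},
  ...
}
$ mimicline network --in fixtures/coi.fasta --out net.tsv
{
  "n_sequences": 300,
  "n_haplotypes": 7,
  "n_edges": 6,
  "n_variable": 13,
  "n_parsimony_informative": 12
}
```

The discordance test says: within the 564–713 km hybrid-zone window,
southern haplogroups are over-represented relative to the black-allele
frequency (χ² = 5.04, p = 0.025) — the planted signature of the
mitochondrial cline sitting south of the color cline.  The COI
alignment collapses to 7 haplotypes in two groups separated by 8
mutational steps, with 13 variable sites of which 12 are
parsimony-informative.

Fitting cline models to a binary trait simulated from a cline with
center 607 km and width 157.6 km (n = 500 specimens-as-localities):

```python
from mimicline.synthetic_data import simulate_cline_observations
from mimicline.cline_fit import fit_cline, MCMCSettings, select_model

x, y = simulate_cline_observations(607.0, 157.6, 500, seed=11)
fits = [fit_cline(x, y, mc, mcmc=MCMCSettings(iterations=15_000, seed=5))
        for mc in ("I", "II")]
best, table = select_model(fits)
```

prints, via the fit report: selected model I, center 596.5 km
(95% credible interval 578.4–615.1, 2-logL support 577.3–615.6),
width 142.1 km, with AICc 94.3 for model I vs 98.5 for model II.  The
truth (607, 157.6) lies inside the intervals; the parsimonious
fixed-scaling model wins, as it should for a binary trait spanning
0 to 1.

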