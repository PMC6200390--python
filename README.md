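# microbiability

Variance partitioning of dairy-cow methane emissions into host-genetic and
rumen-microbiome components.

Enteric methane (CH₄) production varies widely among lactating dairy cows.
Two inheritance-like channels can explain that variation: the cow's own
additive genetics, and the composition of her rumen microbial community.
This package implements the quantitative-genetic machinery to separate the
two for animal breeders and rumen microbiologists working with pedigree
records, 16S OTU count tables, and per-cow phenotypes:

* **Heritability** — the animal model
  `y = Xb + a + e`, `a ~ N(0, A σ²ₐ)`, where **A** is the pedigree numerator
  relationship matrix (tabular method), gives `h² = σ²ₐ / σ²ₚ`.
* **Microbiability** — the analogous microbial model `m ~ N(0, M σ²ₘ)`,
  where `M = XX'/n` is built from natural-log transformed relative
  abundances of bacterial + archaeal OTUs, centered and scaled within
  sequencing platform, gives `m² = σ²ₘ / σ²ₚ`.
* **Joint model** — both random effects fit simultaneously by AI-REML with
  EM fallback, with SEs from the average-information matrix, delta-method
  SEs for the ratios, and boundary-mixture likelihood-ratio tests.
* **Per-taxon scans** — animal-model heritability of each taxon's log
  abundance, and mixed-model association of each taxon with the phenotype
  (P3D-style or exact), both with Benjamini–Hochberg FDR control.
* **Community structure** — Bray–Curtis dissimilarity, PCoA, top/bottom-10%
  emitter contrasts (Mann–Whitney), and ANOVA + animal-model decomposition
  of ordination axes.
* **Synthetic herds** — a generator that emulates the full study design
  (multi-generation sire-dominated pedigree, compositional OTU counts with
  a heritable minority of taxa, platform/batch structure, herd/parity/
  lactation fixed effects) with known ground truth, so every estimator can
  be validated by parameter recovery.

The fixed-effect structure throughout is herd, parity, days in milk (dim)
and the Wilmink early-lactation term `exp(-0.065 · dim)`; taxon-level models
add sequencing batch nested within platform.

## Worked example

```python
from microbiability import (SimConfig, simulate_dataset, build_A,
                            microbial_kernel, build_design, fit_reml)

cfg = SimConfig(n_founders=400, n_generations=2, n_sires=12,
                n_bact_otus=400, n_arch_otus=40,
                true_h2=0.21, true_m2=0.13, seed=5)
ds = simulate_dataset(cfg)

ids = ds.phenotypes["animal"].tolist()
A = build_A(ds.pedigree, subset=ids)
M = microbial_kernel(ds.otu_table).subset(ids)
X, _ = build_design(ds.phenotypes)
fit = fit_reml(ds.phenotypes["ch4_g_day"].to_numpy(), X,
               {"A": A.values, "M": M.values})
print(f"h2 = {fit.ratios['A']:.3f} +/- {fit.ratio_se['A']:.3f}")
print(f"m2 = {fit.ratios['M']:.3f} +/- {fit.ratio_se['M']:.3f}")
```

Output from this exact script:

```
h2 = 0.212 +/- 0.106
m2 = 0.177 +/- 0.076
```

Both intervals cover the configured truth (0.21, 0.13); a single herd of
~400 cows carries limited information about either ratio (on other seeds
the microbial component can hit the zero boundary), which is why the
package's validation averages over many replicate herds of 1000 cows (see
below).

The same analysis runs from the shell:

```sh
microbiability simulate --out sim/          # writes pedigree, OTU counts,
                                            # phenotypes + truth sidecar
microbiability run --pedigree sim/pedigree.csv \
    --phenotypes sim/phenotypes.tsv --otus sim/otu_counts.tsv --out results/
microbiability report results/
```

`results/` then holds tidy TSVs (`varcomp.tsv`, `lrt.tsv`, `taxon_h2.tsv`,
`association.tsv`, `manhattan.tsv`, PCoA coordinates/eigenvalues, emitter
groups, Mann–Whitney tests, axis decompositions) and a `manifest.json`
recording input checksums, filter counts and realized FDR thresholds.

## Layout

```
src/microbiability/
  pedigree.py     pedigree parsing, tabular A matrix, ancestor pruning
  microbiome.py   OTU filters (depth/abundance/prevalence), transforms, M
  reml.py         design builder, eigen + AI-REML, LRT, Wald, h2 scan
  association.py  per-taxon mixed-model scan, BH FDR, Manhattan table
  community.py    Bray-Curtis, PCoA, deciles, Mann-Whitney, axis ANOVA
  simulate.py     synthetic herd generator with ground-truth sidecar
  recovery.py     replicate parameter-recovery studies
  pipeline.py     end-to-end orchestration + manifest + report
  cli.py          click command line (simulate / kinship / kernel / run / report)
```

See `docs/methods.md` for the statistical model, numerical choices, and
what the synthetic herds do and do not emulate.
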