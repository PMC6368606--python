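# springdiv

Comparative functional-diversity analyses for chemosynthetic hot-spring
metagenomes.

Hot springs fed by mixtures of vapor-phase and deep hydrothermal fluids host
unusually diverse chemosynthetic microbial communities. `springdiv`
implements the computations used to quantify that diversity and its drivers:

* **Protein-family binning** — greedy incremental clustering of predicted
  proteins with a 90% → 60% → 30% identity cascade (Smith–Waterman local
  alignment, BLOSUM62, ≥80% coverage of the shorter sequence), yielding
  abundance-weighted family counts per metagenome.
* **Rarefaction** — Monte-Carlo subsampling without replacement and its
  closed-form companion E[S_d] = Σ_f [1 − C(N−N_f, d)/C(N, d)], so
  unequally sequenced springs can be compared at a common depth.
* **Diversity vs fluid mixing** — OLS regression of family richness on
  log₁₀(SO₄²⁻/Cl⁻), the geochemical proxy separating vapor-phase-fed from
  reservoir-fed springs.
* **KO profiles** — per-metagenome normalization, the centered enrichment
  statistic E = (a − m)/m (E = S−1 flags a KO exclusive to one of S
  metagenomes, E = −1 flags absence), KEGG category subsetting, Bray–Curtis
  dissimilarity, and principal coordinates analysis.
* **MAG quality and abundance** — the >50% completeness / <7% contamination
  filter and coverage-normalized relative abundances.
* **Genome differentiation** — unshared:shared KO ratios per KEGG category
  (Metabolism vs Genetic Information Processing) for intra-lineage genome
  pairs, and reciprocal-best-hit average amino-acid identity (AAI).
* **Phylogenetic placement** — root-to-tip distances and the fraction of a
  tree's branch length contributed by a tagged tip set.

A synthetic-study generator (`springdiv.synthetic`) produces complete studies
— proteomes with known family structure, geochemistry with a planted
richness–mixing slope, KO tables with planted exclusive KOs, genome pairs
with planted shared fractions, MAG tables, random trees — so the whole
pipeline is testable end-to-end with known ground truth.

## Worked example

Simulate a 15-spring study, recover protein families, and relate subsampled
richness to the fluid-mixing axis:

```python
from springdiv.synthetic import SyntheticConfig, generate_study
from springdiv.seqcluster import cascade, filter_by_length, family_abundance
from springdiv.diversity import fit_diversity_model, subsampled_richness
from springdiv.function_profile import normalize_ko, ko_enrichment, bray_curtis, pcoa

study = generate_study(SyntheticConfig(seed=42, n_springs=15))

records = filter_by_length(study.all_proteins())
assignment = cascade(records)                      # 90 -> 60 -> 30 % cascade
table = family_abundance(assignment, records)
print(f"{len(records)} proteins -> {table.shape[1]} families")

richness = subsampled_richness(table, depth=100, n_reps=100, seed=42)
fit = fit_diversity_model(richness, study.geochem)
print(f"slope={fit.slope:.2f}, adj R^2={fit.adj_r2:.2f}, p={fit.p_value:.2e}, n={fit.n}")

enrichment = ko_enrichment(normalize_ko(study.ko_table))
ko = study.truth["exclusive_kos"][0]
spring = study.truth["exclusive_ko_spring"][ko]
print(f"enrichment of exclusive {ko} in {spring}: {enrichment.loc[ko, spring]:.1f}")
```

Output (≈35 s, dominated by the alignment-based cascade):

```
2868 proteins -> 195 families
slope=2.40, adj R^2=0.65, p=1.60e-04, n=15
enrichment of exclusive K00093 in SP012: 14.0
```

The cascade recovers the generator's planted families exactly (adjusted Rand
index 1.0), so the 195 families are the 195 planted ones. The fitted slope
(2.40 families per log unit at a 100-protein subsampling depth) is smaller
than the planted slope of 8 because fixed-depth rarefaction compresses
richness differences — exactly why springs must be compared at a common
depth. The exclusive KO scores S − 1 = 14, the enrichment ceiling for 15
metagenomes.

The same steps are available from the shell:

```bash
springdiv simulate --seed 42 --outdir study/
springdiv cluster --fasta-dir study/proteins --out fam
springdiv rarefy --table fam.families.tsv --depths 100 --reps 100 --seed 42 --out rare.tsv
springdiv enrich --ko study/ko_table.tsv --map study/ko_categories.tsv \
    --subset "Energy Metabolism" --out enrichment.tsv
springdiv tree-metrics --tree study/tree.nwk --tips study/tagged_tips.txt
```

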