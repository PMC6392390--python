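# barcode-eval

Toolkit for evaluating how well short standardized DNA regions — DNA barcodes
such as the plastid loci *matK* and *rbcL* — identify and discriminate plant
species. It is aimed at researchers building regional barcode reference
libraries who need to answer, from aligned sequences and a morphological
taxonomy: *How often does the nearest barcode identify the right species? Is
there a "barcoding gap"? Which species are indistinguishable? Do species,
genera and families come out monophyletic on barcode trees? Do molecular
identifications agree with the vouchers' morphology?*

## What it computes

**Tamura–Nei (TN93) divergence.** Pairwise distances distinguish purine
transitions (A↔G, observed proportion *P₁*), pyrimidine transitions (C↔T,
*P₂*) and transversions (*Q*), with empirical base frequencies π pooled over
each pair and pairwise deletion of gap/missing sites:

```
d = k₁·h(w₁) + k₂·h(w₂) + k₃·h(w₃)

k₁ = 2π_Aπ_G/π_R            w₁ = 1 − P₁/k₁ − Q/(2π_R)
k₂ = 2π_Cπ_T/π_Y            w₂ = 1 − P₂/k₂ − Q/(2π_Y)
k₃ = 2(π_Rπ_Y − π_Aπ_Gπ_Y/π_R − π_Cπ_Tπ_R/π_Y)
                            w₃ = 1 − Q/(2π_Rπ_Y)
```

with `h(w) = −ln w`, or `h(w) = a(w^(−1/a) − 1)` under gamma-distributed
rates across sites with shape *a*. Saturated pairs are reported as undefined,
never truncated.

**Best-close-match (BCM) identification.** Every barcode queries all the
others. A threshold *T* — the empirical 95th percentile of intraspecific
distances — bounds acceptable matches; the species composition of the nearest
matches yields a four-way verdict per query: *correct*, *ambiguous*,
*incorrect*, or *unidentified*.

**Barcoding gap and discrimination.** The gap is present when the minimum
interspecific divergence exceeds the maximum intraspecific divergence; the
per-species analogue (local gap) scores each species as discriminated or not.
Frequency (%) histograms of both divergence classes and a Welch *t*-test
comparing them accompany the gap report.

**Concordance.** Each specimen's morphological identification is compared
with its per-locus molecular identification (supplied, or assigned by nearest
distance to a labelled reference) at species/genus/family rank; two-locus
disagreement at family level flags probable mislabeling or contamination, and
flagged vouchers are excluded before the identification statistics.

**Trees and monophyly.** Neighbor joining (exact on additive matrices) with
nonparametric bootstrap supports, Fitch parsimony with
nearest-neighbor-interchange search, and rank-level monophyly percentages
scored as unrooted bipartitions (a taxon is monophyletic when some edge
separates exactly its leaves; "supported" requires support > 70 by default).
Externally built trees in newick are accepted for scoring.

**Synthetic data.** A generator evolves multi-locus datasets under the same
TN93(+Γ) process the estimator assumes, down a balanced
family/genus/species hierarchy with two specimens per species, intraspecific
divergence near 0.001 and interspecific divergence in the 0.1–0.3 range. It
can plant species that share an identical barcode with a congener, mislabeled
vouchers, and per-locus dropout — so every downstream statistic can be
checked against known ground truth.

## Worked example

```python
from barcode_eval import (
    SimulationConfig, simulate_dataset, PipelineConfig, run_pipeline,
)

cfg = SimulationConfig(seed=7, dropout_by_locus={})   # 50 species x 2 specimens
ds, truth = simulate_dataset(cfg)
report = run_pipeline(ds, PipelineConfig(bootstrap_replicates=100, seed=7), "demo_out")
print(open("demo_out/report.md").read())
```

prints (abridged):

```
## Best-close-match identification (% of queries)

| Barcode | correct | ambiguous | incorrect | unidentified | T |
|---|---|---|---|---|---|
| matK | 91.1 | 4.4 | 0.0 | 4.4 | 0.0025 |
| rbcL | 91.1 | 4.4 | 0.0 | 4.4 | 0.0036 |
| matK+rbcL | 91.1 | 4.4 | 0.0 | 4.4 | 0.0022 |

## Divergences and discrimination

| Barcode | mean intra | mean inter | gap present | discriminated (%) |
|---|---|---|---|---|
| matK | 0.0011 | 0.2463 | False | 95.6 |
```

Reading the numbers: with this seed the simulator planted five species with
barcodes identical to a congener's and five mislabeled vouchers. The
mislabeled vouchers are flagged by the concordance stage and excluded (two of
them happen to hit shared-barcode species, whose now-singleton species drop
out of the cohort). The surviving shared-barcode pair produces the
*ambiguous* queries (4.4% = 4 of 90) and drags the minimum interspecific
divergence to zero, so no barcoding gap exists even though mean intraspecific
divergence (~0.001) is two orders of magnitude below the interspecific mean
(~0.25) — exactly the failure mode the per-species discrimination score
isolates (95.6% of species remain discriminable).

The same analyses are available from the shell:

```bash
barcode-eval simulate --config sim.json --out data/ --seed 7
barcode-eval run --fasta matK=data/matK.fasta --fasta rbcL=data/rbcL.fasta \
    --meta data/metadata.tsv --out results/ --seed 7
barcode-eval monophyly --tree results/matK/nj_tree.newick \
    --meta data/metadata.tsv --rank family
```

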