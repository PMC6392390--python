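# Methods

This note records the models, parameter choices and numerical conventions
behind `barcode-eval`, and what the synthetic-data validation does and does
not demonstrate about real barcode datasets.

## Distance model

Pairwise divergence is estimated under the Tamura–Nei (1993) substitution
model, which allows unequal base frequencies and three exchange classes:
purine transitions (A↔G), pyrimidine transitions (C↔T) and transversions.
Per pair, the observed proportions *P₁*, *P₂*, *Q* of these classes and the
base frequencies π (pooled over both sequences of the pair, not
dataset-wide) enter the closed form given in the package README. Conventions:

- **Pairwise deletion.** For each pair independently, sites where either
  sequence carries `-`, `N` or `?` are excluded. `N`/`?` are missing data,
  `-` is a gap; all three are treated identically for site exclusion and for
  end trimming, because upstream alignment tools mix these conventions.
  Complete deletion would discard most columns of a sparse multi-family
  alignment.
- **Undefined rather than truncated.** When a logarithm (or power) argument
  is ≤ 0 — saturation, or a base composition incompatible with the observed
  counts — the pair is flagged undefined and excluded downstream (with a
  count available from the matrix object). Truncating to a ceiling would
  silently bias gap and threshold statistics.
- **Gamma rate correction.** With rate variation across sites following a
  gamma(*a*) distribution, each −ln *w* term becomes *a*(*w*^(−1/*a*) − 1).
  The shape is an explicit opt-in (`gamma_shape`), default off: the
  appropriate shape is dataset-specific and silently assuming one would be
  worse than reporting the uncorrected distance. The estimator was checked
  against `ape::dist.dna` (models TN93 and TN93+Γ) to 1e-9 on fixed count
  sets, and reduces to the Jukes–Cantor closed form under equal frequencies
  and proportional counts.
- Lineage-specific (non-stationary) composition heterogeneity is **not**
  modelled; the standard stationary TN93 estimator is used.

## Best-close-match identification

The threshold *T* is the empirical quantile of intraspecific distances with
no interpolation: the smallest intraspecific value *x* such that at least
⌈0.95·*n*⌉ of the *n* intraspecific distances are ≤ *x*. Each barcode then
queries all others (never itself — self-matches would trivialize the test):
no defined neighbour within [0, *T*] ⇒ *unidentified*; otherwise the match
set is every database entry within a relative tolerance (default 1e-9) of
the minimum distance, and its species composition gives *correct* /
*ambiguous* / *incorrect*. The tolerance exists because floating-point
distances make exact tie detection fragile; conspecific and heterospecific
co-minima give *ambiguous* regardless of ordering. *T* is computed per
dataset (each marker and the concatenation get their own).

Note a structural consequence of the threshold definition: in a clean
dataset roughly 5% of species have their conspecific distance above *T*, so
best-close-match "correct" saturates near 95%, not 100%.

## Gap analysis and discrimination

The global barcoding gap is `min(inter) > max(intra)`. Because one pair of
indistinguishable species drives `min(inter)` to ~0, the global gap is
fragile; the per-species verdict (local gap: largest conspecific distance
strictly smaller than the smallest distance to any heterospecific) is the
informative statistic. "Discriminated" has no single standard operational
definition; the local-gap criterion was chosen because species sharing an
identical barcode with a congener must fail it, which matches how
undiscriminable species are described in the field. A species with no
defined heterospecific distance is reported *unassessable* and excluded from
the denominator. Histograms use half-open bins [k·w, (k+1)·w) on a shared
grid, default width 0.01, normalized to percent within each class. Welch's
unequal-variance t-test (with Welch–Satterthwaite df) compares the two
divergence classes; one-way ANOVA is available for comparing markers.

## Concordance screening

Molecular identifications are inputs (metadata columns) or are assigned by
nearest distance against a labelled reference alignment; ties at the minimum
are truncated to the deepest rank shared by all tied references. Per
specimen, the verdict is the deepest rank (species/genus/family) at which
either locus agrees with morphology. When neither locus matches even at
family rank: both loci agreeing with each other at family level (or a single
available locus) ⇒ *incorrect*; two loci disagreeing at family level ⇒
*mislabeled* (probable voucher mislabeling or contamination). The pipeline
excludes flagged specimens before the identification statistics, mirroring
standard curation practice; matching is on normalized name strings, with no
synonymy resolution.

## Trees and monophyly

Neighbor joining follows Saitou–Nei with the Q-criterion; ties break on the
first (row-major) pair, so results are deterministic given input order.
Negative branch-length estimates are clamped to zero and the total deficit
logged. On additive matrices the implementation recovers topology and all
path lengths exactly (validated on random 8-taxon matrices to 1e-9).
Bootstrap supports resample alignment columns with replacement, rebuild the
NJ tree, and report the percentage of replicates containing each original
bipartition (default 1000 replicates as a library default; the pipeline uses
100, which is sufficient for the >70% criterion at the simulated signal
strength).

Monophyly is assessed on the unrooted tree: a taxon is monophyletic iff some
edge bipartitions the leaves into exactly that taxon versus the rest, so no
outgroup or rooting choice is needed (verified rooting-invariant).
"Supported" means the defining edge's support strictly exceeds the cutoff
(default 70); single-representative taxa are excluded from percentages.
Order-level congruence against a user-supplied reference grouping uses the
same bipartition rule on unions of orders.

Fitch parsimony treats `-`, `N`, `?` as fully ambiguous (any nucleotide),
never as a fifth state; the count is exact for binary (unrooted-binary)
trees and uses the sequential-intersection generalization at multifurcating
nodes. The parsimony search is steepest-descent nearest-neighbor-interchange
from an NJ start with deterministic tie-breaking; on 6-taxon simulated
alignments it attains the exhaustive-search optimum, but like all local
search it can stall on phylogenetically unstructured (pure-noise) data.

## Synthetic-data generator

The generator emulates a two-specimens-per-species regional plant survey:

| parameter | default | rationale |
|---|---|---|
| hierarchy | 5 families × 2 genera × 5 species × 2 specimens | 50 species / 100 specimens: desk-scale analogue of a survey cohort |
| loci | matK 800 bp, rbcL 550 bp | typical recovered barcode lengths |
| base frequencies | (0.30, 0.20, 0.20, 0.30) | AT-rich plastid composition |
| κ_R, κ_Y | 2.0 | moderate transition bias |
| b_individual | 0.0005 | conspecific divergence ≈ 0.001 substitutions/site |
| b_species / b_genus / b_family | 0.06 / 0.03 / 0.05 | interspecific divergences ≈ 0.1–0.3 across taxonomic depth |
| frac_shared_barcode | 0.10 | fraction of species indistinguishable from a congener |
| frac_mislabeled | 0.05 | voucher mislabeling rate |
| dropout (matK, rbcL) | 0.34, 0.05 | unequal marker recoverability |

Sites evolve independently under the same TN93 process the estimator
assumes, using the closed-form transition probabilities (checked against
`scipy.linalg.expm`); gamma rate multipliers, when enabled, are continuous
and fixed per site across the whole tree, keeping simulator and estimator
consistent. Each locus has its own random stream derived from the seed and
the locus name, so adding a locus never perturbs another. Counted selections
(shared species, mislabels, dropout) take floor(fraction × n) items from a
name-sorted, seed-shuffled list, so datasets are byte-reproducible.

Design choices worth flagging:

- **Shared barcodes are identical, and sharing is symmetric.** A
  shared-barcode group is a set of ≥ 2 congeneric species whose specimens
  all receive the group's ancestor sequence verbatim, and *every* species in
  the group is flagged. Applying individual branches after cloning would
  make sharing asymmetric and stochastic — the "donor" species would fail
  discrimination without being flagged — which would leave the ground truth
  ill-defined. Exactly floor(frac × n_species) species are flagged; an odd
  count is accommodated by one within-genus triple.
- **Mislabels are cross-family.** A mislabeled specimen's morphological
  label is replaced by that of a random species from a *different family*,
  emulating gross voucher mix-ups/contamination — the error class the
  two-locus family-level concordance rules are designed to catch. Same-genus
  misidentifications are real but undetectable by those rules, so planting
  them would only blur the ground truth.
- **Molecular labels are idealized.** The emitted per-locus molecular labels
  are the true taxonomy (as if an external reference database identified
  every clean sequence perfectly). The distance-based
  `nearest_reference_assignment` path is exercised separately in the tests.
- NOT emulated: indels and alignment error, rate variation among lineages,
  non-stationary composition, unbalanced taxon sampling, intraspecific
  geographic structure, sequencing error. Passing the synthetic validation
  therefore shows the *statistics are computed correctly under the assumed
  model*, not that the model captures every difficulty of field data.

## Pipeline and problem sizes

Stage order: concordance screening → exclusion of flagged vouchers → filter
to species with ≥ 2 representatives → per-marker and concatenated analyses
(complete-case concatenation: only specimens with every locus). All
artifacts are hashed into a manifest; identical input, configuration and
seed give a byte-identical manifest. Per-marker artifacts depend only on
that marker's alignment and the shared specimen screen, so removing one
locus from the configuration leaves the others' outputs unchanged whenever
the screening decisions are unchanged (with single-locus evidence the
two-locus *mislabeled* category degrades to *incorrect*, which can relabel —
but not unflag — screened specimens).

The validation suite and the acceptance script run the pipeline at 50
species × 2 specimens with 100 bootstrap replicates, estimator-consistency
checks at L = 2000 over 200 replicates, NJ recovery on 100 random 8-taxon
additive matrices, and exhaustive parsimony enumeration at 6 taxa (105
topologies) — sizes chosen so the full battery completes in minutes on one
core while keeping every check statistically meaningful.

## Known limitations

- Identical sequences make NJ joins arbitrary (though deterministic);
  bootstrap support for such internal edges is an artifact of tie-breaking,
  not signal. Monophyly of shared-barcode species on NJ trees should be
  interpreted accordingly.
- The TN93 estimator's variance grows sharply near saturation; gamma-corrected
  distances with small shape values amplify this further.
- Maximum-likelihood tree inference is out of scope; externally computed ML
  trees can be supplied in newick for monophyly scoring.
- The CLI reads whole alignments into memory; it targets reference-library
  scale (thousands of specimens), not population-genomic scale.
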