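# Methods

This note records the models, the defaults and the numerical choices made
where the design was genuinely open, and what the synthetic tests do and
do not demonstrate about real data.

## Ontology distances and term probability

The ontology is held as a directed acyclic graph with edges from a term to
its `is_a` parents (`part_of` edges can be included by a parser switch but
are off by default). Obsolete terms are dropped at parse time; they carry
no annotations in current GO releases. A term is its own ancestor, so the
self-distance is zero and ancestor closure is idempotent.

The closest-common-parent (ccp) distance between same-namespace terms is
the minimum over common ancestors *a* of the sum of shortest directed hop
counts from each term to *a*. Ties between equally close ancestors are
broken by greater ancestor depth (longest path from the namespace root),
then lexicographic id, so downstream head-term selection is deterministic.
Cross-namespace pairs are incomparable and treated as infinitely distant;
clustering is always run within one namespace.

Term probability is the propagated annotation frequency: after closing
every gene's term set under ancestors, `p(t)` is the fraction of genes
annotated in *t*'s namespace that carry *t*. This is the standard
frequency estimate behind information content `IC(t) = −ln p(t)`; the
namespace root has `p = 1` and `IC = 0`. Genes without annotations stay in
the universe (backgrounds mean "all genes of the organism") but do not
enter the namespace denominator.

## Gene distance and clustering

The distance between two genes in a namespace is, by default, the minimum
ccp distance over all cross pairs of their *direct* (unpropagated) terms —
the best-matching-pair reading of per-term comparison. A symmetrised
best-match average is available (`aggregation="best_match_average"`); both
are tested. Genes without annotations in the namespace take part in no
cluster and are reported separately rather than forced into one.

Clustering is average-linkage agglomeration on the gene-gene distance
matrix, cut at an explicit hop height θ (default 4). Average linkage was
chosen over single linkage to resist chaining, and the explicit cut makes
the operating point auditable: θ = 0 groups only genes with shared or
identical-distance-zero terms, θ = ∞ returns one cluster per namespace.
Output ordering (descending size, then head-term id) is deterministic;
there is no seed dependence anywhere in the analysis path.

The head term of a cluster is the maximal-IC term ancestral (post-closure)
to at least `coverage_fraction` of the member genes. The operation's own
default is full coverage (1.0); the *pipeline* default is 0.8 because a
full-coverage head collapses to the namespace root as soon as a cluster
absorbs a single unrelated gene, which defeats head-term reporting on
noisy DE sets — 0.8 keeps the head stable under up to one-fifth
contamination while still describing the cluster. When only a namespace
root qualifies, the root is returned and flagged.

## Overrepresentation, score and ranking

Overrepresentation of a head term against a DE gene set is the log₂ ratio
of the set frequency to the genome-background frequency. No pseudocount is
added: a term absent from the set scores −∞, which propagates as an
honest "maximally underrepresented" signal rather than a fabricated finite
value. The cluster score is `Σ_t IC(t)·n_t` over member terms with natural
logs — the minimal monotone combination of term rarity and gene support;
the namespace root contributes zero. An exact hypergeometric upper-tail p
is attached to every record for reference but never used to filter or
rank, and no multiple-testing correction is applied (ranking, not
hypothesis rejection, is the output).

Time-point comparison evaluates every discovered head term's
overrepresentation against every time point's DE set, so the delta for an
ordered pair (TP1→TP3, TP3→TP7 by default) is defined whenever both DE
sets exist. Head terms scored at a single time point only are flagged, not
imputed. Increase and decrease lists are ranked by descending cluster
score (a term's score is taken from the cluster it actually headed; if it
headed clusters at several time points, the maximum), ties by term id;
the top 5 per namespace are reported by default. Direction calls use an
absolute ε of 1e−9.

## Gene-set filters and trends

The root-specific filter is conjunctive with inclusive boundaries: leaf
FPKM ≤ 3 in *every* sink- and source-leaf sample, root FPKM ≥ 5 in at
least one root sample, and |log₂ fold change| ≥ 1 with p ≤ 0.15 at some
time point. "Fold change of at least ±2" is read as |log₂fc| ≥ 1 with
PSR/SR in the numerator. The DE set per time point is p ≤ α (default
0.05), boundary included.

Trend classification averages replicates per (tissue, time point)
arithmetically, regresses mean FPKM on the time-point index (equal
spacing) and uses the signed statistic `sign(slope)·R²`: R² itself is
nonnegative, so thresholds of +0.5/−0.5 only make sense attached to the
signed form. The rule: FR_UP when the fibrous-class mean exceeds the
storage-class mean at every time point; otherwise SR_UP / SR_D when the
storage-class signed R² exceeds +0.5 / falls below −0.5; otherwise SR_EQ.

The Welch stand-in for upstream differential expression computes the log₂
fold change of group means with pseudocount 1 (guards zeros on the FPKM
scale) and a Welch t test on log₂(FPKM+1) replicates. With both groups at
zero variance the test statistic is undefined; the stand-in then reports
p = 1 for equal means and p = 0 otherwise, which makes the zero-noise
limit of the generator well defined. At three replicates per group the
test is conservative (observed type-I error ≈ 0.036 at nominal 0.05 on
null data), which the acceptance band accommodates.

## qPCR quantification and root-type calls

Relative expression uses the efficiency-corrected ratio
`E_t^(ΔCt_t) / E_r^(ΔCt_r)` with ΔCt = calibrator − sample; at E = 2 this
is exactly 2^−ΔΔCt. Efficiencies are inputs (per-cycle amplification
factors in [1, 2]); technical replicates are averaged on the Ct scale
before any exponentiation. In the dual-marker log ratio
`log₂(relexp(FR_UP1)/relexp(SR_UP3))` the reference gene cancels exactly
and the calibrator contributes the same additive constant to every root.
Because a "mean of PFR-called roots" calibrator is circular (calls need a
calibrator first), the default calibrator is the per-gene mean Ct over all
roots, which centres the cohort; a two-pass `pfr_mean` mode (provisional
calls, then recalibration on the PFR-called roots) is available and shifts
all log ratios by one constant. The call threshold τ defaults to 0 (the
two groups are of opposite sign); |log₂ ratio| ≤ τ is reported ambiguous.

Group comparisons: Student and Welch two-sample t tests; Tukey HSD over
all pairwise contrasts (headline statistic: the largest studentized range
q with its p); and a two-way ANOVA whose group labels are
(factor A, factor B) tuples, reporting the factor-A main effect, with the
interaction term included when every cell has ≥ 2 observations.

## Synthetic-data generator

The generator emulates the study design: four tissues (SIL, SOL, PFR_FR,
PSR_SR) × four time points × three biological replicates; per-gene
baseline log₂ FPKM ~ Normal(3, 1.2); replicate noise Normal(0, 0.25) on
the log₂ scale (lognormal abundances). Planted structures are disjoint
gene slices recorded in a truth object:

* 12 root-specific genes — leaf FPKM ≤ 2, fibrous-root FPKM in [5, 8],
  storage-root FPKM in [24, 40] (≥ 2-fold contrast with the pseudocount);
* 4 genes per trend group with profiles *linear on the FPKM scale*, so
  the noiseless signed R² is exactly ±1 or 0;
* 30 genes of an enriched GO branch gaining 1.5 log₂ units in the
  storage class from TP3 onward.

The synthetic ontology grows 100 terms per namespace (biological process
and molecular function): the first `branching` (default 3) terms attach
to the root, later terms to a uniformly chosen parent with spare child
capacity, and 10% of terms gain a second, strictly shallower parent —
acyclic by construction. The planted branch head is the deepest term with
at least three children; branch genes are annotated to round-robin pairs
of its children, so the head covers all of them while no single child
covers more than about two-thirds, and the branch subtree sits far from
the rest of the DAG relative to the default cut height. The qPCR
generator gives storage-type roots a marker-Ct advantage growing by 0.8
cycles per week over weeks 1–4 (mirrored for fibrous-type roots), Ct
noise Normal(0, 0.3) per technical replicate, four technical replicates,
and marker/reference efficiencies of 1.95/2.0.

At zero noise every planted truth is recovered exactly by the matching
selector; all generation is reproducible byte-for-byte from one seed
(component sub-seeds are derived via a seed sequence).

What the generator does *not* emulate: count-based mean–variance
coupling, transcript-length effects, correlated co-expression modules,
batch effects, annotation bias toward well-studied genes, or DAG
structure as irregular as real GO. Passing tests therefore demonstrate
correctness of the implemented rules and robustness at the stated noise
levels, not performance on field data.

## Problem sizes and limitations

The default study size (500 genes, 100 terms per namespace, 50 generator
seeds for recovery rates, 100 000 null genes for the type-I check) was
chosen so the full suite and the acceptance script each complete in about
one to two minutes on one CPU while keeping the planted signals at
realistic strength. Known limitations: distance matrices are built
gene-by-gene in Python (quadratic in DE-set size; fine for hundreds of
genes, slow beyond tens of thousands); −∞ overrepresentation values are
reported as-is rather than smoothed; the two-way ANOVA expects a complete
crossed design; and the head-term rule assumes the cluster's genes share
at least the namespace root, which holds whenever each namespace is
single-rooted.
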