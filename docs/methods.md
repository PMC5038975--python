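# Methods

## The similarity model

`phenomatch` scores how similar a drug's side-effect profile is to the
phenotype profile of a gene, with both profiles annotated against one
multi-parent ontology DAG (a 4-level adverse-event hierarchy in the
intended application; any DAG works, and SMQ-style cross-hierarchy
groupings are represented as additional parent links).

**Term specificity.** Information content is intrinsic — computed from the
ontology structure, not from annotation frequency, so heavily studied
phenotypes are not mistaken for specific ones:

    IC(t) = 1 − ln(child(t) + 1) / ln(N)

`child(t)` counts transitive descendants by default (a `direct` mode exists
for sensitivity analysis) and `N` is the total term count. IC is 1 at
leaves, 0 at a root that dominates all other terms, and never decreases
from parent to child. The ratio form makes IC independent of the logarithm
base. A single-term ontology is degenerate; IC is defined as 1 there and a
warning is emitted.

**Term-pair score.** For side effect *i* and trait *j*,

    s_ij = IC(MICA(i, j)) · min(f_i·c_i, f_j·c_j)

MICA is the common ancestor with maximal IC; ancestor sets are
self-inclusive, so an identical pair is anchored at the term itself and
scores maximally. MICA ties break to the lexicographically smallest term
id, making every downstream ranking deterministic.

**Weights.** The frequency weight `f = −ln(k/n)` vanishes for terms
annotated to every entity of a corpus. The co-occurrence weight is
`c = −ln J(A, B)` with J the Jaccard index of the two terms' entity sets,
evaluated inside each term's own corpus (`c_i` among drugs, `c_j` among
genes); a `pooled` mode computing one Jaccard over both corpora is
available behind `ScoringConfig.cooccurrence_mode`. Two conventions close
the gaps the formula leaves open:

* *J = 0 cap.* `−ln 0` is infinite; never-co-occurring pairs instead take
  `c = −ln(1/(|A∪B|+1))` — maximally but finitely informative, growing only
  logarithmically with support.
* *Identity.* The co-occurrence weight exists to penalise redundant term
  pairs within a profile corpus. A side effect compared with the literally
  identical trait term is a perfect cross-corpus match, not a redundant
  pair, so in scoring it takes the supremum of the capped weight,
  `−ln(1/(n+1))`. Applying the within-corpus self-Jaccard (J = 1, c = 0)
  instead would zero out every exact match — measurably destroying the
  planted signal (ranking AUC drops below chance) — and any smaller value
  than the supremum lets a never-co-occurring sibling pair outweigh a
  perfect match. The within-corpus primitive `cooccurrence_weight(t, t)`
  still returns 0, as a statement about profile redundancy.

Terms present in the ontology but absent from a corpus have undefined
weights; any term-pair score touching one is 0 rather than an error.

**Aggregation.** Per gene–drug pair: every gene trait contributes its
best-matching side effect (mean over all traits); every side effect
contributes its best-matching trait, but only the top `K = 20` side-effect
values enter (all of them when the drug has fewer than 20). This cutoff is
the polypharmacology correction — a drug's profile aggregates the effects
of several targets plus idiosyncratic noise, and only the side effects
echoing the *compared* gene should count; the selected set may differ
between genes. Ties at rank K break by (score desc, term id asc), so the
reported contributing side effects are reproducible. The default
combination is the pooled mean of both directions' value lists (a
`mean_of_means` mode is provided; the two agree when the lists have equal
length).

**Scaling and normalization.** The raw score is multiplied by
`ln(#gene terms)` — genes with little phenotypic information produce
chance matches, and a single-trait gene is deliberately scaled to 0 (with a
logged warning; `ln_n_plus_1` mode retains such genes) — and by a burden
weight from the tertile of the drug's side-effect count (1, 0.66, 0.33;
boundaries are the 33%/66% linear-interpolation quantiles, boundary ties
falling to the lower bin). Finally scores are divided by the maximum scaled
value of the run; the maximum is recorded in the output metadata so runs
remain comparable. Scaling precedes normalization.

## Evaluation

Benchmarks follow the curated drug–target construction: the universe is
the cross product of all drugs and genes appearing in at least one usable
positive (a `scored` mode uses every scored pair instead). The confusion
curve has one point per distinct score, thresholds descending; tied pairs
cross the threshold together, so no rate depends on an arbitrary intra-tie
order. Derived rates: precision, TPR, FPR, accuracy and lift =
precision/prevalence; AUC is the trapezoid area under (FPR, TPR) from the
origin. `threshold_at_precision` returns the lowest score whose curve
point still reaches the requested precision — the high/low split score.
The trivial all-positive classifier has lift exactly 1 at the lowest
threshold.

The causal side-effect fraction of a pair is the share of its (≤ 20)
contributing side effects independently known to be caused through the
gene's protein; high- vs low-scoring groups are compared with a one-sided
Mann–Whitney rank-sum test (normal approximation, tie correction; fully
degenerate input yields p = 0.5 with a warning). PPI proximity is the
minimum hop count from the gene to any known target of the drug: 0 means
the gene *is* a target, 1 a direct interactor; unreachable genes get a
`None` sentinel. Mapping coverage is binned by term frequency with
half-open-left, closed-right bins (gene side: 1, ]1,5], ]5,10], ]10,50],
]50,100], >100; drug side adds ]100,500] and >500 because a few side
effects recur across hundreds of drugs).

## The synthetic study generator

The generator produces everything the pipeline consumes — ontology,
annotation corpora, planted gene–drug truth, a PPI graph and a causal
gene–side-effect catalogue — from one seed, with per-artifact sub-streams
so that, e.g., adding drugs does not perturb gene sampling.

The default study: a complete depth-4, branching-3 hierarchy (40 terms, 27
leaves), 50 genes with 4–6 leaf traits sampled uniformly, 30 single-target
drugs that echo 95% of their target's traits (each echo swapped for a
sibling leaf with probability 0.05, modelling the imperfect
mouse-to-human phenotype correspondence), topped up to a fixed budget of 7
side effects with unrelated noise. Noise leaves are drawn from a Zipf
profile (exponent 1.5) over a seed-fixed popularity ranking — like real
adverse events, a common head recurs across many drugs while the tail is
rare; the frequency weight is precisely the mechanism that neutralises the
common head. Noise avoids only the already-echoed terms: excluding whole
target trait sets would make the no-signal control (copy fraction 0)
anti-correlated instead of chance-level.

Choices that keep the desk scale faithful to the method's assumptions:

* *Leaf-only trait sampling* keeps the IC of exact matches at 1, making the
  planted signal analytically predictable.
* *Fixed side-effect budget.* With a 27-leaf vocabulary, drug profile sizes
  can only vary by a few terms, yet the burden tertiles would still hand
  out a 3× penalty across ±1-count differences — pure noise at this scale,
  whereas the real data the correction was designed for spans two orders
  of magnitude in profile size. Holding the budget constant makes the
  tertiles degenerate (every drug weight 1) in the default study; burden
  weighting is exercised by its own unit tests and by the stress
  configuration.
* *Trait/target ranges* (4–6 traits, one target) keep the chance that an
  unrelated drug covers a full gene profile small; with 27 leaves, larger
  profiles make accidental full coverage — indistinguishable from a
  planted pair by any method — common enough to cap attainable ranking
  quality well below what the real, far sparser vocabularies allow.

`polypharmacology_stress_config` is the heavy-noise regime: branching 4
(85 terms, 64 leaves), exactly 3 targets per drug, 60% echo, 20–30 noise
side effects (variable, so burden weighting is active). Here drug profiles
exceed the K = 20 cutoff and the top-20 correction measurably raises
ranking AUC over the uncorrected score, paired per seed.

What the generator does **not** emulate: side-effect frequency/severity
structure, realistic term-usage distributions of a clinical vocabulary,
annotation noise in the positives, or orthology mapping losses. Passing
tests therefore show the pipeline's internal correctness and the method's
behaviour under its own assumptions — not performance on real
pharmacovigilance data.

## Problem sizes and reported quantities

Tests and `scripts/acceptance.py` run on the 40-term / 50-gene / 30-drug
default study (1500 pairs), 20 stress seeds for the paired cutoff
comparison and 5 replicates for the no-signal control; the control is
reported as a mean because a single ~30-positive study has an AUC sampling
standard deviation of ~0.05. All randomness derives from the script's
`--seed` via `numpy.random.SeedSequence`.

## Known limitations

* The normalization maximum is run-relative; scores from different runs are
  comparable only through the recorded maximum.
* A gene with one annotation scores 0 under the default `ln_n` scaling by
  design; use `ln_n_plus_1` when such genes must be retained.
* `confusion_curve` emits one point per distinct score; published curves
  produced by sweep-granularity tools may differ cosmetically, not in AUC.
* The PPI generator wires targets to decoys at random; proximity analyses
  on it demonstrate plumbing, not biology.
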